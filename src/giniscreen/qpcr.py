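"""Comparative-Ct (delta-delta-Ct) quantification of transcript stabilisation.

Candidates from the array screen are validated by semi-quantitative
real-time RT-PCR: target-gene threshold cycles are normalised to a
reference gene (GAPDH in the assay this models) and calibrated to the
matched untreated control of the same cell line,

    dCt(cond)  = mean Ct(target, cond) - mean Ct(reference, cond)
    ddCt       = dCt(treated) - dCt(untreated)
    fold       = 2 ** (-ddCt)

assuming perfect doubling per cycle. The stabilisation call is
fold >= threshold (default 1.5, boundary inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import SampleSheet, ValidationError

__all__ = [
    "CtRecord",
    "ddct_fold",
    "stabilisation_call",
    "validation_concordance",
    "read_ct_table",
    "write_fold_table",
]


@dataclass
class CtRecord:
    """Replicate threshold cycles for one (individual, gene role, condition).

    ``role`` is ``"target"`` (the candidate gene) or ``"reference"``
    (the housekeeping normaliser). Typically four replicate Cts; at least
    two are required so a standard error exists.
    """

    individual_id: str
    role: str
    treatment: str
    cts: tuple[float, ...]
    gene: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("target", "reference"):
            raise ValidationError(f"role must be 'target' or 'reference', got {self.role!r}")
        if self.treatment not in ("caffeine", "untreated"):
            raise ValidationError(f"unknown treatment {self.treatment!r}")
        if len(self.cts) < 2:
            raise ValidationError(
                f"{self.individual_id}/{self.role}/{self.treatment}: "
                "need >= 2 replicate Ct values"
            )
        arr = np.asarray(self.cts, dtype=float)
        if not np.isfinite(arr).all() or (arr <= 0).any():
            raise ValidationError(
                f"{self.individual_id}/{self.role}/{self.treatment}: "
                "Ct values must be finite and positive"
            )

    @property
    def mean(self) -> float:
        return float(np.mean(self.cts))

    @property
    def sem(self) -> float:
        arr = np.asarray(self.cts, dtype=float)
        return float(arr.std(ddof=1) / np.sqrt(len(arr)))


def ddct_fold(
    target_treated: CtRecord,
    ref_treated: CtRecord,
    target_untreated: CtRecord,
    ref_untreated: CtRecord,
) -> tuple[float, float]:
    """Fold change and its standard error by the comparative-Ct method.

    The SEM is first-order error propagation through 2**(-ddCt):
    sem(fold) = fold * ln2 * sqrt(sum of the four mean-Ct sems squared).
    """
    records = (target_treated, ref_treated, target_untreated, ref_untreated)
    ind = {r.individual_id for r in records}
    if len(ind) != 1:
        raise ValidationError(f"Ct records mix individuals: {sorted(ind)}")
    for r, (role, trt) in zip(
        records,
        [("target", "caffeine"), ("reference", "caffeine"),
         ("target", "untreated"), ("reference", "untreated")],
    ):
        if r.role != role or r.treatment != trt:
            raise ValidationError(
                f"expected ({role}, {trt}) record, got ({r.role}, {r.treatment})"
            )
    dct_treated = target_treated.mean - ref_treated.mean
    dct_untreated = target_untreated.mean - ref_untreated.mean
    ddct = dct_treated - dct_untreated
    fold = float(2.0 ** (-ddct))
    sem = fold * np.log(2.0) * np.sqrt(sum(r.sem**2 for r in records))
    return fold, float(sem)


def stabilisation_call(fold: float, threshold: float = 1.5) -> bool:
    """True iff the transcript is stabilised at least ``threshold``-fold."""
    if fold <= 0:
        raise ValidationError("fold must be positive")
    return fold >= threshold


@dataclass
class ConcordanceSummary:
    """How qPCR stabilisation calls line up with affected status in a family."""

    family_id: str
    n_affected_positive: int
    n_affected: int
    n_unaffected_positive: int
    n_unaffected: int
    discordant: list[str] = field(default_factory=list)

    @property
    def fully_concordant(self) -> bool:
        return not self.discordant


def validation_concordance(
    calls: dict[str, bool], sheet: SampleSheet, family_id: str
) -> ConcordanceSummary:
    """Summarise stabilisation calls against affected status.

    Discordant individuals are affected members without stabilisation or
    unaffected members with it (the screen's "unaffected carrier"
    exception pattern). Every family member must have a call.
    """
    affected = sheet.family_members(family_id, "affected")
    unaffected = sheet.family_members(family_id, "unaffected")
    members = affected + unaffected
    unknown = set(calls) - set(sheet.data["individual_id"])
    if unknown:
        raise ValidationError(f"unknown individual {sorted(unknown)[0]!r}")
    missing = [m for m in members if m not in calls]
    if missing:
        raise ValidationError(f"no stabilisation call for {missing[0]!r}")
    discordant = [m for m in affected if not calls[m]] + [
        m for m in unaffected if calls[m]
    ]
    return ConcordanceSummary(
        family_id=family_id,
        n_affected_positive=sum(calls[m] for m in affected),
        n_affected=len(affected),
        n_unaffected_positive=sum(calls[m] for m in unaffected),
        n_unaffected=len(unaffected),
        discordant=sorted(discordant),
    )


# ---------------------------------------------------------------------------
# text formats
# ---------------------------------------------------------------------------


def read_ct_table(path: str | Path) -> list[CtRecord]:
    """Read a Ct CSV: individual_id, gene, role, treatment, rep1..repK."""
    df = pd.read_csv(path)
    required = ["individual_id", "gene", "role", "treatment"]
    for col in required:
        if col not in df.columns:
            raise ValidationError(f"Ct table missing column {col!r}")
    rep_cols = [c for c in df.columns if c.startswith("rep")]
    if len(rep_cols) < 2:
        raise ValidationError("Ct table needs >= 2 replicate columns (rep1, rep2, ...)")
    records = []
    for _, row in df.iterrows():
        cts = tuple(float(row[c]) for c in rep_cols if pd.notna(row[c]))
        records.append(
            CtRecord(
                individual_id=str(row["individual_id"]),
                role=str(row["role"]),
                treatment=str(row["treatment"]),
                cts=cts,
                gene=str(row["gene"]),
            )
        )
    return records


def write_fold_table(
    folds: dict[str, tuple[float, float]],
    calls: dict[str, bool],
    path: str | Path,
) -> None:
    """Write per-individual folds, SEMs and stabilisation calls as TSV."""
    rows = [
        {
            "individual_id": ind,
            "fold": fold,
            "sem": sem,
            "stabilised": calls[ind],
        }
        for ind, (fold, sem) in sorted(folds.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")
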