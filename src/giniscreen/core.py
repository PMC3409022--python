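"""Core containers and plain-text formats for the NMD-inhibition screen.

The screen works on two tables:

* an expression matrix — probe x array intensities exported from bead-array
  scanner software as a tab-separated "sample probe profile", either on the
  raw (strictly positive) intensity scale or on log2 scale after transform;
* a sample sheet — one row per hybridised array, annotating the family,
  the individual the lymphoblastoid cell line came from, affected status,
  caffeine treatment and technical-replicate index.

Both are round-trippable text formats (UTF-8, LF, fixed column order) so a
written file re-read and re-written is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GiniError",
    "FormatError",
    "ValidationError",
    "ExpressionMatrix",
    "SampleSheet",
    "ScreenPolicy",
    "DesignSummary",
    "read_expression",
    "write_expression",
    "read_sample_sheet",
    "write_sample_sheet",
    "validate_design",
]

STATUSES = ("affected", "unaffected", "control")
TREATMENTS = ("caffeine", "untreated")

#: required sample-sheet columns, in canonical order
SHEET_COLUMNS = [
    "array_id",
    "family_id",
    "individual_id",
    "status",
    "treatment",
    "replicate",
    "caffeine_mM",
]


class GiniError(Exception):
    """Base class for errors raised by this package."""


class FormatError(GiniError):
    """A file could not be parsed as the expected text format."""


class ValidationError(GiniError):
    """Parsed data violates a domain invariant."""


@dataclass
class ExpressionMatrix:
    """Probe x array intensity matrix with a probe -> gene-symbol map.

    Parameters
    ----------
    data
        DataFrame of intensities, index = probe ids, columns = array ids.
    genes
        Series mapping probe id -> gene symbol, aligned with ``data.index``.
        Probes without an annotated symbol default to their own id.
    scale
        ``"raw"`` (strictly positive intensities) or ``"log2"``.
    """

    data: pd.DataFrame
    genes: pd.Series
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValidationError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate probe id {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValidationError(f"duplicate array id {dup!r}")
        if not self.genes.index.equals(self.data.index):
            raise ValidationError("gene-symbol index does not match probe ids")
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(vals).all():
            i, j = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"non-finite intensity at probe {self.data.index[i]!r}, "
                f"array {self.data.columns[j]!r}"
            )
        if self.scale == "raw" and (vals <= 0).any():
            i, j = np.argwhere(vals <= 0)[0]
            raise ValidationError(
                f"non-positive raw intensity at probe {self.data.index[i]!r}, "
                f"array {self.data.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def array_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_probes(self) -> int:
        return self.data.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.data.shape[1]

    def subset_arrays(self, array_ids: Sequence[str]) -> "ExpressionMatrix":
        """Return a view-like copy restricted to the given arrays, in order."""
        missing = [a for a in array_ids if a not in self.data.columns]
        if missing:
            raise ValidationError(f"unknown array id {missing[0]!r}")
        return ExpressionMatrix(self.data[list(array_ids)], self.genes, self.scale)


@dataclass
class SampleSheet:
    """Array-level annotations: one row per hybridised array.

    Extra columns beyond :data:`SHEET_COLUMNS` are preserved as opaque
    annotations. Each individual must have equal numbers of caffeine-treated
    and untreated arrays (the screen contrasts each treated array against
    its own untreated control).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in SHEET_COLUMNS:
            if col not in df.columns:
                raise ValidationError(f"sample sheet missing required column {col!r}")
        if df["array_id"].duplicated().any():
            dup = df.loc[df["array_id"].duplicated(), "array_id"].iloc[0]
            raise ValidationError(f"duplicate array id {dup!r}")
        bad_status = set(df["status"]) - set(STATUSES)
        if bad_status:
            raise ValidationError(f"unknown status {bad_status.pop()!r}")
        bad_trt = set(df["treatment"]) - set(TREATMENTS)
        if bad_trt:
            raise ValidationError(f"unknown treatment {bad_trt.pop()!r}")
        if (df["replicate"].astype(int) < 1).any():
            raise ValidationError("replicate indices must be >= 1")
        key = df[["individual_id", "treatment", "replicate"]]
        if key.duplicated().any():
            row = df.loc[key.duplicated()].iloc[0]
            raise ValidationError(
                "duplicate (individual, treatment, replicate): "
                f"({row['individual_id']}, {row['treatment']}, {row['replicate']})"
            )
        caff = df["caffeine_mM"].astype(float)
        untreated = df["treatment"] == "untreated"
        if (caff[untreated] != 0).any():
            bad = df.loc[untreated & (caff != 0), "array_id"].iloc[0]
            raise ValidationError(f"untreated array {bad!r} has non-zero caffeine dose")
        if (caff[~untreated] <= 0).any():
            bad = df.loc[~untreated & (caff <= 0), "array_id"].iloc[0]
            raise ValidationError(f"caffeine array {bad!r} has non-positive dose")
        counts = df.groupby(["individual_id", "treatment"]).size().unstack(fill_value=0)
        for trt in TREATMENTS:
            if trt not in counts.columns:
                counts[trt] = 0
        unbalanced = counts[counts["caffeine"] != counts["untreated"]]
        if len(unbalanced):
            raise ValidationError(
                f"individual {unbalanced.index[0]!r} has "
                f"{unbalanced['caffeine'].iloc[0]} caffeine vs "
                f"{unbalanced['untreated'].iloc[0]} untreated arrays"
            )

    def canonical(self) -> "SampleSheet":
        """Sorted copy: fixed column order, rows by family/individual/treatment/replicate."""
        extras = [c for c in self.data.columns if c not in SHEET_COLUMNS]
        df = self.data[SHEET_COLUMNS + sorted(extras)].copy()
        df = df.sort_values(
            ["family_id", "individual_id", "treatment", "replicate"],
            kind="stable",
        ).reset_index(drop=True)
        return SampleSheet(df)

    @property
    def individuals(self) -> list[str]:
        return sorted(self.data["individual_id"].unique())

    @property
    def families(self) -> list[str]:
        return sorted(self.data["family_id"].unique())

    def family_members(self, family_id: str, status: str | None = None) -> list[str]:
        df = self.data[self.data["family_id"] == family_id]
        if len(df) == 0:
            raise ValidationError(f"unknown family {family_id!r}")
        if status is not None:
            df = df[df["status"] == status]
        return sorted(df["individual_id"].unique())

    def arrays_for(self, individual_id: str, treatment: str) -> list[str]:
        df = self.data
        sel = (df["individual_id"] == individual_id) & (df["treatment"] == treatment)
        sub = df.loc[sel].sort_values("replicate", kind="stable")
        return list(sub["array_id"])

    def status_of(self, individual_id: str) -> str:
        st = self.data.loc[self.data["individual_id"] == individual_id, "status"].unique()
        if len(st) == 0:
            raise ValidationError(f"unknown individual {individual_id!r}")
        return st[0]


@dataclass
class ScreenPolicy:
    """Decision rules for calling significance and selecting candidates.

    ``alpha`` is the BH-adjusted p-value threshold; a positive B-statistic
    (posterior probability of differential expression above 50%) is
    additionally required by default. ``direction`` restricts the
    affected-individual calls to up-regulation ("stabilised after caffeine").
    ``affected_rule`` demands significance in all affected family members or
    in at least ``k`` of them; ``unaffected_exclusion`` sets the scope of the
    unaffected veto (same family, or unaffected members of every family).
    """

    alpha: float = 0.05
    require_positive_B: bool = True
    direction: str = "up"
    affected_rule: str = "all"
    k: int = 1
    unaffected_exclusion: str = "same_family"
    fold_report_thresholds: tuple[float, ...] = (1.5, 2.0)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.direction not in ("up", "any"):
            raise ValidationError(f"direction must be 'up' or 'any', got {self.direction!r}")
        if self.affected_rule not in ("all", "at_least_k"):
            raise ValidationError(f"unknown affected_rule {self.affected_rule!r}")
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if self.unaffected_exclusion not in ("same_family", "all_families"):
            raise ValidationError(
                f"unknown unaffected_exclusion {self.unaffected_exclusion!r}"
            )
        if any(t <= 1 for t in self.fold_report_thresholds):
            raise ValidationError("fold thresholds must exceed 1")


@dataclass
class DesignSummary:
    """Per-family array bookkeeping plus study totals."""

    per_family: pd.DataFrame  # index family_id; n_affected, n_unaffected, n_controls, replicates, n_arrays
    n_individuals: int
    n_arrays: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{len(self.per_family)} families, {self.n_individuals} cell lines, "
            f"{self.n_arrays} arrays\n{self.per_family.to_string()}"
        )


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, scale: str = "raw") -> ExpressionMatrix:
    """Read a tab-separated probe-profile file.

    Layout: header row; first column ``ProbeID``; optional second column
    ``Symbol`` (gene symbols); every further column one array, header =
    array id. Raises :class:`FormatError` / :class:`ValidationError` with
    diagnostics naming the offending probe or array.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "ProbeID":
        raise FormatError(
            f"{path.name}: first column must be 'ProbeID', got {df.columns[0]!r}"
        )
    has_symbol = len(df.columns) > 1 and df.columns[1] == "Symbol"
    array_cols = list(df.columns[(2 if has_symbol else 1):])
    if not array_cols:
        raise FormatError(f"{path.name}: no array columns")
    probes = pd.Index(df["ProbeID"], name="ProbeID")
    values = pd.DataFrame(index=probes)
    for col in array_cols:
        num = pd.to_numeric(df[col], errors="coerce")
        if num.isna().any():
            bad = df.loc[num.isna(), "ProbeID"].iloc[0]
            raise FormatError(
                f"{path.name}: non-numeric value for probe {bad!r} in array {col!r}"
            )
        values[col] = num.to_numpy(float)
    if has_symbol:
        genes = pd.Series(df["Symbol"].to_numpy(), index=probes)
        genes = genes.fillna(pd.Series(probes, index=probes))
    else:
        genes = pd.Series(probes, index=probes)
    return ExpressionMatrix(values, genes, scale)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the tab-separated probe profile (UTF-8, LF, shortest-repr floats)."""
    path = Path(path)
    out = matrix.data.copy()
    out.insert(0, "Symbol", matrix.genes)
    out.index.name = "ProbeID"
    out.to_csv(path, sep="\t", lineterminator="\n", encoding="utf-8")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read and validate the array annotation CSV."""
    df = pd.read_csv(path)
    for col in SHEET_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{Path(path).name}: missing required column {col!r}")
    df["replicate"] = df["replicate"].astype(int)
    df["caffeine_mM"] = df["caffeine_mM"].astype(float)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.canonical().data.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def validate_design(sheet: SampleSheet) -> DesignSummary:
    """Check design consistency and summarise arrays per family.

    For every family the array count must equal
    (affected + unaffected + controls) x 2 conditions x replicates.
    Raises if an individual appears in more than one family.
    """
    df = sheet.data
    fam_per_ind = df.groupby("individual_id")["family_id"].nunique()
    if (fam_per_ind > 1).any():
        bad = fam_per_ind[fam_per_ind > 1].index[0]
        raise ValidationError(f"individual {bad!r} assigned to more than one family")

    rows = []
    for fam, sub in df.groupby("family_id"):
        inds = sub.drop_duplicates("individual_id")
        n_aff = int((inds["status"] == "affected").sum())
        n_un = int((inds["status"] == "unaffected").sum())
        n_ctl = int((inds["status"] == "control").sum())
        reps = int(sub["replicate"].max())
        n_arrays = len(sub)
        expected = (n_aff + n_un + n_ctl) * 2 * reps
        if n_arrays != expected:
            raise ValidationError(
                f"family {fam!r}: {n_arrays} arrays but design implies {expected}"
            )
        rows.append(
            {
                "family_id": fam,
                "n_affected": n_aff,
                "n_unaffected": n_un,
                "n_controls": n_ctl,
                "replicates": reps,
                "n_arrays": n_arrays,
            }
        )
    per_family = pd.DataFrame(rows).set_index("family_id").sort_index()
    return DesignSummary(
        per_family=per_family,
        n_individuals=int(df["individual_id"].nunique()),
        n_arrays=len(df),
    )
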