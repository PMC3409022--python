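"""Synthetic NMD-inhibition microarray experiments on multi-case families.

The generator reproduces the statistical structure the analysis assumes,
so every downstream stage is testable without any array download:

* paired caffeine/untreated arrays per individual in technical replicates;
* a large "global caffeine response" gene set, differentially expressed in
  every individual with random sign;
* planted PTC-carrier genes: heterozygous stabilisation shows up as a
  small positive log2 fold change Delta, scaled per carrier by that
  individual's NMD-inhibition efficiency eta (an individual-level
  property, drawn once and reused across genes);
* per-array multiplicative scale artefacts that quantile normalization
  removes;
* Gaussian biological (per gene x individual) and technical (per
  gene x array) noise on the log2 scale.

The log2 signal for probe g on array a of individual i is

    y(g, a) = mu_g + b(g, i) + x(a) * delta(g, i) + eps(g, a)

with x = 1 iff caffeine-treated, delta the global effect (all individuals)
or eta(i) * Delta (carriers of a planted gene), and the written raw value
2**y * array_scale(a). Identical parameters and seed give bit-identical
output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, SampleSheet, ValidationError
from .qpcr import CtRecord

__all__ = [
    "PlantedGene",
    "SimParams",
    "SimTruth",
    "design_from_family_spec",
    "simulate_expression",
    "simulate_ct",
]

#: caffeine dose carried as metadata on treated arrays (mM); the
#: concentration found optimal for lymphoblastoid cell lines
DEFAULT_CAFFEINE_MM = 7.5


@dataclass(frozen=True)
class PlantedGene:
    """A PTC-bearing gene planted in specific carriers of one family."""

    gene: str
    family_id: str
    log2_fold: float  # Delta: log2 stabilisation fold at full NMD inhibition
    carriers: tuple[str, ...]


@dataclass
class SimParams:
    """Generator settings (log2 units unless noted).

    Defaults emulate the screen's study conditions: baseline intensities
    around 2**7 with 1.5 log2 units of spread, modest biological
    (sigma_bio) and technical (sigma_tech) noise, ~15% of genes in the
    global caffeine response with half-normal effect magnitudes of scale
    0.5 plus ``global_effect_min``, per-individual NMD-inhibition
    efficiency eta drawn uniformly from ``eta_range``, and per-array scale
    factors with 0.05 log2 sd. ``positive_control_fold`` is the realised
    (not eta-scaled) stabilisation of ``positive_control_gene`` in
    ``status == "control"`` individuals, mirroring the assay's
    truncation-bearing control cell line.
    """

    n_probes: int = 5000
    probes_per_gene: int = 2
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    sigma_bio: float = 0.10
    sigma_tech: float = 0.15
    array_scale_sd: float = 0.05
    p_global: float = 0.15
    global_effect_sd: float = 0.5
    global_effect_min: float = 0.0
    planted: tuple[PlantedGene, ...] = ()
    eta_range: tuple[float, float] = (0.5, 1.5)
    positive_control_gene: str | None = None
    positive_control_fold: float = 2.78
    ct_noise_sd: float = 0.05
    ct_replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < 1 or self.probes_per_gene < 1:
            raise ValidationError("n_probes and probes_per_gene must be >= 1")
        for name in ("baseline_sd", "sigma_bio", "sigma_tech", "array_scale_sd",
                     "global_effect_sd", "global_effect_min", "ct_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 <= self.p_global < 1:
            raise ValidationError("p_global must be in [0, 1)")
        lo, hi = self.eta_range
        if not (0 < lo <= hi):
            raise ValidationError("eta_range must satisfy 0 < lo <= hi")
        if self.positive_control_fold <= 0:
            raise ValidationError("positive_control_fold must be positive")
        if self.ct_replicates < 2:
            raise ValidationError("ct_replicates must be >= 2")


@dataclass
class SimTruth:
    """Ground-truth labels for recovery tests.

    global_effects : gene -> true log2 effect delta (all individuals).
    planted : the planted PTC genes (never in the global set).
    eta : individual -> NMD-inhibition efficiency.
    array_log2_scale : array -> log2 of the multiplicative scale factor.
    """

    global_effects: dict[str, float]
    planted: list[PlantedGene]
    eta: dict[str, float]
    array_log2_scale: dict[str, float]
    positive_control: tuple[str, float] | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "global_effects": self.global_effects,
            "planted": [asdict(p) for p in self.planted],
            "eta": self.eta,
            "array_log2_scale": self.array_log2_scale,
            "positive_control": list(self.positive_control)
            if self.positive_control
            else None,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        planted = [
            PlantedGene(
                gene=p["gene"],
                family_id=p["family_id"],
                log2_fold=p["log2_fold"],
                carriers=tuple(p["carriers"]),
            )
            for p in payload["planted"]
        ]
        pc = payload.get("positive_control")
        return cls(
            global_effects=payload["global_effects"],
            planted=planted,
            eta=payload["eta"],
            array_log2_scale=payload["array_log2_scale"],
            positive_control=(pc[0], float(pc[1])) if pc else None,
        )


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def design_from_family_spec(
    families: Sequence[tuple], replicates: int
) -> SampleSheet:
    """Build the array design from family sizes.

    ``families`` holds tuples ``(family_id, n_affected, n_unaffected)`` or
    ``(family_id, n_affected, n_unaffected, n_controls)``. Every individual
    gets one caffeine and one untreated array per technical replicate, with
    deterministic ids (e.g. ``B-A1_caf_r2``).
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    rows = []
    seen = set()
    for spec in families:
        fam, n_aff, n_un = spec[0], int(spec[1]), int(spec[2])
        n_ctl = int(spec[3]) if len(spec) > 3 else 0
        if fam in seen:
            raise ValidationError(f"duplicate family id {fam!r}")
        seen.add(fam)
        if min(n_aff, n_un, n_ctl) < 0:
            raise ValidationError(f"family {fam!r}: negative individual count")
        if n_aff + n_un + n_ctl == 0:
            raise ValidationError(f"family {fam!r} has zero individuals")
        members = (
            [(f"{fam}-A{i + 1}", "affected") for i in range(n_aff)]
            + [(f"{fam}-U{i + 1}", "unaffected") for i in range(n_un)]
            + [(f"{fam}-C{i + 1}", "control") for i in range(n_ctl)]
        )
        for ind, status in members:
            for rep in range(1, replicates + 1):
                for trt, tag, dose in (
                    ("caffeine", "caf", DEFAULT_CAFFEINE_MM),
                    ("untreated", "unt", 0.0),
                ):
                    rows.append(
                        {
                            "array_id": f"{ind}_{tag}_r{rep}",
                            "family_id": fam,
                            "individual_id": ind,
                            "status": status,
                            "treatment": trt,
                            "replicate": rep,
                            "caffeine_mM": dose,
                        }
                    )
    return SampleSheet(pd.DataFrame(rows)).canonical()


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------


def _gene_names(n_genes: int) -> list[str]:
    return [f"GENE{i + 1:05d}" for i in range(n_genes)]


def simulate_expression(
    design: SampleSheet, params: SimParams
) -> tuple[ExpressionMatrix, SimTruth]:
    """Generate a raw intensity matrix plus its ground truth.

    Probes are grouped into genes of ``probes_per_gene`` consecutive
    probes; all probes of a gene share its true effect. Planted genes are
    excluded from the global-response draw so the two truth sets never
    overlap.
    """
    params.__post_init__()  # re-validate in case fields were mutated
    rng = np.random.default_rng(params.seed)

    n_probes = params.n_probes
    n_genes = math.ceil(n_probes / params.probes_per_gene)
    genes = _gene_names(n_genes)
    gene_of_probe = np.repeat(np.arange(n_genes), params.probes_per_gene)[:n_probes]
    probe_ids = [
        f"PRB{i + 1:06d}" for i in range(n_probes)
    ]

    df = design.data
    individuals = sorted(df["individual_id"].unique())
    ind_index = {ind: k for k, ind in enumerate(individuals)}
    arrays = list(df["array_id"])
    array_ind = np.array([ind_index[i] for i in df["individual_id"]])
    array_treated = (df["treatment"] == "caffeine").to_numpy()

    gene_index = {g: j for j, g in enumerate(genes)}
    fam_members = {
        fam: set(sub["individual_id"]) for fam, sub in df.groupby("family_id")
    }
    planted_gene_idx = set()
    for p in params.planted:
        if p.gene not in gene_index:
            raise ValidationError(f"planted gene {p.gene!r} not in the simulated panel")
        if p.family_id not in fam_members:
            raise ValidationError(f"planted family {p.family_id!r} not in the design")
        missing = set(p.carriers) - fam_members[p.family_id]
        if missing:
            raise ValidationError(
                f"carrier {sorted(missing)[0]!r} not in family {p.family_id!r}"
            )
        planted_gene_idx.add(gene_index[p.gene])
    if params.positive_control_gene is not None:
        if params.positive_control_gene not in gene_index:
            raise ValidationError(
                f"positive-control gene {params.positive_control_gene!r} "
                "not in the simulated panel"
            )
        planted_gene_idx.add(gene_index[params.positive_control_gene])

    # fixed draw order for determinism
    mu = rng.normal(params.baseline_mean, params.baseline_sd, size=n_probes)
    eligible = np.array(
        [j for j in range(n_genes) if j not in planted_gene_idx], dtype=int
    )
    n_global = int(round(params.p_global * n_genes))
    n_global = min(n_global, len(eligible))
    global_idx = np.sort(rng.choice(eligible, size=n_global, replace=False))
    signs = rng.choice([-1.0, 1.0], size=n_global)
    mags = params.global_effect_min + np.abs(
        rng.normal(0.0, params.global_effect_sd, size=n_global)
    )
    global_delta = signs * mags
    eta = rng.uniform(params.eta_range[0], params.eta_range[1], size=len(individuals))
    b = rng.normal(0.0, params.sigma_bio, size=(n_probes, len(individuals)))
    zeta = rng.normal(0.0, params.array_scale_sd, size=len(arrays))
    eps = rng.normal(0.0, params.sigma_tech, size=(n_probes, len(arrays)))

    # per (gene, individual) treatment effect
    delta_gi = np.zeros((n_genes, len(individuals)))
    delta_gi[global_idx, :] = global_delta[:, None]
    for p in params.planted:
        j = gene_index[p.gene]
        for c in p.carriers:
            delta_gi[j, ind_index[c]] = eta[ind_index[c]] * p.log2_fold
    if params.positive_control_gene is not None:
        j = gene_index[params.positive_control_gene]
        ctl = df.loc[df["status"] == "control", "individual_id"].unique()
        for c in ctl:
            delta_gi[j, ind_index[c]] = math.log2(params.positive_control_fold)

    delta_probe_ind = delta_gi[gene_of_probe, :]  # probes x individuals
    y = (
        mu[:, None]
        + b[:, array_ind]
        + delta_probe_ind[:, array_ind] * array_treated[None, :]
        + eps
    )
    raw = np.exp2(y + zeta[None, :])

    data = pd.DataFrame(raw, index=pd.Index(probe_ids, name="ProbeID"), columns=arrays)
    gene_series = pd.Series(
        [genes[j] for j in gene_of_probe], index=data.index
    )
    matrix = ExpressionMatrix(data, gene_series, "raw")

    truth = SimTruth(
        global_effects={genes[j]: float(d) for j, d in zip(global_idx, global_delta)},
        planted=list(params.planted),
        eta={ind: float(e) for ind, e in zip(individuals, eta)},
        array_log2_scale={a: float(z) for a, z in zip(arrays, zeta)},
        positive_control=(
            (params.positive_control_gene, params.positive_control_fold)
            if params.positive_control_gene
            else None
        ),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Ct simulation
# ---------------------------------------------------------------------------

_CT_TARGET_BASE = 24.0
_CT_REF_BASE = 20.0


def simulate_ct(
    individuals: Iterable[str],
    target_folds: dict[str, float],
    params: SimParams,
    gene: str = "target",
) -> list[CtRecord]:
    """Simulate replicate Ct values for a qPCR validation run.

    For each individual the target's treated mean Ct sits
    ``log2(fold)`` cycles below its untreated mean (one fold doubling =
    one cycle earlier); the reference gene is treatment-independent.
    Gaussian noise of sd ``params.ct_noise_sd`` is added per replicate.
    """
    rng = np.random.default_rng(params.seed)
    records: list[CtRecord] = []
    for ind in individuals:
        fold = target_folds[ind]
        if fold <= 0:
            raise ValidationError(f"individual {ind!r}: fold must be positive")
        means = {
            ("target", "untreated"): _CT_TARGET_BASE,
            ("target", "caffeine"): _CT_TARGET_BASE - math.log2(fold),
            ("reference", "untreated"): _CT_REF_BASE,
            ("reference", "caffeine"): _CT_REF_BASE,
        }
        for (role, trt), m in means.items():
            cts = m + rng.normal(0.0, params.ct_noise_sd, size=params.ct_replicates)
            records.append(
                CtRecord(
                    individual_id=ind,
                    role=role,
                    treatment=trt,
                    cts=tuple(float(c) for c in cts),
                    gene=gene if role == "target" else "reference",
                )
            )
    return records
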