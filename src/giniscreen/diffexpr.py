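"""Gene-wise linear model with empirical-Bayes variance moderation.

For one individual the contrast is caffeine-treated minus untreated over n
technical replicate pairs, fitted per probe as a two-group comparison:

    beta_g   = mean(treated) - mean(untreated)        (log2 fold change)
    s2_g     = pooled within-group variance, d_g = 2n - 2 df
    v_g      = 2/n  (unscaled variance of beta_g, i.e. var = v_g * sigma_g^2)

Gene-wise variances are then shrunk toward a common prior: assuming
sigma_g^2 follows a scaled inverse chi-square prior with d0 degrees of
freedom and scale s0^2, the posterior variance is

    s2_post = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)

and the moderated t-statistic beta / (sqrt(s2_post * v_g)) follows a
Student-t distribution with d0 + d_g degrees of freedom under the null.
(d0, s0^2) are estimated from the marginal distribution of the log sample
variances via the digamma/trigamma moment equations; the B-statistic is the
log posterior odds of differential expression under a two-component mixture
with prior DE probability p1 and prior variance v0 (unscaled) for the true
effect of a DE gene.

The moderated statistics are authored here; Benjamini-Hochberg adjustment
delegates to statsmodels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix, SampleSheet, ValidationError

__all__ = [
    "EBayesHyper",
    "fit_contrast",
    "pooled_contrast_fit",
    "estimate_hyperparams",
    "trigamma_inverse",
    "estimate_v0",
    "moderate",
    "ebayes",
    "bh_adjust",
    "write_contrast",
]

logger = logging.getLogger(__name__)

#: cap for the prior degrees of freedom when the trigamma equation has no
#: positive solution (no excess variability between gene variances)
D0_CAP = 1e6

#: bounds for sqrt(v0 * s0^2), the prior sd of a true log2 fold change
V0_SD_LIM = (0.1, 4.0)

FIT_COLUMNS = ["gene", "logFC", "AveExpr", "s2", "df_resid", "v_unscaled"]


@dataclass
class EBayesHyper:
    """Empirical-Bayes hyperparameters.

    d0, s02 : prior degrees of freedom and prior variance of the gene-wise
        variance distribution. p1 : prior probability that a gene is
        differentially expressed. v0 : unscaled prior variance of the true
        log2 fold change of a DE gene; ``None`` means "estimate from the
        moderated t-statistics".
    """

    d0: float
    s02: float
    p1: float = 0.01
    v0: float | None = None

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ValidationError("d0 must be positive")
        if self.s02 <= 0:
            raise ValidationError("s0^2 must be positive")
        if not 0 < self.p1 < 1:
            raise ValidationError("p1 must be in (0, 1)")
        if self.v0 is not None and self.v0 < 0:
            raise ValidationError("v0 must be non-negative")


# ---------------------------------------------------------------------------
# per-gene linear model fits
# ---------------------------------------------------------------------------


def _two_group_fit(
    genes: pd.Series, treated: np.ndarray, untreated: np.ndarray
) -> pd.DataFrame:
    """Vectorised two-group fit; rows are probes, columns replicate arrays."""
    n_t, n_u = treated.shape[1], untreated.shape[1]
    beta = treated.mean(axis=1) - untreated.mean(axis=1)
    ave = np.hstack([treated, untreated]).mean(axis=1)
    ss = treated.var(axis=1, ddof=1) * (n_t - 1) + untreated.var(axis=1, ddof=1) * (
        n_u - 1
    )
    df_resid = n_t + n_u - 2
    s2 = ss / df_resid
    v = 1.0 / n_t + 1.0 / n_u
    return pd.DataFrame(
        {
            "gene": genes.to_numpy(),
            "logFC": beta,
            "AveExpr": ave,
            "s2": s2,
            "df_resid": float(df_resid),
            "v_unscaled": v,
        },
        index=genes.index,
    )


def fit_contrast(
    matrix: ExpressionMatrix, sheet: SampleSheet, individual: str
) -> pd.DataFrame:
    """Per-probe treated-vs-untreated fit for one individual.

    Returns a DataFrame indexed by probe with columns
    ``gene, logFC, AveExpr, s2, df_resid, v_unscaled``. Requires a log2
    matrix and at least two replicate pairs (otherwise there are no
    residual degrees of freedom).
    """
    if matrix.scale != "log2":
        raise ValidationError("fit_contrast expects a log2 matrix")
    t_arrays = sheet.arrays_for(individual, "caffeine")
    u_arrays = sheet.arrays_for(individual, "untreated")
    if len(t_arrays) != len(u_arrays):
        raise ValidationError(
            f"individual {individual!r}: unbalanced treated/untreated arrays"
        )
    n = len(t_arrays)
    if n < 2:
        raise ValidationError(
            f"individual {individual!r} has {n} replicate pair(s); need >= 2"
        )
    treated = matrix.subset_arrays(t_arrays).data.to_numpy(dtype=float)
    untreated = matrix.subset_arrays(u_arrays).data.to_numpy(dtype=float)
    return _two_group_fit(matrix.genes, treated, untreated)


def pooled_contrast_fit(matrix: ExpressionMatrix, sheet: SampleSheet) -> pd.DataFrame:
    """Unpaired all-treated vs all-untreated fit across every array.

    This is the "global caffeine response" contrast: pairing by individual
    is ignored, d_g = N_T + N_U - 2 and v_g = 1/N_T + 1/N_U.
    """
    if matrix.scale != "log2":
        raise ValidationError("pooled_contrast_fit expects a log2 matrix")
    df = sheet.data
    t_arrays = list(df.loc[df["treatment"] == "caffeine", "array_id"])
    u_arrays = list(df.loc[df["treatment"] == "untreated", "array_id"])
    if len(t_arrays) < 2 or len(u_arrays) < 2:
        raise ValidationError("pooled contrast needs >= 2 arrays per condition")
    treated = matrix.subset_arrays(t_arrays).data.to_numpy(dtype=float)
    untreated = matrix.subset_arrays(u_arrays).data.to_numpy(dtype=float)
    return _two_group_fit(matrix.genes, treated, untreated)


# ---------------------------------------------------------------------------
# hyperparameter estimation
# ---------------------------------------------------------------------------


def trigamma_inverse(y: float | np.ndarray) -> float | np.ndarray:
    """Solve trigamma(x) = y for x > 0 by Newton iteration (tol 1e-8).

    trigamma is strictly decreasing on (0, inf) with range (0, inf), so a
    unique solution exists for any y > 0. Very small y maps to large x;
    values implying x above the d0 cap are truncated by the caller.
    """
    y_arr = np.atleast_1d(np.asarray(y, dtype=float))
    if (y_arr <= 0).any():
        raise ValidationError("trigamma_inverse requires y > 0")
    # initial guess from the large-x asymptote trigamma(x) ~ 1/x + 1/(2x^2)
    x = 0.5 + 1.0 / y_arr
    for _ in range(100):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y_arr) / special.polygamma(2, x)
        x = x + dif
        if np.max(-dif / x) < 1e-10:
            break
    return x if np.ndim(y) else float(x[0])


def estimate_hyperparams(fits: pd.DataFrame) -> tuple[float, float]:
    """Estimate (d0, s0^2) from gene-wise sample variances.

    Uses the moment equations of log s2 under the scaled-F marginal: with
    e_g = log s2_g - digamma(d_g/2) + log(d_g/2),

        mean(e)  = log s0^2 + digamma(d0/2) - log(d0/2)
        var(e)   = trigamma(d0/2) + mean trigamma(d_g/2)

    solved for d0 by trigamma inversion (Newton, tol 1e-8). Genes with zero
    sample variance carry no information about the variance distribution
    and are excluded. If the between-gene spread does not exceed the
    sampling spread, d0 is capped at 1e6 (effectively infinite shrinkage).
    """
    ok = fits["s2"].to_numpy() > 0
    s2 = fits.loc[ok, "s2"].to_numpy(dtype=float)
    dg = fits.loc[ok, "df_resid"].to_numpy(dtype=float)
    if len(s2) < 2:
        raise ValidationError("need >= 2 genes with positive variance")
    e = np.log(s2) - special.digamma(dg / 2.0) + np.log(dg / 2.0)
    excess = e.var(ddof=1) - special.polygamma(1, dg / 2.0).mean()
    if excess > 0:
        d0 = 2.0 * trigamma_inverse(excess)
        d0 = min(d0, D0_CAP)
    else:
        d0 = D0_CAP
    s02 = math.exp(e.mean() + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return float(d0), float(s02)


def estimate_v0(
    t: np.ndarray,
    v_unscaled: np.ndarray,
    df_total: np.ndarray,
    hyper: EBayesHyper,
) -> float:
    """Moment-match the prior effect variance v0 from the largest |t| values.

    The top ceil(p1 * G) moderated t^2 values are assumed to come from DE
    genes; for the i-th largest, the matching two-sided upper-tail
    Student-t quantile q_i at its df gives a candidate
    v0_i = v_g * max(0, t_i^2 / q_i^2 - 1), and v0 is their mean, clamped
    so that sqrt(v0 * s0^2) stays within 0.1..4 log2 units. With fewer
    than 1/p1 genes a diffuse fallback v0 = 4 * mean(v_g) is used.
    """
    t = np.asarray(t, dtype=float)
    v_unscaled = np.asarray(v_unscaled, dtype=float)
    df_total = np.asarray(df_total, dtype=float)
    G = len(t)
    r = math.ceil(hyper.p1 * G)
    lo, hi = (V0_SD_LIM[0] ** 2 / hyper.s02, V0_SD_LIM[1] ** 2 / hyper.s02)
    if G < 1.0 / hyper.p1:
        logger.warning(
            "estimate_v0: only %d genes (< 1/p1); using diffuse fallback", G
        )
        return float(np.clip(4.0 * v_unscaled.mean(), lo, hi))
    t2 = t**2
    top = np.argsort(-t2, kind="stable")[:r]
    ranks = np.arange(1, r + 1)
    # rank-i |t| among G corresponds to two-sided tail probability (i-0.5)/G
    q = stats.t.isf((ranks - 0.5) / (2.0 * G), df_total[top])
    cand = v_unscaled[top] * np.maximum(0.0, t2[top] / q**2 - 1.0)
    return float(np.clip(cand.mean(), lo, hi))


# ---------------------------------------------------------------------------
# moderation
# ---------------------------------------------------------------------------


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def moderate(fits: pd.DataFrame, hyper: EBayesHyper) -> pd.DataFrame:
    """Apply empirical-Bayes moderation to a per-gene fit table.

    Returns the fit columns plus ``s2_post, t, df_total, P.Value,
    adj.P.Val, B``. If ``hyper.v0`` is None it is estimated from the
    moderated t-statistics before computing B.
    """
    d0, s02 = hyper.d0, hyper.s02
    s2 = fits["s2"].to_numpy(dtype=float)
    dg = fits["df_resid"].to_numpy(dtype=float)
    beta = fits["logFC"].to_numpy(dtype=float)
    v = fits["v_unscaled"].to_numpy(dtype=float)

    if (s2 == 0).any():
        logger.info(
            "moderate: %d gene(s) with zero sample variance shrunk to the prior",
            int((s2 == 0).sum()),
        )
    s2_post = (d0 * s02 + dg * s2) / (d0 + dg)
    df_total = d0 + dg
    t = beta / np.sqrt(s2_post * v)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    adj = bh_adjust(p)

    v0 = hyper.v0
    if v0 is None:
        v0 = estimate_v0(t, v, np.broadcast_to(df_total, t.shape), hyper)

    # log posterior odds of differential expression
    shrink = v / (v + v0)
    odds = (
        math.log(hyper.p1 / (1.0 - hyper.p1))
        + 0.5 * np.log(shrink)
        + ((1.0 + df_total) / 2.0)
        * np.log((t**2 + df_total) / (t**2 * shrink + df_total))
    )

    out = fits.copy()
    out["s2_post"] = s2_post
    out["t"] = t
    out["df_total"] = df_total
    out["P.Value"] = p
    out["adj.P.Val"] = adj
    out["B"] = odds
    out.attrs["hyper"] = EBayesHyper(d0=d0, s02=s02, p1=hyper.p1, v0=v0)
    return out


def ebayes(fits: pd.DataFrame, p1: float = 0.01, v0: float | None = None) -> pd.DataFrame:
    """Convenience: estimate hyperparameters then moderate.

    Synthetic noise-free data can make every sample variance zero; the
    hierarchy is then degenerate and a tiny fixed prior variance is used so
    the statistics stay defined (true effects get arbitrarily large t,
    exact-null genes get t = 0).
    """
    try:
        d0, s02 = estimate_hyperparams(fits)
    except ValidationError:
        logger.warning(
            "all gene variances are zero; falling back to a degenerate prior"
        )
        d0, s02 = D0_CAP, 1e-8
    return moderate(fits, EBayesHyper(d0=d0, s02=s02, p1=p1, v0=v0))


def write_contrast(result: pd.DataFrame, path: str | Path) -> None:
    """Write a moderated contrast as TSV in the conventional topTable layout."""
    cols = ["gene", "logFC", "AveExpr", "t", "P.Value", "adj.P.Val", "B"]
    out = result[cols].rename(columns={"gene": "Symbol"})
    out.index.name = "ProbeID"
    out.to_csv(path, sep="\t", lineterminator="\n", encoding="utf-8")
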