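"""Family-level candidate selection from per-individual contrasts.

A gene is a candidate PTC carrier gene for a family when it is
significantly up-regulated after caffeine in the family's affected
members (all of them under the default policy), NOT differentially
expressed in any direction in the unaffected members of the exclusion
scope, and NOT part of the global caffeine response (genes responding to
treatment in everyone, which cannot carry a family-specific truncating
mutation).

Significance throughout means BH-adjusted p below alpha, optionally with
a positive B-statistic (posterior probability of differential expression
above 50%). Testing is per probe; candidate logic is per gene, using each
gene's best probe (smallest adjusted p, ties broken by larger |log2FC|,
then lexicographic probe id).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, SampleSheet, ScreenPolicy, ValidationError
from .diffexpr import ebayes, pooled_contrast_fit

__all__ = [
    "CandidateRecord",
    "gene_level",
    "significant_set",
    "global_response",
    "select_family_candidates",
    "summarize_candidates",
    "write_candidates",
]


@dataclass
class CandidateRecord:
    """One family x gene candidate (or exclusion) with per-individual evidence."""

    family_id: str
    gene: str
    n_affected_significant: int
    max_adj_p: float
    min_abs_log2fc: float
    min_B: float
    excluded_by: str  # none | unaffected_hit | global_response
    evidence: pd.DataFrame = field(repr=False)  # per individual: logFC, adj.P.Val, B, significant

    @property
    def fold_change(self) -> float:
        """Smallest fold change across affected members (conservative report)."""
        return float(2.0 ** self.min_abs_log2fc)


def gene_level(result: pd.DataFrame) -> pd.DataFrame:
    """Collapse a per-probe contrast to genes via each gene's best probe.

    Best = minimum adjusted p, ties by larger |logFC|, then lexicographic
    probe id. Returns a DataFrame indexed by gene with the winning probe's
    statistics and a ``probe`` column.
    """
    df = result.copy()
    df["probe"] = df.index
    df["_abs_fc"] = df["logFC"].abs()
    df = df.sort_values(
        ["adj.P.Val", "_abs_fc", "probe"],
        ascending=[True, False, True],
        kind="stable",
    )
    best = df.drop_duplicates("gene").set_index("gene").drop(columns="_abs_fc")
    return best.sort_index()


def significant_set(result: pd.DataFrame, policy: ScreenPolicy) -> pd.DataFrame:
    """Gene-level table of significant genes with direction labels.

    A gene is significant when its best probe has adj_p < alpha, B > 0 if
    the policy requires it, and (for direction="up") a positive log2 fold
    change. The returned frame is indexed by gene with a ``direction``
    column ("up"/"down"); an empty result is legitimate.
    """
    best = gene_level(result)
    keep = best["adj.P.Val"] < policy.alpha
    if policy.require_positive_B:
        keep &= best["B"] > 0
    if policy.direction == "up":
        keep &= best["logFC"] > 0
    out = best.loc[keep].copy()
    out["direction"] = np.where(out["logFC"] > 0, "up", "down")
    return out


def global_response(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    policy: ScreenPolicy,
    p1: float = 0.01,
) -> tuple[pd.DataFrame, dict[float, int]]:
    """The global caffeine response: one pooled treated-vs-untreated contrast.

    All arrays are pooled regardless of individual or family (pairing
    ignored), moderated, and thresholded with direction="any" — caffeine
    can push a transcript either way. Also reports, for each fold
    threshold in the policy, how many significant genes changed at least
    that much (on the absolute fold scale).
    """
    fits = pooled_contrast_fit(matrix, sheet)
    result = ebayes(fits, p1=p1)
    any_dir = ScreenPolicy(
        alpha=policy.alpha,
        require_positive_B=policy.require_positive_B,
        direction="any",
        fold_report_thresholds=policy.fold_report_thresholds,
    )
    sig = significant_set(result, any_dir)
    abs_fold = 2.0 ** sig["logFC"].abs()
    counts = {
        thr: int((abs_fold >= thr).sum()) for thr in policy.fold_report_thresholds
    }
    return sig, counts


def _scope_unaffected(
    sheet: SampleSheet, family_id: str, policy: ScreenPolicy
) -> list[str]:
    if policy.unaffected_exclusion == "same_family":
        return sheet.family_members(family_id, "unaffected")
    return sorted(
        sheet.data.loc[
            sheet.data["status"] == "unaffected", "individual_id"
        ].unique()
    )


def select_family_candidates(
    per_individual: dict[str, pd.DataFrame],
    sheet: SampleSheet,
    family_id: str,
    global_set: set[str] | pd.DataFrame,
    policy: ScreenPolicy,
) -> list[CandidateRecord]:
    """Apply the family selection logic and return candidates + exclusions.

    ``per_individual`` maps individual id -> moderated per-probe contrast.
    Genes passing the affected rule are returned as records; those hit in
    an unaffected member or in the global set keep ``excluded_by`` labels
    so reports can show why a gene fell out. Candidates have
    ``excluded_by == "none"``.
    """
    affected = sheet.family_members(family_id, "affected")
    if not affected:
        raise ValidationError(f"family {family_id!r} has no affected members")
    unaffected = _scope_unaffected(sheet, family_id, policy)
    for ind in affected + sheet.family_members(family_id, "unaffected"):
        if ind not in per_individual:
            raise ValidationError(f"no contrast result for individual {ind!r}")

    if isinstance(global_set, pd.DataFrame):
        global_genes = set(global_set.index)
    else:
        global_genes = set(global_set)

    sig_up = {ind: significant_set(per_individual[ind], policy) for ind in affected}
    any_dir_policy = ScreenPolicy(
        alpha=policy.alpha,
        require_positive_B=policy.require_positive_B,
        direction="any",
    )
    sig_any: dict[str, set[str]] = {}
    for ind in unaffected:
        if ind not in per_individual:
            raise ValidationError(f"no contrast result for individual {ind!r}")
        sig_any[ind] = set(significant_set(per_individual[ind], any_dir_policy).index)
    sig_any_unaff: set[str] = set().union(*sig_any.values()) if sig_any else set()

    hit_counts: dict[str, int] = {}
    for ind in affected:
        for gene in sig_up[ind].index:
            hit_counts[gene] = hit_counts.get(gene, 0) + 1
    need = len(affected) if policy.affected_rule == "all" else policy.k
    passing = sorted(g for g, c in hit_counts.items() if c >= need)

    gene_tables = {ind: gene_level(per_individual[ind]) for ind in set(affected) | set(unaffected)}
    records = []
    for gene in passing:
        if gene in sig_any_unaff:
            excluded = "unaffected_hit"
        elif gene in global_genes:
            excluded = "global_response"
        else:
            excluded = "none"
        rows = []
        for ind in affected + [u for u in unaffected if u not in affected]:
            tab = gene_tables[ind]
            if gene in tab.index:
                r = tab.loc[gene]
                is_aff = ind in affected
                hit = gene in (sig_up[ind].index if is_aff else sig_any[ind])
                rows.append(
                    {
                        "individual_id": ind,
                        "status": sheet.status_of(ind),
                        "logFC": float(r["logFC"]),
                        "adj.P.Val": float(r["adj.P.Val"]),
                        "B": float(r["B"]),
                        "significant": hit,
                    }
                )
        evidence = pd.DataFrame(rows)
        aff_rows = evidence[evidence["individual_id"].isin(affected)]
        records.append(
            CandidateRecord(
                family_id=family_id,
                gene=gene,
                n_affected_significant=int(hit_counts[gene]),
                max_adj_p=float(aff_rows["adj.P.Val"].max()),
                min_abs_log2fc=float(aff_rows["logFC"].abs().min()),
                min_B=float(aff_rows["B"].min()),
                excluded_by=excluded,
                evidence=evidence,
            )
        )
    return records


def summarize_candidates(
    records: "list[CandidateRecord] | pd.DataFrame",
) -> dict:
    """Summarise candidate lists across families.

    Accepts either CandidateRecord lists (exclusions are dropped) or a
    DataFrame with ``family_id`` and ``gene`` columns (e.g. a published
    candidate table being replayed). Returns per-family counts, the
    distinct-gene count, and genes occurring in more than one family.
    """
    if isinstance(records, pd.DataFrame):
        df = records[["family_id", "gene"]].copy()
    else:
        df = pd.DataFrame(
            [
                {"family_id": r.family_id, "gene": r.gene}
                for r in records
                if r.excluded_by == "none"
            ],
            columns=["family_id", "gene"],
        )
    per_family = df.groupby("family_id")["gene"].nunique().to_dict()
    fam_per_gene = df.groupby("gene")["family_id"].nunique()
    multi = sorted(fam_per_gene[fam_per_gene > 1].index)
    return {
        "per_family": per_family,
        "n_candidates": int(len(df)),
        "n_distinct_genes": int(df["gene"].nunique()),
        "multi_family_genes": multi,
    }


def write_candidates(
    records: list[CandidateRecord], path: str | Path, include_excluded: bool = False
) -> None:
    """Write the candidate table as TSV (Family, Gene, fold, adj p, B).

    The reported fold change is the smallest across affected members, the
    adjusted p-value the largest — the weakest supporting evidence.
    """
    rows = []
    for r in sorted(records, key=lambda r: (r.family_id, r.gene)):
        if r.excluded_by != "none" and not include_excluded:
            continue
        rows.append(
            {
                "Family": r.family_id,
                "Gene": r.gene,
                "FoldChange": round(r.fold_change, 4),
                "AdjPValue": r.max_adj_p,
                "Bstatistic": round(r.min_B, 4),
                "NAffectedSignificant": r.n_affected_significant,
                "ExcludedBy": r.excluded_by,
            }
        )
    cols = [
        "Family",
        "Gene",
        "FoldChange",
        "AdjPValue",
        "Bstatistic",
        "NAffectedSignificant",
        "ExcludedBy",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )
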