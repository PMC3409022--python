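"""Significance rule, global response, family candidate selection."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

import giniscreen as g
from giniscreen.core import ValidationError
from giniscreen.published import reference_candidates


def _result_frame(rows: list[dict]) -> pd.DataFrame:
    """Build a moderated-contrast-like frame from per-probe dicts."""
    df = pd.DataFrame(rows)
    df.index = pd.Index(df.pop("probe"), name="ProbeID")
    for col, default in [("AveExpr", 7.0), ("s2", 0.02), ("df_resid", 4.0),
                         ("v_unscaled", 2 / 3), ("s2_post", 0.02),
                         ("t", 0.0), ("df_total", 8.0), ("P.Value", 0.5)]:
        if col not in df:
            df[col] = default
    return df


class TestSignificantSet:
    def test_reference_rows_all_pass_the_rule(self):
        """Every published family x gene call satisfies adj p < 0.05 and B > 0."""
        ref = reference_candidates()
        rows = [
            {
                "probe": f"p{i}",
                "gene": r["gene"],
                "logFC": math.log2(r["fold_change"]),
                "adj.P.Val": r["adj_p"],
                "B": r["B"],
            }
            for i, r in ref.iterrows()
        ]
        # one frame per family so the duplicated gene is collapsed per family
        for fam in ref["family_id"].unique():
            fam_rows = [row for row, (_, r) in zip(rows, ref.iterrows())
                        if r["family_id"] == fam]
            sig = g.significant_set(_result_frame(fam_rows), g.ScreenPolicy())
            assert len(sig) == len(fam_rows)
            assert (sig["direction"] == "up").all()

    def test_negative_b_excluded_when_required(self):
        frame = _result_frame(
            [{"probe": "p1", "gene": "X", "logFC": 0.5, "adj.P.Val": 0.04, "B": -0.2}]
        )
        assert len(g.significant_set(frame, g.ScreenPolicy())) == 0
        relaxed = g.ScreenPolicy(require_positive_B=False)
        assert list(g.significant_set(frame, relaxed).index) == ["X"]

    def test_direction_filter(self):
        frame = _result_frame(
            [{"probe": "p1", "gene": "X", "logFC": -0.5, "adj.P.Val": 0.001, "B": 2.0}]
        )
        assert len(g.significant_set(frame, g.ScreenPolicy(direction="up"))) == 0
        sig = g.significant_set(frame, g.ScreenPolicy(direction="any"))
        assert sig.loc["X", "direction"] == "down"

    def test_gene_collapse_prefers_min_adjp_then_larger_fold(self):
        frame = _result_frame(
            [
                {"probe": "pB", "gene": "X", "logFC": 0.2, "adj.P.Val": 0.01, "B": 1.0},
                {"probe": "pA", "gene": "X", "logFC": 0.9, "adj.P.Val": 0.02, "B": 1.5},
                {"probe": "pC", "gene": "Y", "logFC": 0.5, "adj.P.Val": 0.01, "B": 1.0},
                {"probe": "pD", "gene": "Y", "logFC": -0.5, "adj.P.Val": 0.01, "B": 1.0},
            ]
        )
        best = g.gene_level(frame)
        assert best.loc["X", "probe"] == "pB"  # smaller adj p wins
        # equal adj p and equal |logFC|: lexicographic probe id
        assert best.loc["Y", "probe"] == "pC"


class TestFamilySelection:
    def _per_individual(self):
        """Four genes x four individuals, brute-force enumerable.

        gene1 up in both affected only; gene2 up in one affected; gene3 up
        in everyone; gene4 up in both affected (but globally responsive).
        """
        sig = {"adj.P.Val": 0.001, "B": 3.0}
        null = {"adj.P.Val": 0.9, "B": -4.0}

        def frame(gene_states: dict[str, bool]):
            return _result_frame(
                [
                    {
                        "probe": f"p_{gene}",
                        "gene": gene,
                        "logFC": 0.6 if on else 0.01,
                        **(sig if on else null),
                    }
                    for gene, on in gene_states.items()
                ]
            )

        return {
            "F-A1": frame({"gene1": True, "gene2": True, "gene3": True, "gene4": True}),
            "F-A2": frame({"gene1": True, "gene2": False, "gene3": True, "gene4": True}),
            "F-U1": frame({"gene1": False, "gene2": False, "gene3": True, "gene4": False}),
            "F-U2": frame({"gene1": False, "gene2": False, "gene3": True, "gene4": False}),
        }

    def _sheet(self):
        return g.design_from_family_spec([("F", 2, 2)], 2)

    def test_toy_selection_matches_enumeration(self):
        records = g.select_family_candidates(
            self._per_individual(), self._sheet(), "F", {"gene4"}, g.ScreenPolicy()
        )
        by_gene = {r.gene: r for r in records}
        assert by_gene["gene1"].excluded_by == "none"
        assert "gene2" not in by_gene  # fails the all-affected rule
        assert by_gene["gene3"].excluded_by == "unaffected_hit"
        assert by_gene["gene4"].excluded_by == "global_response"
        candidates = [r.gene for r in records if r.excluded_by == "none"]
        assert candidates == ["gene1"]

    def test_at_least_k_rule_admits_partial_support(self):
        policy = g.ScreenPolicy(affected_rule="at_least_k", k=1)
        records = g.select_family_candidates(
            self._per_individual(), self._sheet(), "F", set(), policy
        )
        genes = {r.gene for r in records if r.excluded_by == "none"}
        assert "gene2" in genes

    def test_candidate_evidence_table_covers_family(self):
        records = g.select_family_candidates(
            self._per_individual(), self._sheet(), "F", set(), g.ScreenPolicy()
        )
        rec = next(r for r in records if r.gene == "gene1")
        assert set(rec.evidence["individual_id"]) == {"F-A1", "F-A2", "F-U1", "F-U2"}
        assert rec.n_affected_significant == 2

    def test_zero_affected_family_rejected(self):
        sheet = g.design_from_family_spec([("F", 0, 2)], 2)
        with pytest.raises(ValidationError, match="no affected"):
            g.select_family_candidates({}, sheet, "F", set(), g.ScreenPolicy())

    def test_no_significant_genes_gives_empty_list(self):
        null = _result_frame(
            [{"probe": "p1", "gene": "gene1", "logFC": 0.0, "adj.P.Val": 0.9, "B": -3.0}]
        )
        per = {ind: null for ind in ("F-A1", "F-A2", "F-U1", "F-U2")}
        records = g.select_family_candidates(
            per, self._sheet(), "F", set(), g.ScreenPolicy()
        )
        assert records == []


class TestGlobalResponse:
    def test_truth_recovery_with_strong_effects(self):
        """Operation-level truth oracle on log2 data (10 seeds)."""
        recalls, precisions = [], []
        sheet = g.design_from_family_spec([("A", 5, 3), ("B", 3, 4), ("C", 3, 6)], 3)
        for seed in range(10):
            p = g.SimParams(
                n_probes=2000, p_global=0.1, global_effect_min=0.5, seed=seed
            )
            matrix, truth = g.simulate_expression(sheet, p)
            normed = g.log2_transform(matrix)
            sig, _ = g.global_response(normed, sheet, g.ScreenPolicy())
            found, true = set(sig.index), set(truth.global_effects)
            recalls.append(len(found & true) / len(true))
            precisions.append(len(found & true) / max(len(found), 1))
        assert np.mean(recalls) >= 0.9
        assert np.mean(precisions) >= 0.9

    def test_null_global_set_is_near_empty(self):
        sheet = g.design_from_family_spec([("F", 3, 3)], 3)
        p = g.SimParams(n_probes=2000, p_global=0.0, seed=3)
        matrix, _ = g.simulate_expression(sheet, p)
        normed = g.log2_transform(g.quantile_normalize(matrix))
        sig, counts = g.global_response(normed, sheet, g.ScreenPolicy())
        assert len(sig) <= 5

    def test_fold_counts_partition_monotonically(self):
        sheet = g.design_from_family_spec([("F", 3, 3)], 3)
        p = g.SimParams(n_probes=2000, p_global=0.2, seed=6)
        matrix, _ = g.simulate_expression(sheet, p)
        normed = g.log2_transform(g.quantile_normalize(matrix))
        sig, counts = g.global_response(normed, sheet, g.ScreenPolicy())
        assert counts[2.0] <= counts[1.5] <= len(sig)

    def test_missing_condition_rejected(self, tiny_matrix):
        sheet = g.design_from_family_spec([("F", 1, 1)], 2)
        df = sheet.data[sheet.data["treatment"] == "caffeine"]
        logged = g.log2_transform(tiny_matrix)
        with pytest.raises(ValidationError):
            g.pooled_contrast_fit(logged, g.SampleSheet(df.assign(replicate=[1, 2, 1, 2])))


class TestScreenInvariants:
    def test_candidates_never_intersect_global_set(self, planted_run):
        sheet = planted_run["sheet"]
        sig, _ = g.global_response(planted_run["normed"], sheet, g.ScreenPolicy())
        records = g.select_family_candidates(
            planted_run["per_individual"], sheet, "F", sig, g.ScreenPolicy()
        )
        candidates = {r.gene for r in records if r.excluded_by == "none"}
        assert candidates.isdisjoint(set(sig.index))

    def test_tightening_alpha_shrinks_significant_sets(self, planted_run):
        result = planted_run["per_individual"]["F-A1"]
        previous = None
        for alpha in (0.2, 0.1, 0.05, 0.01):
            sig = set(g.significant_set(result, g.ScreenPolicy(alpha=alpha)).index)
            if previous is not None:
                assert sig.issubset(previous)
            previous = sig

    def test_label_swap_removes_planted_candidate(self, planted_run):
        sheet = planted_run["sheet"]
        swapped_df = sheet.data.copy()
        swapped_df["status"] = swapped_df["status"].map(
            {"affected": "unaffected", "unaffected": "affected"}
        )
        swapped = g.SampleSheet(swapped_df)
        for s, name in ((sheet, "original"), (swapped, "swapped")):
            records = g.select_family_candidates(
                planted_run["per_individual"], s, "F", set(), g.ScreenPolicy()
            )
            candidates = {r.gene for r in records if r.excluded_by == "none"}
            if name == "original":
                assert "GENE00010" in candidates
            else:
                assert "GENE00010" not in candidates


class TestSummarize:
    def test_reference_table_replay(self):
        summary = g.summarize_candidates(reference_candidates())
        assert summary["per_family"] == {"A": 2, "B": 2, "C": 5}
        assert summary["n_distinct_genes"] == 8
        assert summary["multi_family_genes"] == ["PPARGC1A"]

    def test_record_list_summary_skips_exclusions(self):
        ev = pd.DataFrame()
        records = [
            g.CandidateRecord("A", "X", 2, 0.01, 0.2, 1.0, "none", ev),
            g.CandidateRecord("A", "Y", 2, 0.01, 0.2, 1.0, "global_response", ev),
            g.CandidateRecord("B", "X", 2, 0.01, 0.2, 1.0, "none", ev),
        ]
        summary = g.summarize_candidates(records)
        assert summary["per_family"] == {"A": 1, "B": 1}
        assert summary["multi_family_genes"] == ["X"]
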