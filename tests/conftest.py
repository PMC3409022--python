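"""Shared fixtures: small simulated studies and deterministic hypothesis runs."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import giniscreen as g

settings.register_profile(
    "ci",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: the three-family study design: (family, n affected, n unaffected), 3 replicates
TABLE_FAMILIES = [("A", 5, 3), ("B", 3, 4), ("C", 3, 6)]


@pytest.fixture(scope="session")
def table_design() -> g.SampleSheet:
    return g.design_from_family_spec(TABLE_FAMILIES, 3)


@pytest.fixture(scope="session")
def one_family_design() -> g.SampleSheet:
    return g.design_from_family_spec([("F", 3, 3)], 3)


@pytest.fixture()
def tiny_matrix() -> g.ExpressionMatrix:
    """3 probes x 2 arrays raw matrix with gene symbols."""
    data = pd.DataFrame(
        [[4.0, 8.0], [2.0, 2.0], [1.0, 16.0]],
        index=pd.Index(["p1", "p2", "p3"], name="ProbeID"),
        columns=["a1", "a2"],
    )
    genes = pd.Series(["G1", "G1", "G2"], index=data.index)
    return g.ExpressionMatrix(data, genes, "raw")


@pytest.fixture(scope="session")
def planted_run() -> dict:
    """One simulated single-family run with a strongly planted gene.

    Uses a large stabilisation fold (log2 3) so that the selection logic
    itself — not detection power — is exercised.
    """
    sheet = g.design_from_family_spec([("F", 3, 3)], 3)
    carriers = tuple(sheet.family_members("F", "affected"))
    planted = g.PlantedGene("GENE00010", "F", math.log2(3.0), carriers)
    params = g.SimParams(n_probes=1000, planted=(planted,), seed=5)
    matrix, truth = g.simulate_expression(sheet, params)
    normed = g.log2_transform(g.quantile_normalize(matrix))
    per_individual = {
        ind: g.ebayes(g.fit_contrast(normed, sheet, ind))
        for ind in sheet.individuals
    }
    return {
        "sheet": sheet,
        "truth": truth,
        "normed": normed,
        "per_individual": per_individual,
        "planted": planted,
    }
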