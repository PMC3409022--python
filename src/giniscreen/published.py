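"""Reference values from the familial breast-cancer GINI screen this
package models.

These are inputs for replay and bookkeeping checks, not computed outputs:
the three family designs (affected/unaffected cell-line counts, three
technical replicates each), the published per-family candidate table
(fold change, BH-adjusted p-value and B-statistic for each family x gene
call), the positive-control statistics for the truncation-bearing SMAD4
colon-cancer cell line, and the size of the global caffeine response set.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = [
    "FAMILY_DESIGNS",
    "REPLICATES",
    "reference_candidates",
    "POSITIVE_CONTROL",
    "GLOBAL_RESPONSE_COUNTS",
]

#: family id -> (n affected LCLs, n unaffected LCLs)
FAMILY_DESIGNS: dict[str, tuple[int, int]] = {
    "A": (5, 3),
    "B": (3, 4),
    "C": (3, 6),
}

#: technical replicates per (individual, condition)
REPLICATES = 3

_CANDIDATES_TSV = """\
family_id\tgene\tfold_change\tadj_p\tB
A\tWNT5A\t1.14\t0.005560\t0.04
A\tRAB3B\t1.17\t0.004254\t0.33
B\tPPARGC1A\t1.19\t0.001226\t4.23
B\tCD14\t1.19\t0.001875\t1.19
C\tPPARGC1A\t1.41\t3.00E-11\t25.02
C\tMETRNL\t1.44\t0.001146\t2.51
C\tBMP6\t1.43\t3.61E-05\t6.67
C\tPRDM1\t1.25\t0.000314\t4.04
C\tGRSF1\t1.69\t0.007637\t0.23
"""


def reference_candidates() -> pd.DataFrame:
    """The published candidate table (one row per family x gene call)."""
    return pd.read_csv(io.StringIO(_CANDIDATES_TSV), sep="\t")


#: array statistics of the SMAD4 transcript in the HT29 positive control
#: (heterozygous-deletion truncation; fold realised without eta scaling),
#: and the fold range seen across replicate qPCR validations
POSITIVE_CONTROL = {
    "gene": "SMAD4",
    "fold": 2.78,
    "adj_p": 7.83e-07,
    "B": 12.94,
    "qpcr_fold_range": (2.5, 3.7),
}

#: size of the reported global caffeine response set and how many of those
#: genes changed more than 1.5- / 2-fold
GLOBAL_RESPONSE_COUNTS = {"total": 6520, 1.5: 1364, 2.0: 292}
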