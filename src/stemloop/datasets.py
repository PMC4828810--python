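"""Bundled reference tables.

Two published *Asparagus officinalis* miRNA tables ship with the package as
plain TSV: the novel-miRNA locus table (one row per precursor locus,
including one star entry) and the male/female differential-expression table
(printed TPM pairs, fold-change ratios, and log2 values). They serve as
fixed inputs for arithmetic and summary-statistics checks.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("stemloop.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def published_novel_loci() -> pd.DataFrame:
    """Published novel-miRNA locus table (39 miRNAs + 1 star, 47 locus rows)."""
    return _load("novel_loci_published.tsv")


def published_de_table() -> pd.DataFrame:
    """Published differential-expression table (63 miRNAs, female vs male)."""
    return _load("de_published.tsv")


# One printed row (aof-miR160b) is arithmetically inconsistent: the ratio of
# its printed TPMs (11.89/5.96 = 1.995) does not reproduce the printed ratio
# 1.943; it is excluded from recomputation checks.
INCONSISTENT_RATIO_ROWS = ("aof-miR160b",)

# Rows where log2 of the rounded and the unrounded ratio agree at 4 decimal
# places, so the printed log2 is unambiguous to recompute.
UNAMBIGUOUS_LOG2_ROWS = ("aof-miR160d",)
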