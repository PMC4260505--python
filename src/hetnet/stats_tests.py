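"""Supporting inferential statistics.

Two pieces of arithmetic back the analysis: a Pearson chi-squared
homogeneity test on class-by-disease-category count tables (are two gene
classes drawn from the same mix of physiological systems?) and
Benjamini-Hochberg false-discovery-rate adjustment for families of
enrichment p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["CategoryTable", "chisq_homogeneity", "bh_adjust"]


@dataclass
class CategoryTable:
    """Counts of genes per (class, disease category) cell."""

    row_names: list[str]
    col_names: list[str]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.row_names), len(self.col_names)):
            raise ValueError("counts shape does not match row/column names")
        if (self.counts < 0).any():
            raise ValueError("negative cell count")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CategoryTable":
        return cls(
            row_names=[str(r) for r in df.index],
            col_names=[str(c) for c in df.columns],
            counts=df.to_numpy(),
        )

    @classmethod
    def from_tsv(cls, path) -> "CategoryTable":
        return cls.from_dataframe(pd.read_csv(path, sep="\t", index_col=0))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_names, columns=self.col_names)


def chisq_homogeneity(table: CategoryTable, yates: bool = False):
    """Pearson chi-squared test of homogeneity across classes.

    Zero-total columns are dropped with a warning (they contribute no
    information and break the expected-count computation); a zero row
    margin is an error.  The Yates continuity correction applies to 2x2
    tables only and is off by default — the class-by-category tables here
    are wider than 2x2.

    Returns (statistic, degrees of freedom, p-value).
    """
    counts = np.asarray(table.counts, dtype=float)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("testing needs at least 2 rows and 2 columns")
    col_totals = counts.sum(axis=0)
    if (col_totals == 0).any():
        dropped = [c for c, t in zip(table.col_names, col_totals) if t == 0]
        logger.warning("dropping zero-total categories: %s", dropped)
        counts = counts[:, col_totals > 0]
        if counts.shape[1] < 2:
            raise ValueError("fewer than 2 non-empty categories remain")
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("a class (row) has zero total count")
    if yates and counts.shape != (2, 2):
        raise ValueError("Yates correction applies to 2x2 tables only")
    stat, p, dof, _ = chi2_contingency(counts, correction=yates)
    return float(stat), int(dof), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_i = min over ranks j >= rank(i) of (m * p_(j) / j), capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
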