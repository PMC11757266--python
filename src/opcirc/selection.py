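"""Dual-test FDR feature selection.

Each feature is screened univariately against the binary PLOS label
with a type-dependent test — two-sided Mann-Whitney U for real-valued
features, Fisher's exact test for binary ones — and the resulting
p-values are controlled at a false-discovery rate of q = 0.01 with the
Benjamini-Yekutieli step-up rule. Benjamini-Yekutieli (rather than
Benjamini-Hochberg) is used because feature columns extracted from the
same underlying series are strongly dependent, and BY controls the FDR
under arbitrary dependence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["SelectionResult", "fdr_select"]

DEFAULT_Q = 0.01


@dataclass
class SelectionResult:
    """Per-feature screening outcome at FDR level ``q``."""

    table: pd.DataFrame  # columns: pvalue, test, rejected, rank
    q: float

    @property
    def selected(self) -> list[str]:
        sel = self.table.index[self.table["rejected"]]
        return list(sel)

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def _is_binary(x: np.ndarray) -> bool:
    return len(np.unique(x[~np.isnan(x)])) <= 2


def _feature_pvalue(x: np.ndarray, y: np.ndarray) -> tuple[float, str]:
    """(p-value, test name) for one feature column against labels y."""
    if len(np.unique(x)) < 2:
        return 1.0, "constant"
    if _is_binary(x):
        hi = x == np.nanmax(x)
        tab = np.array(
            [
                [np.sum(hi & (y == 1)), np.sum(hi & (y == 0))],
                [np.sum(~hi & (y == 1)), np.sum(~hi & (y == 0))],
            ]
        )
        _, p = stats.fisher_exact(tab, alternative="two-sided")
        return float(p), "exact"
    res = stats.mannwhitneyu(x[y == 1], x[y == 0], alternative="two-sided")
    return float(res.pvalue), "rank-sum"


def fdr_select(
    features: pd.DataFrame, labels, q: float = DEFAULT_Q
) -> SelectionResult:
    """Screen features against a binary outcome with FDR control.

    Requires both classes present with at least 10 patients each.
    Constant features are assigned p = 1 and can never be selected.
    """
    y = np.asarray(labels, dtype=int)
    if len(y) != len(features):
        raise ValueError("labels and feature rows differ in length")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    if counts.min() < 10:
        raise ValueError(
            f"need >= 10 patients per class, got {dict(zip(classes, counts))}"
        )
    pvals, tests = [], []
    for col in features.columns:
        p, t = _feature_pvalue(features[col].to_numpy(dtype=float), y)
        pvals.append(p)
        tests.append(t)
    pvals = np.asarray(pvals)
    rejected, _, _, _ = multipletests(pvals, alpha=q, method="fdr_by")
    table = pd.DataFrame(
        {
            "pvalue": pvals,
            "test": tests,
            "rejected": rejected,
            "rank": stats.rankdata(pvals, method="ordinal").astype(int),
        },
        index=features.columns,
    )
    return SelectionResult(table=table, q=q)
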