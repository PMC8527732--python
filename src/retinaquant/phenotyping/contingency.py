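"""Contingency-table tests: exact 2x2 test and Pearson chi-squared.

The 2x2 exact p-value is computed by direct hypergeometric enumeration:
with margins fixed, every admissible table whose probability does not
exceed that of the observed table (within a small relative tolerance for
floating-point ties) contributes to the two-sided p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

_TIE_REL_TOL = 1.0 + 1e-7


@dataclass
class ContingencyResult:
    p_value: float
    method: str
    statistic: float | None = None


def _validate(table: np.ndarray) -> np.ndarray:
    table = np.asarray(table)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("table must be 2 x k with k >= 2")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        if np.any(table != np.floor(table)) or np.any(table < 0):
            raise ValueError("table entries must be non-negative integers")
        table = table.astype(int)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate margins: a row or column sums to zero")
    return table.astype(int)


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided exact p for a 2x2 table by hypergeometric enumeration."""
    table = _validate(table)
    if table.shape != (2, 2):
        raise ValueError("exact test requires a 2x2 table")
    a = table[0, 0]
    row1 = int(table[0].sum())
    col1 = int(table[:, 0].sum())
    total = int(table.sum())
    support = np.arange(max(0, row1 + col1 - total), min(row1, col1) + 1)
    pmf = stats.hypergeom.pmf(support, total, col1, row1)
    p_obs = pmf[support == a][0]
    return float(min(pmf[pmf <= p_obs * _TIE_REL_TOL].sum(), 1.0))


def chi2_test(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared (no continuity correction); returns (stat, p)."""
    table = _validate(table)
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def compare_proportions(table: np.ndarray, method: str = "auto") -> ContingencyResult:
    """Test homogeneity of proportions across the columns of a 2 x k table.

    ``auto`` uses the exact test for 2x2 tables (sparse cells are the rule
    in prevalence tables) and Pearson chi-squared for k > 2; ``fisher`` and
    ``chi2`` force a method.
    """
    table = _validate(table)
    if method not in ("auto", "fisher", "chi2"):
        raise ValueError("method must be auto, fisher or chi2")
    if method == "fisher" or (method == "auto" and table.shape == (2, 2)):
        return ContingencyResult(p_value=fisher_exact_2x2(table), method="fisher")
    stat, p = chi2_test(table)
    return ContingencyResult(p_value=p, method="chi2", statistic=stat)
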