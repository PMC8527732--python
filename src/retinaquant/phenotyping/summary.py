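"""Prevalence summary tables (flag rows x group columns, with p-values)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .contingency import compare_proportions
from .prevalence import prevalence_with_ci
from .types import COMPONENT_DEFINITIONS, COMPOSITE_DEFINITIONS

FLAG_ROWS: tuple[str, ...] = tuple(COMPONENT_DEFINITIONS) + tuple(COMPOSITE_DEFINITIONS)


def prevalence_table(flags: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-group prevalence of every flag plus a between-group p-value.

    ``flags`` holds 0/1 flag columns; ``groups`` is an aligned categorical
    series.  For each flag the output has, per group, ``<g>_count`` and a
    formatted ``<g>_pct_ci`` cell, plus the homogeneity test p-value (exact
    for two groups, chi-squared otherwise); the p-value is NaN when no eye
    in any group carries the flag.
    """
    if len(flags) != len(groups):
        raise ValueError("flags and groups must be aligned")
    group_levels = list(pd.unique(groups))
    rows = []
    for flag in FLAG_ROWS:
        if flag not in flags.columns:
            continue
        row: dict[str, object] = {"flag": flag}
        counts, sizes = [], []
        for g in group_levels:
            sub = flags.loc[np.asarray(groups == g), flag]
            count, n = int(sub.sum()), int(len(sub))
            ci = prevalence_with_ci(count, n)
            row[f"{g}_count"] = count
            row[f"{g}_n"] = n
            row[f"{g}_pct_ci"] = f"{ci.percent:.1f} ({ci.lower:.1f}-{ci.upper:.1f})"
            counts.append(count)
            sizes.append(n)
        table = np.array([counts, [n - c for c, n in zip(counts, sizes)]])
        if table[0].sum() == 0 or np.any(table.sum(axis=0) == 0):
            row["p_value"] = np.nan
            row["test"] = "NA"
        else:
            res = compare_proportions(table)
            row["p_value"] = round(res.p_value, 3)
            row["test"] = res.method
        rows.append(row)
    return pd.DataFrame(rows).set_index("flag")
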