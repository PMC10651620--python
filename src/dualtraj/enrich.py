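"""Competitive enrichment of metabolite classes among screening results.

For each Biocrates-style class, a one-sided Wilcoxon rank-sum (Mann–Whitney)
test asks whether the class's metabolites have systematically smaller
screening p-values than the rest of the panel.  The null distribution is
exact for classes of up to ``exact_max`` members and a tie-corrected normal
approximation beyond that.  Classes smaller than ``min_size`` (singletons by
default) cannot be tested competitively and are reported as not estimable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["enrich_classes"]


def enrich_classes(
    screen_table: pd.DataFrame,
    class_map: pd.Series | dict,
    min_size: int = 2,
    p_column: str = "p_omnibus",
    exact_max: int = 10,
) -> pd.DataFrame:
    """Rank-sum class enrichment on a screening table.

    ``class_map`` maps every metabolite in ``screen_table`` to exactly one
    class.  Returns one row per class sorted by enrichment p-value, with
    not-estimable classes (size < ``min_size``, or no out-group) flagged in
    the ``status`` column.
    """
    cm = pd.Series(class_map)
    tab = screen_table.dropna(subset=[p_column])
    unmapped = [m for m in tab["metabolite"] if m not in cm.index]
    if unmapped:
        raise KeyError(f"metabolites missing from class map: {unmapped[:5]}")
    pvals = tab.set_index("metabolite")[p_column]
    classes = cm.reindex(pvals.index)

    rows = []
    for cls, members in classes.groupby(classes):
        in_p = pvals[members.index].to_numpy()
        out_p = pvals[~pvals.index.isin(members.index)].to_numpy()
        size = len(in_p)
        if size < min_size:
            rows.append({"class": cls, "size": size, "statistic": np.nan,
                         "p_value": np.nan, "status": "not estimable"})
            continue
        if len(out_p) == 0:
            # degenerate: no out-group to compete against
            rows.append({"class": cls, "size": size, "statistic": np.nan,
                         "p_value": 1.0, "status": "no out-group"})
            continue
        method = "exact" if size <= exact_max and len(np.unique(pvals)) == len(pvals) else "asymptotic"
        res = stats.mannwhitneyu(in_p, out_p, alternative="less", method=method)
        rows.append({"class": cls, "size": size, "statistic": float(res.statistic),
                     "p_value": float(res.pvalue), "status": "ok"})
    out = pd.DataFrame(rows, columns=["class", "size", "statistic", "p_value", "status"])
    return out.sort_values("p_value", na_position="last").reset_index(drop=True)
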