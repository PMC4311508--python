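"""Tissue-specificity index and expressed-proportion summaries.

The panel covers 17 tissues: 16 from a public multi-tissue expression
compendium plus skin, where the skin column is the average RPKM of three
uninvolved-skin replicates.  The specificity index of gene g in tissue s is
T_s = RPKM_s / sum_t RPKM_t, so each defined gene's indices sum to one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

SKIN = "skin"


def average_skin_replicates(panel: pd.DataFrame, prefix: str = "skin_") -> pd.DataFrame:
    """Collapse replicate skin columns (``skin_*``) into one averaged column."""
    rep_cols = [c for c in panel.columns if c.startswith(prefix)]
    if not rep_cols:
        if SKIN in panel.columns:
            return panel.copy()
        raise ValueError("panel has no skin columns to average")
    out = panel.drop(columns=rep_cols).copy()
    out[SKIN] = panel[rep_cols].mean(axis=1)
    return out


def specificity_index(panel: pd.DataFrame) -> pd.DataFrame:
    """Row-normalized expression fractions T_s; all-zero genes become NaN."""
    if (panel.values < 0).any():
        raise ValueError("negative expression values in tissue panel")
    totals = panel.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ts = panel.div(totals, axis=0)
    ts[totals == 0] = np.nan
    return ts


def expressed_proportions(
    panel: pd.DataFrame, categories: pd.Series, threshold: float = 0.1
) -> pd.DataFrame:
    """Fraction of each category's genes expressed (RPKM >= threshold,
    inclusive) in each tissue."""
    common = panel.index.intersection(categories.index)
    expressed = panel.loc[common] >= threshold
    out = expressed.groupby(categories.loc[common]).mean()
    out.index.name = "category"
    return out


def high_specificity_subset(
    skin_ts: pd.Series, t_min: float = 0.4
) -> pd.Index:
    """Genes with skin specificity strictly above ``t_min``."""
    return skin_ts.index[skin_ts > t_min]


def compare_specificity(
    skin_ts: pd.Series, group_a: pd.Index, group_b: pd.Index
) -> tuple[float, float]:
    """One-sided Mann-Whitney U test that group_a has higher skin specificity.

    Undefined (NaN) indices are excluded.  Returns (U, p).
    """
    a = skin_ts.loc[skin_ts.index.intersection(group_a)].dropna()
    b = skin_ts.loc[skin_ts.index.intersection(group_b)].dropna()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group in specificity comparison")
    u, p = stats.mannwhitneyu(a, b, alternative="greater")
    return float(u), float(p)
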