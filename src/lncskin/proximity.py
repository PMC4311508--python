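"""Distances from gene starts to predicted regulatory elements.

Chromatin-state segmentations of nine cell lines provide strong-enhancer and
active-promoter elements.  For every gene we measure the distance from its
strand-aware start (TSS) to the closest element per cell line, then compare
the two ectodermally derived lines (NHEK, HMEC) against the other lines via
the relative distance D_ecto / D_average, where D_average is the mean
closest distance over the remaining eight lines.  lncRNAs within 5 kb of an
enhancer but not a promoter are called elncRNAs, and vice versa plncRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

STATE_LABELS = {
    "Strong_Enhancer": "enhancer",
    "Active_Promoter": "promoter",
}


@dataclass
class ElementTrack:
    """Sorted per-chromosome intervals of one element type in one cell line."""

    cell_line: str
    element: str  # 'enhancer' | 'promoter'
    intervals: dict[str, np.ndarray]  # chrom -> (n, 2) array of [start, end)

    @classmethod
    def from_bed(
        cls, bed: pd.DataFrame, cell_line: str, element: str,
        labels: dict[str, str] | None = None,
    ) -> "ElementTrack":
        labels = labels or STATE_LABELS
        keep = bed[bed["state"].map(labels) == element]
        ivs = {
            str(c): np.array(sorted(zip(g["start"], g["end"])), dtype=np.int64)
            for c, g in keep.groupby("chrom")
        }
        return cls(cell_line, element, ivs)


def nearest_element_distance(
    chrom: str, position: int, track: ElementTrack
) -> float:
    """bp from a point to the nearest element interval; NaN when the
    chromosome has no elements; 0 when the point is inside one."""
    arr = track.intervals.get(chrom)
    if arr is None or len(arr) == 0:
        return float("nan")
    starts, ends = arr[:, 0], arr[:, 1]
    inside = (starts <= position) & (position < ends)
    if inside.any():
        return 0.0
    gaps = np.where(
        position < starts, starts - position, position - (ends - 1)
    )
    return float(gaps.min())


def gene_starts(table: pd.DataFrame, mode: str = "tss") -> pd.Series:
    """Per-gene start positions; ``tss`` is strand-aware, ``left`` is the
    smaller coordinate."""
    if mode == "left":
        return table["start"]
    if mode != "tss":
        raise ValueError("mode must be 'tss' or 'left'")
    return pd.Series(
        np.where(table["strand"] == "-", table["end"] - 1, table["start"]),
        index=table.index,
    )


def distance_table(
    table: pd.DataFrame, tracks: list[ElementTrack], mode: str = "tss"
) -> pd.DataFrame:
    """Genes x cell-lines closest distances for one element type."""
    starts = gene_starts(table, mode)
    out = {}
    for tr in tracks:
        out[tr.cell_line] = [
            nearest_element_distance(c, int(p), tr)
            for c, p in zip(table["chrom"], starts)
        ]
    return pd.DataFrame(out, index=table.index)


def relative_distance(
    dists: pd.DataFrame, ecto_cell: str
) -> pd.DataFrame:
    """Relative distance D_ecto/D_average of one ectodermal line against the rest.

    D_average is the mean closest distance over the other cell lines; the
    ratio is NaN (flagged undefined) when D_average is 0 or any input is
    missing.
    """
    others = [c for c in dists.columns if c != ecto_cell]
    d_ecto = dists[ecto_cell]
    d_avg = dists[others].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = d_ecto / d_avg
    rel[d_avg == 0] = np.nan
    return pd.DataFrame(
        {"D_ecto": d_ecto, "D_average": d_avg, "relative": rel}
    )


def iqr_trim(values: np.ndarray, k: float = 1.5) -> np.ndarray:
    """Drop values outside [Q1 - k*IQR, Q3 + k*IQR] (linear-interpolation
    quartiles)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return v
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return v[(v >= q1 - k * iqr) & (v <= q3 + k * iqr)]


def summarize_relative_distance(
    rel: pd.Series, categories: pd.Series
) -> pd.DataFrame:
    """Outlier-trimmed mean and standard error of relative distance per category."""
    rows = []
    common = rel.index.intersection(categories.index)
    for cat, ids in categories.loc[common].groupby(categories.loc[common]).groups.items():
        vals = iqr_trim(rel.loc[ids].values)
        n = len(vals)
        rows.append(
            {
                "category": cat,
                "n": n,
                "mean": float(vals.mean()) if n else np.nan,
                "se": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("category")


def classify_elnc_plnc(
    enhancer_dist: pd.Series, promoter_dist: pd.Series, window: float = 5000.0
) -> pd.Series:
    """elncRNA: enhancer within the window but no promoter; plncRNA converse;
    otherwise neither."""
    e_close = enhancer_dist < window
    p_close = promoter_dist < window
    out = pd.Series("neither", index=enhancer_dist.index, name="class")
    out[e_close & ~p_close] = "elncRNA"
    out[p_close & ~e_close] = "plncRNA"
    return out


def nearest_coding_neighbor(
    lnc_table: pd.DataFrame,
    coding_table: pd.DataFrame,
    max_distance: float | None = None,
    mode: str = "tss",
) -> pd.Series:
    """For each lncRNA, the id of the closest protein-coding gene by
    start-position distance on the same chromosome (optionally within
    ``max_distance`` bp)."""
    lnc_starts = gene_starts(lnc_table, mode)
    cod_starts = gene_starts(coding_table, mode)
    out = {}
    for lid in lnc_table.index:
        chrom = lnc_table.at[lid, "chrom"]
        cands = coding_table.index[coding_table["chrom"] == chrom]
        if len(cands) == 0:
            continue
        d = (cod_starts.loc[cands] - lnc_starts.loc[lid]).abs()
        best = d.idxmin()
        if max_distance is not None and d.loc[best] > max_distance:
            continue
        out[lid] = best
    return pd.Series(out, name="neighbor")


def neighbor_correlation(
    lnc_values: pd.Series, neighbor_values: pd.Series, pairs: pd.Series
) -> tuple[float, float]:
    """Spearman correlation between paired lncRNA and neighbor-gene values.

    ``pairs`` maps lncRNA id -> coding neighbor id; exact tie handling via
    average ranks.  Raises for fewer than 3 complete pairs.
    """
    xs, ys = [], []
    for lid, gid in pairs.items():
        if lid in lnc_values.index and gid in neighbor_values.index:
            x, y = lnc_values[lid], neighbor_values[gid]
            if np.isfinite(x) and np.isfinite(y):
                xs.append(x)
                ys.append(y)
    if len(xs) < 3:
        raise ValueError(f"insufficient pairs for correlation: {len(xs)}")
    rho, p = stats.spearmanr(xs, ys)
    return float(rho), float(p)
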