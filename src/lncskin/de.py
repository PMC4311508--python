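"""Count normalization, RPKM, and negative-binomial differential expression.

The differential-expression machinery follows the classic read-count model
for two-group RNA-seq comparisons: per-sample size factors by the
median-of-ratios estimator, per-gene dispersions by method of moments
shrunk toward a fitted mean-dispersion trend (taking the maximum of the
two, which is conservative), and an exact-style two-sided test comparing
the group sums under a negative-binomial null of equal concentrations.

Differential expression is declared at FDR <= 0.1 and |log2 fold change| >= 1
(both boundaries inclusive); cytokine-response calls use FDR <= 0.1 with
fold change > 2 (enhanced) or < 0.5 (repressed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

GROUPS = ("NN", "PN", "PP")

#: pseudocount (in normalized counts) added to group means before the log2 ratio
LOG2FC_PSEUDOCOUNT = 0.5


@dataclass
class CountsMatrix:
    """Genes x samples integer read counts with group labels and gene lengths."""

    counts: pd.DataFrame
    groups: pd.Series
    lengths: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)[:5]}")
        bad = set(self.groups.unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        missing_len = set(self.counts.index) - set(self.lengths.index)
        if missing_len:
            raise ValueError(f"genes without lengths: {sorted(missing_len)[:5]}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]

    def write(self, counts_path, groups_path, lengths_path=None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
        self.groups.rename("group").to_csv(groups_path, sep="\t", index_label="sample")
        if lengths_path is not None:
            self.lengths.rename("length").to_csv(
                lengths_path, sep="\t", index_label="gene_id"
            )

    @classmethod
    def read(cls, counts_path, groups_path, lengths_path) -> "CountsMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
        groups = pd.read_csv(groups_path, sep="\t", index_col="sample")["group"]
        lengths = pd.read_csv(lengths_path, sep="\t", index_col="gene_id")["length"]
        return cls(counts, groups, lengths)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    s_j = median_g k_gj / (prod_j k_gj)^(1/m), over genes with nonzero counts
    in every sample.  With ``pseudo_reference`` the geometric mean is taken
    over positive counts only, rescuing datasets where no gene is ubiquitous.
    """
    k = counts.values.astype(float)
    with np.errstate(divide="ignore"):
        logk = np.log(k)
    all_pos = np.isfinite(logk).all(axis=1)
    if all_pos.any():
        ref = logk[all_pos].mean(axis=1)
        ratios = logk[all_pos] - ref[:, None]
        sf = np.exp(np.median(ratios, axis=0))
    elif pseudo_reference:
        npos = np.isfinite(logk).sum(axis=1)
        usable = npos >= max(2, counts.shape[1] // 2)
        if not usable.any():
            raise ValueError("no genes with enough nonzero counts for normalization")
        ref = np.nanmean(np.where(np.isfinite(logk), logk, np.nan)[usable], axis=1)
        ratios = logk[usable] - ref[:, None]
        sf = np.exp(np.nanmedian(np.where(np.isfinite(ratios), ratios, np.nan), axis=0))
    else:
        raise ValueError(
            "no gene has nonzero counts in all samples; "
            "retry with pseudo_reference=True"
        )
    return pd.Series(sf, index=counts.columns, name="size_factor")


def rpkm(cm: CountsMatrix) -> pd.DataFrame:
    """Reads per kilobase of mature transcript per million mapped reads."""
    lengths = cm.lengths.loc[cm.counts.index].values.astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive for RPKM")
    libsize = cm.counts.values.sum(axis=0).astype(float)
    vals = cm.counts.values * 1e9 / (lengths[:, None] * libsize[None, :])
    return pd.DataFrame(vals, index=cm.counts.index, columns=cm.counts.columns)


def group_mean_rpkm(cm: CountsMatrix) -> pd.DataFrame:
    expr = rpkm(cm)
    return pd.DataFrame(
        {g: expr[cm.samples_in_group(g)].mean(axis=1) for g in GROUPS if cm.samples_in_group(g)}
    )


def coefficient_of_variation(expr: pd.DataFrame, samples: list[str]) -> pd.Series:
    """Per-gene sd/mean over the given samples; NaN where the mean is zero."""
    sub = expr[samples].values
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return pd.Series(cv, index=expr.index, name="cv")


# ---------------------------------------------------------------------------
# Dispersion estimation
# ---------------------------------------------------------------------------

def _moment_dispersions(
    norm: np.ndarray, inv_sf_mean: dict[str, float], group_cols: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-moments dispersion per gene, pooled over the two groups.

    For normalized counts x = K/s, Var(x) ~ q/s + alpha q^2, so
    alpha ~ (v - m * E[1/s]) / m^2 within each group.
    """
    alphas = np.zeros(norm.shape[0])
    weights = 0.0
    base_mean = np.zeros(norm.shape[0])
    total_n = 0
    for g, cols in group_cols.items():
        x = norm[:, cols]
        n = x.shape[1]
        m = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (v - m * inv_sf_mean[g]) / m**2, 0.0)
        alphas += (n - 1) * np.nan_to_num(a)
        weights += n - 1
        base_mean += n * m
        total_n += n
    return alphas / weights, base_mean / total_n


def _fit_dispersion_trend(means: np.ndarray, alphas: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of alpha(m) = a0 + a1/m with non-negative coefficients."""
    ok = (means > 0) & (alphas > 0)
    if ok.sum() < 10:
        a0 = float(np.clip(np.median(alphas[alphas > 0]) if (alphas > 0).any() else 0.01, 1e-6, None))
        return a0, 0.0
    A = np.column_stack([np.ones(ok.sum()), 1.0 / means[ok]])
    coef, _ = optimize.nnls(A, alphas[ok])
    return float(coef[0]), float(coef[1])


# ---------------------------------------------------------------------------
# The exact-style NB test
# ---------------------------------------------------------------------------

def _nb_logpmf(x: np.ndarray, mu: float, var: float) -> np.ndarray:
    if var <= mu * (1 + 1e-9):
        return stats.poisson.logpmf(x, mu)
    r = mu * mu / (var - mu)
    p = r / (r + mu)
    return stats.nbinom.logpmf(x, r, p)


def _exact_pvalue(
    kA: int, kB: int, muA: float, varA: float, muB: float, varB: float
) -> float:
    """Two-sided exact-style p: probability of splits of kA+kB at least as
    extreme (no more probable) than the observed one under equal concentrations."""
    total = kA + kB
    center = total * muA / (muA + muB)
    hw = 12.0 * np.sqrt(varA + varB) + 25.0
    lo = max(0, int(np.floor(center - hw)))
    hi = min(total, int(np.ceil(center + hw)))
    a = np.arange(lo, hi + 1)
    logp = _nb_logpmf(a, muA, varA) + _nb_logpmf(total - a, muB, varB)
    log_obs = _nb_logpmf(np.array([kA]), muA, varA)[0] + _nb_logpmf(
        np.array([kB]), muB, varB
    )[0]
    m = logp.max()
    probs = np.exp(logp - m)
    denom = probs.sum()
    num = probs[logp <= log_obs + 1e-8].sum()
    if denom <= 0:
        return 1.0
    return float(min(1.0, num / denom))


def nb_test(
    cm: CountsMatrix,
    group_a: str,
    group_b: str,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Negative-binomial test of equal expression between two sample groups.

    Returns a per-gene table with normalized group means, log2 fold change
    (``group_b`` over ``group_a``), p-value, BH FDR and the DE call.
    """
    cols_a = cm.samples_in_group(group_a)
    cols_b = cm.samples_in_group(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need at least two samples per group")
    sub = cm.counts[cols_a + cols_b]
    if (sub[cols_a].values.sum() == 0) or (sub[cols_b].values.sum() == 0):
        raise ValueError("a group has an all-zero library")
    if factors is None:
        factors = size_factors(sub, pseudo_reference=True)
    sf = factors.loc[sub.columns].values.astype(float)
    k = sub.values.astype(np.int64)
    norm = k / sf[None, :]

    ia = np.arange(len(cols_a))
    ib = np.arange(len(cols_a), len(cols_a) + len(cols_b))
    group_cols = {group_a: ia, group_b: ib}
    inv_sf_mean = {
        group_a: float(np.mean(1.0 / sf[ia])),
        group_b: float(np.mean(1.0 / sf[ib])),
    }
    alpha_hat, base_mean = _moment_dispersions(norm, inv_sf_mean, group_cols)
    a0, a1 = _fit_dispersion_trend(base_mean, alpha_hat)
    with np.errstate(divide="ignore"):
        trend = np.where(base_mean > 0, a0 + a1 / base_mean, a0)
    alpha = np.maximum(np.maximum(alpha_hat, trend), 1e-8)

    SA, SB = sf[ia].sum(), sf[ib].sum()
    SA2, SB2 = (sf[ia] ** 2).sum(), (sf[ib] ** 2).sum()
    kA = k[:, ia].sum(axis=1)
    kB = k[:, ib].sum(axis=1)
    q = (kA + kB) / (SA + SB)

    pvals = np.ones(len(q))
    for i in range(len(q)):
        if kA[i] + kB[i] == 0:
            continue
        muA = q[i] * SA
        muB = q[i] * SB
        varA = muA + alpha[i] * q[i] ** 2 * SA2
        varB = muB + alpha[i] * q[i] ** 2 * SB2
        pvals[i] = _exact_pvalue(int(kA[i]), int(kB[i]), muA, varA, muB, varB)

    mean_a = norm[:, ia].mean(axis=1)
    mean_b = norm[:, ib].mean(axis=1)
    log2fc = np.log2(
        (mean_b + LOG2FC_PSEUDOCOUNT) / (mean_a + LOG2FC_PSEUDOCOUNT)
    )
    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            f"mean_{group_a}": mean_a,
            f"mean_{group_b}": mean_b,
            "dispersion": alpha,
            "log2fc": log2fc,
            "p_value": pvals,
        },
        index=sub.index,
    )
    out.index.name = "gene_id"
    out["fdr"] = bh_fdr(out["p_value"].values)
    return call_degs(out)


# ---------------------------------------------------------------------------
# Multiple testing and DE calls
# ---------------------------------------------------------------------------

def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def call_degs(
    results: pd.DataFrame, max_fdr: float = 0.1, min_abs_log2fc: float = 1.0
) -> pd.DataFrame:
    """Flag differential expression at FDR <= max_fdr and |log2FC| >= min_abs_log2fc."""
    results = results.copy()
    if "fdr" not in results.columns:
        results["fdr"] = bh_fdr(results["p_value"].values)
    results["is_de"] = (results["fdr"] <= max_fdr) & (
        results["log2fc"].abs() >= min_abs_log2fc
    )
    return results


def summarize_degs(
    de_tables: dict[str, pd.DataFrame], categories: pd.Series
) -> pd.DataFrame:
    """Per-category DE counts and integer percentages for each comparison.

    ``categories`` maps gene id to its catalog category; genes absent from it
    are ignored.  Percentages are of the expressed genes in the category.
    """
    rows = []
    cats = list(dict.fromkeys(categories.values))
    for comparison, table in de_tables.items():
        common = table.index.intersection(categories.index)
        tab = table.loc[common]
        cat = categories.loc[common]
        for c in cats:
            in_cat = cat == c
            n = int(in_cat.sum())
            n_de = int((tab["is_de"] & in_cat).sum())
            rows.append(
                {
                    "comparison": comparison,
                    "category": c,
                    "n_expressed": n,
                    "n_de": n_de,
                    "pct_de": de_percentage(n_de, n),
                }
            )
    return pd.DataFrame(rows)


def de_percentage(n_de: int, n_total: int) -> int:
    """Integer percentage of DE genes, as printed in the summary tables."""
    if n_total == 0:
        return 0
    return int(round(100.0 * n_de / n_total))


def cytokine_calls(results: pd.DataFrame, max_fdr: float = 0.1) -> pd.DataFrame:
    """Classify genes as cytokine-enhanced (FC > 2) or -repressed (FC < 0.5).

    Only genes at FDR <= max_fdr are eligible; FC is the linear fold change
    2**log2fc.
    """
    fc = 2.0 ** results["log2fc"]
    sig = results["fdr"] <= max_fdr
    out = results.copy()
    out["fc"] = fc
    out["call"] = "none"
    out.loc[sig & (fc > 2.0), "call"] = "enhanced"
    out.loc[sig & (fc < 0.5), "call"] = "repressed"
    return out
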