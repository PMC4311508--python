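"""Guilt-by-association function inference for lncRNAs.

Coding genes carry curated ontology annotations (closed under ancestry in
the term DAG); lncRNAs are essentially unannotated.  Each lncRNA inherits
the propagated annotations of the most-correlated coding gene(s) when the
squared Spearman correlation of their expression profiles (log normalized
counts over the combined NN and PP samples) reaches a cutoff.  The cutoff
is calibrated by repeated sampling of annotated gene pairs: the maximum
same-function correlation of a gene serves as a positive score, the maximum
correlation with a random gene set (sized from the empirical genes-per-term
distribution) as a negative score, and the cutoff maximizing the
recall-weighted F-measure

    F_beta = (1 + beta^2) * rho * gamma / (rho * beta^2 + gamma)

with precision rho, recall gamma and beta = 5 is selected.  Inferred
functions enriched among differentially expressed lncRNAs are found with a
hypergeometric upper-tail test over the universe of lncRNAs that received
at least one inferred function.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .de import bh_fdr


# ---------------------------------------------------------------------------
# Ontology DAG
# ---------------------------------------------------------------------------

class OntologyDAG:
    """Rooted directed acyclic graph of terms with child -> parent edges."""

    def __init__(self, edges: list[tuple[str, str]]):
        g = nx.DiGraph()
        g.add_edges_from(edges)  # child -> parent
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology contains a cycle through edge {cycle[0]}")
        self.graph = g
        self.roots = frozenset(n for n in g.nodes if g.out_degree(n) == 0)

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def ancestors(self, term: str) -> set[str]:
        if term not in self.graph:
            return set()
        return set(nx.descendants(self.graph, term))  # edges point rootward

    @classmethod
    def from_tsv(cls, path) -> "OntologyDAG":
        df = pd.read_csv(path, sep="\t")
        return cls(list(zip(df["child"], df["parent"])))


def propagate_ancestors(
    dag: OntologyDAG, annotations: dict[str, set[str]]
) -> dict[str, set[str]]:
    """Close each gene's term set under ancestry; idempotent."""
    out = {}
    for gene, terms in annotations.items():
        closed = set(terms)
        for t in terms:
            closed |= dag.ancestors(t)
        out[gene] = closed
    return out


# ---------------------------------------------------------------------------
# Correlation machinery
# ---------------------------------------------------------------------------

def _standardized_ranks(expr: pd.DataFrame) -> np.ndarray:
    """Row-wise average ranks, centered and L2-normalized, so that the dot
    product of two rows is their Spearman correlation."""
    ranks = np.apply_along_axis(stats.rankdata, 1, expr.values)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(norms > 0, ranks / norms, 0.0)
    return z


def correlation_matrix(
    lnc_expr: pd.DataFrame, mrna_expr: pd.DataFrame
) -> pd.DataFrame:
    """Squared Spearman correlations, lncRNAs x coding genes.

    Constant profiles have undefined correlation and yield NaN.
    """
    zl = _standardized_ranks(lnc_expr)
    zm = _standardized_ranks(mrna_expr)
    rho = zl @ zm.T
    const_l = (lnc_expr.values.std(axis=1) == 0)[:, None]
    const_m = (mrna_expr.values.std(axis=1) == 0)[None, :]
    rho2 = rho**2
    rho2[np.broadcast_to(const_l | const_m, rho2.shape)] = np.nan
    return pd.DataFrame(rho2, index=lnc_expr.index, columns=mrna_expr.index)


def log_normalized_expression(
    counts: pd.DataFrame, factors: pd.Series
) -> pd.DataFrame:
    """Variance-stabilized profiles log(K/s + 1) used for co-expression."""
    return np.log1p(counts / factors.loc[counts.columns])


# ---------------------------------------------------------------------------
# F-measure and cutoff calibration
# ---------------------------------------------------------------------------

def f_beta(precision: float, recall: float, beta: float) -> float:
    denom = precision * beta**2 + recall
    if denom == 0:
        return 0.0
    return (1 + beta**2) * precision * recall / denom


@dataclass
class CalibrationCurve:
    """Precision/recall/F over a grid of squared-correlation cutoffs."""

    grid: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f_scores: np.ndarray
    beta: float
    chosen_cutoff: float
    auc: float
    n_positive: int
    n_negative: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.grid,
                "precision": self.precision,
                "recall": self.recall,
                f"f_beta{self.beta:g}": self.f_scores,
            }
        )


def calibrate_cutoff(
    expr: pd.DataFrame,
    annotations: dict[str, set[str]],
    dag: OntologyDAG | None = None,
    n_samplings: int = 100_000,
    beta: float = 5.0,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> CalibrationCurve:
    """Calibrate the squared-correlation cutoff by pair sampling.

    Each sampling draws two annotated genes (with replacement across
    samplings).  If they share a function (a propagated term below the
    root), one of them contributes its maximum squared correlation with the
    other members of its functions as a positive score; otherwise its
    maximum over a random gene set, sized from the empirical genes-per-term
    distribution, is a negative score.
    """
    if dag is not None:
        annotations = propagate_ancestors(dag, annotations)
        roots = dag.roots
    else:
        roots = frozenset()
    informative = {
        g: frozenset(t for t in ts if t not in roots)
        for g, ts in annotations.items()
    }
    genes = [g for g in expr.index if informative.get(g)]
    if len(genes) < 4:
        raise ValueError("too few annotated genes for calibration")
    gene_pos = {g: i for i, g in enumerate(genes)}
    z = _standardized_ranks(expr.loc[genes])

    term_members: dict[str, list[int]] = {}
    for g in genes:
        for t in sorted(informative[g]):
            term_members.setdefault(t, []).append(gene_pos[g])
    term_members = {t: term_members[t] for t in sorted(term_members)}
    multi_terms = {t: m for t, m in term_members.items() if len(m) >= 2}
    if len(multi_terms) < 2:
        raise ValueError("need >= 2 functions with >= 2 annotated genes")
    term_sizes = np.array([len(m) for m in term_members.values()])

    partners: dict[int, np.ndarray] = {}
    for gi, g in enumerate(genes):
        mates: set[int] = set()
        for t in informative[g]:
            mates.update(term_members.get(t, ()))
        mates.discard(gi)
        partners[gi] = np.fromiter(mates, dtype=np.int64) if mates else np.empty(0, np.int64)

    rng = np.random.default_rng(seed)
    n = len(genes)
    scores, labels = [], []
    for _ in range(n_samplings):
        i, j = rng.integers(0, n, size=2)
        shared = informative[genes[i]] & informative[genes[j]]
        pick = int(rng.integers(0, 2))
        gi = (i, j)[pick]
        if shared:
            mates = partners[gi]
            if len(mates) == 0:
                continue
            r2 = float(np.max((z[mates] @ z[gi]) ** 2))
            scores.append(r2)
            labels.append(1)
        else:
            m = int(rng.choice(term_sizes))
            others = rng.choice(n, size=min(m, n - 1), replace=False)
            others = others[others != gi]
            if len(others) == 0:
                continue
            r2 = float(np.max((z[others] @ z[gi]) ** 2))
            scores.append(r2)
            labels.append(0)
    scores_arr = np.array(scores)
    labels_arr = np.array(labels)
    n_pos = int(labels_arr.sum())
    n_neg = int(len(labels_arr) - n_pos)
    if n_pos == 0:
        raise ValueError("no positive same-function pairs drawn; increase n_samplings")
    auc = float(roc_auc_score(labels_arr, scores_arr)) if n_neg else float("nan")

    if grid is None:
        grid = np.round(np.arange(0.05, 1.0, 0.05), 10)
    precision = np.zeros(len(grid))
    recall = np.zeros(len(grid))
    fs = np.zeros(len(grid))
    for k, cut in enumerate(grid):
        called = scores_arr >= cut
        tp = int((called & (labels_arr == 1)).sum())
        precision[k] = tp / called.sum() if called.any() else 0.0
        recall[k] = tp / n_pos
        fs[k] = f_beta(precision[k], recall[k], beta)
    chosen = float(grid[int(np.argmax(fs))])
    return CalibrationCurve(
        grid=np.asarray(grid, dtype=float),
        precision=precision,
        recall=recall,
        f_scores=fs,
        beta=beta,
        chosen_cutoff=chosen,
        auc=auc,
        n_positive=n_pos,
        n_negative=n_neg,
    )


# ---------------------------------------------------------------------------
# Annotation transfer
# ---------------------------------------------------------------------------

#: relative tolerance for ties at the maximum correlation
TIE_RTOL = 1e-12


@dataclass
class InferredFunctionSet:
    lnc_id: str
    terms: frozenset[str]
    sources: tuple[str, ...]
    max_rho2: float
    is_cis: bool


def transfer_functions(
    rho2: pd.DataFrame,
    propagated: dict[str, set[str]],
    cutoff: float = 0.5,
    positions: pd.DataFrame | None = None,
    cis_window: float = 1_000_000.0,
) -> list[InferredFunctionSet]:
    """Transfer propagated terms from each lncRNA's most-correlated gene(s).

    All genes tying at the maximum (within relative tolerance) contribute;
    the transferred set is their term union, hence closed under ancestry.
    ``positions`` (chrom/start/end per gene) enables the cis flag: a source
    within ``cis_window`` bp on the same chromosome.
    """
    out = []
    cols = np.array(rho2.columns)
    annotated_cols = np.array([bool(propagated.get(c)) for c in cols])
    for lnc in rho2.index:
        row = rho2.loc[lnc].values.astype(float)
        row = np.where(annotated_cols, row, np.nan)
        if np.all(np.isnan(row)):
            continue
        best = np.nanmax(row)
        if not (best >= cutoff):
            continue
        tie_mask = np.nan_to_num(row, nan=-np.inf) >= best * (1 - TIE_RTOL)
        sources = tuple(sorted(cols[tie_mask]))
        terms: set[str] = set()
        for s in sources:
            terms |= propagated[s]
        is_cis = False
        if positions is not None and lnc in positions.index:
            for s in sources:
                if s in positions.index:
                    if positions.at[s, "chrom"] == positions.at[lnc, "chrom"] and (
                        abs(int(positions.at[s, "start"]) - int(positions.at[lnc, "start"]))
                        <= cis_window
                    ):
                        is_cis = True
                        break
        out.append(
            InferredFunctionSet(
                lnc_id=str(lnc),
                terms=frozenset(terms),
                sources=sources,
                max_rho2=float(best),
                is_cis=is_cis,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Enrichment of inferred functions among DE lncRNAs
# ---------------------------------------------------------------------------

def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) drawing n from a population of N with K successes; k=0 -> 1."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrichment_fold_change(k: int, N: int, K: int, n: int) -> float:
    """Observed/expected ratio k / (K*n/N)."""
    if K == 0 or n == 0:
        return 0.0
    return k * N / (K * n)


def inferred_function_enrichment(
    inferred: list[InferredFunctionSet],
    de_lnc_set: set[str],
    max_genes_displayed: int = 100,
    max_fdr_displayed: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-term hypergeometric enrichment among DE lncRNAs.

    Universe N = lncRNAs with >= 1 inferred function; draws n = those that
    are differentially expressed.  Returns (full table, display table
    filtered to FDR and term size).
    """
    if not inferred:
        raise ValueError("no lncRNAs with inferred functions")
    N = len(inferred)
    de_ids = {f.lnc_id for f in inferred} & set(de_lnc_set)
    n = len(de_ids)
    term_all: dict[str, int] = {}
    term_de: dict[str, int] = {}
    for f in inferred:
        for t in f.terms:
            term_all[t] = term_all.get(t, 0) + 1
            if f.lnc_id in de_ids:
                term_de[t] = term_de.get(t, 0) + 1
    rows = []
    for t in sorted(term_all):
        K = term_all[t]
        k = term_de.get(t, 0)
        rows.append(
            {
                "term": t,
                "K": K,
                "k": k,
                "p_value": hypergeom_upper_tail(k, N, K, n),
                "fc": enrichment_fold_change(k, N, K, n),
            }
        )
    full = pd.DataFrame(rows)
    full["fdr"] = bh_fdr(full["p_value"].values)
    full = full.sort_values("p_value").reset_index(drop=True)
    display = full[
        (full["fdr"] <= max_fdr_displayed) & (full["K"] <= max_genes_displayed)
    ].reset_index(drop=True)
    return full, display
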