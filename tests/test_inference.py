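"""Ontology propagation, correlation transfer, F-beta calibration, enrichment."""

import numpy as np
import pandas as pd
import pytest

from lncskin.inference import (
    CalibrationCurve,
    InferredFunctionSet,
    OntologyDAG,
    calibrate_cutoff,
    correlation_matrix,
    enrichment_fold_change,
    f_beta,
    hypergeom_upper_tail,
    inferred_function_enrichment,
    propagate_ancestors,
    transfer_functions,
)


# ---------------------------------------------------------------------------
# DAG and propagation
# ---------------------------------------------------------------------------

def test_chain_propagates_all_ancestors():
    dag = OntologyDAG([("c", "b"), ("b", "a")])
    out = propagate_ancestors(dag, {"g": {"c"}})
    assert out["g"] == {"a", "b", "c"}


def test_root_annotation_unchanged_and_idempotent():
    dag = OntologyDAG([("c", "b"), ("b", "a")])
    assert propagate_ancestors(dag, {"g": {"a"}})["g"] == {"a"}
    once = propagate_ancestors(dag, {"g": {"c"}})
    assert propagate_ancestors(dag, once) == once


def test_cycle_rejected_with_offending_edge():
    with pytest.raises(ValueError, match="cycle"):
        OntologyDAG([("a", "b"), ("b", "a")])


def test_propagation_matches_transitive_closure_oracle():
    rng = np.random.default_rng(7)
    for _ in range(10):
        n = int(rng.integers(5, 25))
        edges = []
        for child in range(1, n):
            for parent in rng.choice(child, size=min(child, 2), replace=False):
                edges.append((f"t{child}", f"t{parent}"))
        dag = OntologyDAG(edges)
        # oracle: repeated relaxation over the raw edge list
        parents = {}
        for c, p in edges:
            parents.setdefault(c, set()).add(p)
        def closure(t):
            seen, stack = set(), [t]
            while stack:
                for p in parents.get(stack.pop(), ()):
                    if p not in seen:
                        seen.add(p)
                        stack.append(p)
            return seen
        genes = {f"g{i}": {f"t{int(rng.integers(0, n))}"} for i in range(8)}
        out = propagate_ancestors(dag, genes)
        for g, terms in genes.items():
            t = next(iter(terms))
            assert out[g] == {t} | closure(t)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def test_monotone_profiles_have_unit_squared_correlation():
    lnc = pd.DataFrame([[1.0, 2, 3, 4, 5]], index=["l"])
    mrna = pd.DataFrame([[10.0, 20, 30, 40, 50], [5.0, 4, 3, 2, 1]],
                        index=["up", "down"])
    rho2 = correlation_matrix(lnc, mrna)
    assert rho2.loc["l", "up"] == pytest.approx(1.0)
    assert rho2.loc["l", "down"] == pytest.approx(1.0)  # squaring is sign-blind


def test_constant_profile_flagged_nan():
    lnc = pd.DataFrame([[2.0, 2, 2, 2]], index=["l"])
    mrna = pd.DataFrame([[1.0, 2, 3, 4]], index=["g"])
    assert np.isnan(correlation_matrix(lnc, mrna).loc["l", "g"])


def test_correlations_match_scipy_on_small_vectors():
    from scipy.stats import spearmanr

    rng = np.random.default_rng(11)
    lnc = pd.DataFrame(rng.normal(size=(4, 12)), index=[f"l{i}" for i in range(4)])
    mrna = pd.DataFrame(rng.normal(size=(5, 12)), index=[f"g{i}" for i in range(5)])
    rho2 = correlation_matrix(lnc, mrna)
    for l in lnc.index:
        for g in mrna.index:
            ref = spearmanr(lnc.loc[l], mrna.loc[g]).statistic ** 2
            assert rho2.loc[l, g] == pytest.approx(ref)


# ---------------------------------------------------------------------------
# F-beta and calibration
# ---------------------------------------------------------------------------

def test_f_beta_closed_forms():
    # when precision equals recall the F-measure equals both
    assert f_beta(0.37, 0.37, 5.0) == pytest.approx(0.37)
    # direct evaluation: rho=1, gamma=0.5, beta=5 -> 26*0.5/25.5
    assert f_beta(1.0, 0.5, 5.0) == pytest.approx(26 * 0.5 / 25.5)
    assert f_beta(0.0, 0.0, 5.0) == 0.0


@pytest.fixture(scope="module")
def calibration_inputs(fixture_bundle):
    from lncskin.de import size_factors
    from lncskin.inference import log_normalized_expression

    cm = fixture_bundle.counts
    sf = size_factors(cm.counts, pseudo_reference=True)
    cols = [s for s in cm.samples if cm.groups[s] in ("NN", "PP")]
    expr = log_normalized_expression(cm.counts[cols], sf.loc[cols])
    dag = OntologyDAG(fixture_bundle.ontology_edges)
    coding = [g for g in expr.index if g in fixture_bundle.annotations]
    return expr.loc[coding], fixture_bundle.annotations, dag


def test_calibration_is_seed_reproducible(calibration_inputs):
    expr, annotations, dag = calibration_inputs
    a = calibrate_cutoff(expr, annotations, dag=dag, n_samplings=2000, seed=13)
    b = calibrate_cutoff(expr, annotations, dag=dag, n_samplings=2000, seed=13)
    assert np.array_equal(a.precision, b.precision)
    assert np.array_equal(a.recall, b.recall)
    assert a.chosen_cutoff == b.chosen_cutoff and a.auc == b.auc


def test_calibration_discriminates_on_coherent_expression(calibration_inputs):
    expr, annotations, dag = calibration_inputs
    curve = calibrate_cutoff(expr, annotations, dag=dag, n_samplings=5000, seed=1)
    assert curve.auc > 0.6
    assert 0 <= curve.chosen_cutoff <= 1
    # at any grid point where precision == recall, F equals them
    eq = np.isclose(curve.precision, curve.recall)
    assert np.allclose(curve.f_scores[eq], curve.precision[eq])


# ---------------------------------------------------------------------------
# transfer
# ---------------------------------------------------------------------------

def test_transfer_respects_cutoff_boundary():
    rho2 = pd.DataFrame({"g1": [0.49]}, index=["l1"])
    assert transfer_functions(rho2, {"g1": {"t"}}, cutoff=0.5) == []
    rho2 = pd.DataFrame({"g1": [0.5]}, index=["l1"])
    out = transfer_functions(rho2, {"g1": {"t"}}, cutoff=0.5)
    assert out[0].terms == {"t"}


def test_ties_at_maximum_transfer_union_of_terms():
    rho2 = pd.DataFrame({"g1": [0.8], "g2": [0.8], "g3": [0.6]}, index=["l1"])
    out = transfer_functions(
        rho2, {"g1": {"a"}, "g2": {"b"}, "g3": {"c"}}, cutoff=0.5
    )
    assert out[0].sources == ("g1", "g2")
    assert out[0].terms == {"a", "b"}


def test_cis_flag_within_1mb():
    rho2 = pd.DataFrame({"g1": [0.9]}, index=["l1"])
    pos = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "start": [100, 900_000], "end": [200, 900_500]},
        index=["l1", "g1"],
    )
    out = transfer_functions(rho2, {"g1": {"t"}}, cutoff=0.5, positions=pos)
    assert out[0].is_cis
    pos.loc["g1", "start"] = 1_200_000
    out = transfer_functions(rho2, {"g1": {"t"}}, cutoff=0.5, positions=pos)
    assert not out[0].is_cis


def test_planted_coexpressed_lncRNAs_recover_their_term(fixture_bundle):
    from lncskin.de import size_factors
    from lncskin.inference import log_normalized_expression

    cm = fixture_bundle.counts
    sf = size_factors(cm.counts, pseudo_reference=True)
    cols = [s for s in cm.samples if cm.groups[s] in ("NN", "PP")]
    expr = log_normalized_expression(cm.counts[cols], sf.loc[cols])
    dag = OntologyDAG(fixture_bundle.ontology_edges)
    propagated = propagate_ancestors(dag, fixture_bundle.annotations)
    lnc_modules = {
        g: t for g, t in fixture_bundle.modules.items()
        if g not in fixture_bundle.annotations
    }
    lncs = sorted(lnc_modules)
    coding = [g for g in expr.index if g in propagated]
    rho2 = correlation_matrix(expr.loc[lncs], expr.loc[coding])
    inferred = {f.lnc_id: f.terms for f in transfer_functions(rho2, propagated, 0.5)}
    hits = sum(1 for g, t in lnc_modules.items() if t in inferred.get(g, ()))
    assert hits / len(lnc_modules) >= 0.8


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def test_fold_changes_reproduce_printed_table_values():
    # universe of 959 lncRNAs with inferred functions, 490 of them DE
    assert enrichment_fold_change(41, 959, 42, 490) == pytest.approx(1.91, abs=0.005)
    assert enrichment_fold_change(60, 959, 69, 490) == pytest.approx(1.70, abs=0.005)


def test_zero_overlap_gives_p_one_fc_zero():
    assert hypergeom_upper_tail(0, 100, 10, 5) == 1.0
    assert enrichment_fold_change(0, 100, 10, 5) == 0.0


def test_hypergeom_tail_matches_summation_oracle():
    from math import comb

    rng = np.random.default_rng(3)
    for _ in range(25):
        N = int(rng.integers(10, 200))
        K = int(rng.integers(1, N))
        n = int(rng.integers(1, N))
        k = int(rng.integers(0, min(K, n) + 1))
        oracle = sum(
            comb(K, i) * comb(N - K, n - i)
            for i in range(k, min(K, n) + 1)
            if n - i <= N - K
        ) / comb(N, n)
        assert hypergeom_upper_tail(k, N, K, n) == pytest.approx(oracle, rel=1e-9)


def test_enrichment_table_display_filter():
    inferred = []
    for i in range(50):
        terms = {"common"} if i < 40 else {"rare"}
        if i < 10:
            terms = {"common", "rare"}
        inferred.append(InferredFunctionSet(f"l{i}", frozenset(terms), ("g",), 0.9, False))
    de = {f"l{i}" for i in range(12)}
    full, display = inferred_function_enrichment(inferred, de)
    assert set(full["term"]) == {"common", "rare"}
    assert (display["K"] <= 100).all()
    assert (display["fdr"] <= 0.1).all()
    row = full[full["term"] == "rare"].iloc[0]
    assert row["K"] == 20 and row["k"] == 10
    assert row["fc"] == pytest.approx(10 * 50 / (20 * 12))
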