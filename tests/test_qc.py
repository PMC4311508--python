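"""Filter cascade: boundaries, oracles, attrition monotonicity, idempotence."""

import math

import numpy as np
import pandas as pd
import pytest

from lncskin.catalog import Catalog, build_catalog, merge_assemblies
from lncskin.core import (
    GeneModel,
    GenomicInterval,
    ReferenceAnnotation,
    TranscriptModel,
)
from lncskin.io import Track
from lncskin.qc import (
    derive_distance_threshold,
    distance_filter,
    length_filter,
    mappability_filter,
    nearest_exon_distance,
    read_support_filter,
    recurrence_filter,
    recurrence_threshold,
    run_cascade,
)


def tx(tid, pairs, strand="+", chrom="chr1", n_samples=20):
    exons = tuple(GenomicInterval(chrom, a, b, strand) for a, b in pairs)
    return TranscriptModel(
        tid, exons, strand=strand,
        sample_presence=frozenset(f"s{i}" for i in range(n_samples)),
    )


def catalog_of(models, categories):
    rows = []
    for m in models:
        rows.append(
            {
                "transcript_id": m.id,
                "category": categories[m.id],
                "chrom": m.chrom,
                "start": m.start,
                "end": m.end,
                "strand": m.strand,
                "n_exons": len(m.exons),
                "mature_length": m.mature_length,
                "n_samples": len(m.sample_presence),
                "location_only": False,
            }
        )
    table = pd.DataFrame(rows).set_index("transcript_id")
    return Catalog(table, {m.id: m for m in models})


@pytest.fixture(scope="module")
def fixture_catalog(fixture_bundle):
    models = merge_assemblies(fixture_bundle.assemblies)
    return build_catalog(models, fixture_bundle.reference, fixture_bundle.genome)


# ---------------------------------------------------------------------------
# recurrence
# ---------------------------------------------------------------------------

def test_recurrence_threshold_is_eleven_of_216():
    assert recurrence_threshold(216, 0.05) == 11


def test_recurrence_boundary_10_removed_11_kept():
    cat = catalog_of(
        [tx("a", [(0, 300)], n_samples=10), tx("b", [(1000, 1300)], n_samples=11)],
        {"a": "novel_intergenic", "b": "novel_intergenic"},
    )
    kept, removed = recurrence_filter(cat, 216, 0.05)
    assert removed == ["a"] and list(kept.table.index) == ["b"]


def test_recurrence_on_planted_presence_fractions():
    """Novels planted at 4% of samples are all removed; at 6%, all kept."""
    from lncskin.catalog import build_catalog, merge_assemblies
    from lncskin.synthetic_data import (
        FixtureConfig,
        generate_reference,
        generate_sample_assemblies,
    )

    cfg = FixtureConfig(seed=9, novel_presence_fractions=(0.04, 0.06))
    ref, genome = generate_reference(cfg)
    bundle = generate_sample_assemblies(cfg, ref)
    cat = build_catalog(merge_assemblies(bundle), ref, genome)
    truth = bundle.truth.set_index("transcript_id")
    kept, removed = recurrence_filter(cat, cfg.n_samples, 0.05)
    novel = truth[truth["label"].str.startswith("novel")]
    for tid, row in novel.iterrows():
        if row["presence_fraction"] == 0.04:
            assert tid in removed
        else:
            assert tid in kept.table.index


def test_recurrence_rejects_bad_sample_count(fixture_catalog):
    with pytest.raises(ValueError):
        recurrence_filter(fixture_catalog, 0)


# ---------------------------------------------------------------------------
# exon distance
# ---------------------------------------------------------------------------

@pytest.fixture()
def distance_ref():
    g = GeneModel(
        "g1", "protein_coding", "+",
        (GenomicInterval("chr1", 10_000, 10_500, "+"),),
    )
    return ReferenceAnnotation([g])


def test_overlap_gives_zero_distance(distance_ref):
    assert nearest_exon_distance(tx("t", [(10_400, 10_800)]), distance_ref) == 0


def test_gap_of_500(distance_ref):
    assert nearest_exon_distance(tx("t", [(9_000, 9_500)]), distance_ref) == 500


def test_no_other_exon_gives_infinity(distance_ref):
    assert math.isinf(
        nearest_exon_distance(tx("t", [(500, 900)], chrom="chr2"), distance_ref)
    )


def test_distances_match_allpairs_scan(fixture_bundle, fixture_catalog):
    ref = fixture_bundle.reference
    all_exons = [
        (g.chrom, e.start, e.end) for g in ref.genes for e in g.exons
    ]
    novel = fixture_catalog.table[
        fixture_catalog.table["category"].str.startswith("novel")
    ]
    for tid in novel.index[:100]:
        m = fixture_catalog.models[tid]
        best = math.inf
        for chrom, s, e in all_exons:
            if chrom != m.chrom:
                continue
            for ex in m.exons:
                best = min(best, max(s - ex.end, ex.start - e, 0))
        assert nearest_exon_distance(m, ref) == best


def test_derived_threshold_is_median_of_lnc_distances():
    genes = [
        GeneModel("c1", "protein_coding", "+",
                  (GenomicInterval("chr1", 0, 1000, "+"),)),
        GeneModel("l1", "lincRNA", "+",
                  (GenomicInterval("chr1", 2000, 2500, "+"),)),  # d=1000
        GeneModel("l2", "lincRNA", "+",
                  (GenomicInterval("chr1", 4500, 5000, "+"),)),  # d=2000
        GeneModel("l3", "lincRNA", "+",
                  (GenomicInterval("chr1", 8000, 8500, "+"),)),  # d=3000
    ]
    assert derive_distance_threshold(ReferenceAnnotation(genes)) == 2000


def test_derived_threshold_single_lncRNA():
    genes = [
        GeneModel("c1", "protein_coding", "+",
                  (GenomicInterval("chr1", 0, 1000, "+"),)),
        GeneModel("l1", "lincRNA", "+",
                  (GenomicInterval("chr1", 2500, 3000, "+"),)),
    ]
    assert derive_distance_threshold(ReferenceAnnotation(genes)) == 1500


def test_derived_threshold_requires_lncRNAs(distance_ref):
    with pytest.raises(ValueError, match="default"):
        derive_distance_threshold(distance_ref)


def test_distance_filter_boundary_and_annotated_passthrough(distance_ref):
    models = [
        tx("near", [(10_500 + 1999, 10_500 + 2399)]),   # d = 1999 -> removed
        tx("edge", [(10_500 + 2000, 10_500 + 2400)]),   # d = 2000 -> kept
        tx("ann", [(10_600, 10_900)]),                  # annotated, d=0 -> kept
    ]
    cat = catalog_of(models, {"near": "novel_intergenic",
                              "edge": "novel_intergenic",
                              "ann": "annotated_ncRNA"})
    kept, removed, dists = distance_filter(cat, distance_ref, 2000)
    assert removed == ["near"]
    assert {"edge", "ann"} <= set(kept.table.index)
    assert dists["near"] == 1999 and dists["edge"] == 2000


def test_all_premature_artifacts_removed_by_distance(fixture_bundle, fixture_catalog, truth):
    _, removed, _ = distance_filter(fixture_catalog, fixture_bundle.reference)
    prem = set(truth.index[truth["label"] == "artifact_premature"])
    assert prem <= set(removed)
    novels = set(truth.index[truth["label"].str.startswith("novel")])
    assert not novels & set(removed)


# ---------------------------------------------------------------------------
# mappability / length / read support
# ---------------------------------------------------------------------------

def _uniform_track(value, length=100_000):
    return Track({"chr1": (np.array([0]), np.array([length]), np.array([value]))})


def test_mappability_uniform_one_kept_half_removed():
    cat = catalog_of([tx("t", [(100, 600)])], {"t": "novel_intergenic"})
    kept, removed = mappability_filter(cat, _uniform_track(1.0), _uniform_track(1.0))
    assert not removed
    kept, removed = mappability_filter(cat, _uniform_track(0.5), _uniform_track(1.0))
    assert removed == ["t"]


def test_mappability_exact_09_is_retained():
    cat = catalog_of([tx("t", [(100, 600)])], {"t": "novel_intergenic"})
    _, removed = mappability_filter(cat, _uniform_track(0.9), _uniform_track(0.9))
    assert not removed


def test_lowmap_artifacts_removed_true_novels_kept(fixture_bundle, fixture_catalog, truth):
    _, removed = mappability_filter(
        fixture_catalog, fixture_bundle.uniqueness, fixture_bundle.alignability
    )
    lowmap = set(truth.index[truth["label"] == "artifact_lowmap"])
    novels = set(truth.index[truth["label"].str.startswith("novel")])
    assert lowmap <= set(removed)
    assert not novels & set(removed)


def test_length_boundary_and_mature_length_semantics():
    models = [
        tx("short", [(0, 199)]),
        tx("edge", [(0, 200)]),
        tx("sparse", [(0, 75), (4925, 5000)]),  # span 5000, mature 150
    ]
    cat = catalog_of(models, {m.id: "novel_intergenic" for m in models})
    kept, removed = length_filter(cat, 200)
    assert set(removed) == {"short", "sparse"}
    assert list(kept.table.index) == ["edge"]


def test_read_support_boundary_215_vs_216():
    cat = catalog_of(
        [tx("lo", [(0, 300)]), tx("hi", [(1000, 1300)]), tx("zero", [(2000, 2300)])],
        {m: "novel_intergenic" for m in ("lo", "hi", "zero")},
    )
    counts = pd.DataFrame(
        0, index=["lo", "hi", "zero"], columns=[f"s{i}" for i in range(216)]
    )
    counts.iloc[0, :215] = 1
    counts.iloc[1, :216] = 1
    kept, removed = read_support_filter(cat, counts)
    assert set(removed) == {"lo", "zero"}
    assert list(kept.table.index) == ["hi"]


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def cascade(fixture_bundle, fixture_catalog):
    return run_cascade(
        fixture_catalog,
        fixture_bundle.reference,
        fixture_bundle.uniqueness,
        fixture_bundle.alignability,
        fixture_bundle.counts,
    )


def test_attrition_is_monotone_per_category(cascade):
    vals = cascade.report.values
    assert (np.diff(vals, axis=0) <= 0).all()


def test_every_removal_has_exactly_one_stage_tag(cascade, fixture_catalog):
    removed = set(fixture_catalog.table.index) - set(cascade.catalog.table.index)
    assert removed == set(cascade.removal_stage)


def test_artifacts_removed_at_their_targeted_stage(cascade, truth):
    expected = {
        "artifact_premature": "distance",
        "artifact_lowmap": "mappability",
        "artifact_short": "length",
    }
    for tid, stage in cascade.removal_stage.items():
        label = truth.at[tid, "label"]
        if label in expected:
            assert stage == expected[label], (tid, label, stage)


def test_final_novel_count_equals_planted_survivors(cascade, truth):
    final_novel = cascade.catalog.table["category"].str.startswith("novel").sum()
    planted_novel = (truth["label"].str.startswith("novel")).sum()
    assert final_novel == planted_novel  # default fixture plants all above 5%


def test_cascade_is_idempotent(cascade, fixture_bundle):
    again = run_cascade(
        cascade.catalog,
        fixture_bundle.reference,
        fixture_bundle.uniqueness,
        fixture_bundle.alignability,
        fixture_bundle.counts,
    )
    assert not again.removal_stage
    assert list(again.catalog.table.index) == list(cascade.catalog.table.index)


def test_report_serializes_in_table_column_order(cascade, tmp_path):
    path = tmp_path / "report.tsv"
    cascade.report.reset_index().to_csv(path, sep="\t", index=False)
    header = path.read_text().splitlines()[0].split("\t")
    assert header == [
        "stage", "protein_coding", "antisense", "pseudogene", "annotated_ncRNA",
        "novel_intronic", "novel_intergenic", "novel_interleaving",
        "novel_encompassing",
    ]
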