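"""Merging, strand inference and classification against brute-force oracles."""

import numpy as np
import pytest

from lncskin.catalog import (
    build_catalog,
    classify_transcript,
    infer_strand,
    merge_assemblies,
)
from lncskin.core import (
    GeneModel,
    GenomicInterval,
    ReferenceAnnotation,
    TranscriptModel,
    category_for_biotype,
)


def tx(tid, pairs, strand="+", chrom="chr1", samples=()):
    exons = tuple(GenomicInterval(chrom, a, b, strand) for a, b in pairs)
    return TranscriptModel(tid, exons, strand=strand,
                           sample_presence=frozenset(samples))


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def test_identical_transcripts_merge_with_union_presence():
    bundle = {
        "s1": [tx("t1", [(100, 200), (300, 400)], samples=["s1"])],
        "s2": [tx("t1", [(100, 200), (300, 400)], samples=["s2"])],
    }
    out = merge_assemblies(bundle)
    assert len(out) == 1
    assert out[0].sample_presence == {"s1", "s2"}
    assert out[0].id == "t1"


def test_same_intron_chain_different_terminal_ends_merge():
    bundle = {
        "s1": [tx("t1", [(100, 200), (300, 400)], samples=["s1"])],
        "s2": [tx("t1", [(80, 200), (300, 450)], samples=["s2"])],
    }
    out = merge_assemblies(bundle)
    assert len(out) == 1
    assert out[0].start == 80 and out[0].end == 450
    assert out[0].intron_chain() == ((200, 300),)


def test_mono_exon_merge_requires_overlap():
    bundle = {
        "s1": [tx("a", [(100, 200)], samples=["s1"])],
        "s2": [tx("b", [(199, 300)], samples=["s2"]),
               tx("c", [(400, 500)], samples=["s2"])],
    }
    out = merge_assemblies(bundle)
    assert len(out) == 2
    merged = next(t for t in out if t.start == 100)
    assert merged.end == 300 and merged.sample_presence == {"s1", "s2"}


def test_merge_is_order_independent(fixture_bundle):
    per_sample = fixture_bundle.assemblies.per_sample
    fwd = merge_assemblies(per_sample)
    rev = merge_assemblies(dict(reversed(list(per_sample.items()))))
    key = lambda t: (t.chrom, t.start, t.end, t.id)
    assert [key(t) for t in sorted(fwd, key=key)] == [key(t) for t in sorted(rev, key=key)]
    assert all(
        a.sample_presence == b.sample_presence
        for a, b in zip(sorted(fwd, key=key), sorted(rev, key=key))
    )


def test_consensus_count_matches_planted_transcripts(fixture_bundle, truth):
    out = merge_assemblies(fixture_bundle.assemblies)
    assert len(out) == len(truth)
    assert sorted(t.id for t in out) == sorted(truth.index)


# ---------------------------------------------------------------------------
# strand inference
# ---------------------------------------------------------------------------

GENOME = {"chr1": "A" * 30 + "GT" + "A" * 16 + "AG" + "A" * 30}
#          exon1 [10,30), intron [30,50) = GT..AG, exon2 [50,70)


def test_forward_gt_ag_intron_predicts_plus():
    t = tx("t", [(10, 30), (50, 70)], strand=".")
    assert infer_strand(t, GENOME) == "+"


def test_reverse_motif_predicts_minus():
    g = {"chr1": "A" * 30 + "CT" + "A" * 16 + "AC" + "A" * 30}
    t = tx("t", [(10, 30), (50, 70)], strand=".")
    assert infer_strand(t, g) == "-"


def test_mono_exon_and_noncanonical_are_unknown():
    assert infer_strand(tx("t", [(10, 30)], strand="."), GENOME) == "."
    g = {"chr1": "A" * 100}
    assert infer_strand(tx("t", [(10, 30), (50, 70)], strand="."), g) == "."


def test_exon_beyond_chromosome_end_raises():
    with pytest.raises(ValueError, match="beyond chromosome"):
        infer_strand(tx("t", [(10, 30), (50, 2000)], strand="."), GENOME)


def test_planted_strands_recovered_from_genome(fixture_bundle, truth):
    genome = fixture_bundle.genome
    models = merge_assemblies(fixture_bundle.assemblies)
    checked = 0
    for m in models:
        if len(m.exons) < 2:
            continue
        expect = truth.at[m.id, "strand"]
        assert infer_strand(m, genome) == expect
        checked += 1
    assert checked > 20


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def test_exon_identical_to_lincRNA_is_annotated_ncRNA(toy_reference):
    t = tx("t", [(20000, 20500), (21500, 22000)], strand="-")
    assert classify_transcript(t, toy_reference) == ("annotated_ncRNA", False)


def test_transcript_inside_intron_is_novel_intronic(toy_reference):
    t = tx("t", [(4000, 4500)], strand="+")
    assert classify_transcript(t, toy_reference) == ("novel_intronic", False)


def test_intron_plus_intergenic_exons_is_interleaving(toy_reference):
    # one exon in the coding gene's intron, one beyond all gene spans
    t = tx("t", [(4000, 4500), (12000, 12500)], strand="+")
    assert classify_transcript(t, toy_reference) == ("novel_interleaving", False)


def test_gene_nested_in_transcript_intron_is_encompassing(toy_reference):
    t = tx("t", [(18000, 18500), (23000, 23500)], strand="+")
    assert classify_transcript(t, toy_reference) == ("novel_encompassing", False)


def test_opposite_strand_exonic_overlap_is_antisense(toy_reference):
    t = tx("t", [(1500, 1650)], strand="+")  # overlaps gene_as (-) exon only
    assert classify_transcript(t, toy_reference) == ("antisense", False)


def test_unknown_strand_overlap_classified_by_location_and_flagged(toy_reference):
    t = tx("t", [(1000, 1150)], strand=".")
    category, flagged = classify_transcript(t, toy_reference)
    assert category == "protein_coding"
    assert flagged


# ------------------------- brute-force oracle ------------------------------

def _oracle_classify(t, genes):
    """Exhaustive reimplementation of the category rules with naive loops."""
    def overlap(a, b):
        return a.chrom == b.chrom and a.start < b.end and b.start < a.end

    exonic = [g for g in genes
              if any(overlap(e, ge) for e in t.exons for ge in g.exons)]
    if exonic:
        if t.strand in "+-":
            same = [g for g in exonic if g.strand == t.strand]
            pool = same if same else None
            if pool:
                best = max(pool, key=lambda g: (sum(
                    max(0, min(e.end, ge.end) - max(e.start, ge.start))
                    for e in t.exons for ge in g.exons), g.id))
                return category_for_biotype(best.biotype)
            return "antisense"
        best = max(exonic, key=lambda g: (sum(
            max(0, min(e.end, ge.end) - max(e.start, ge.start))
            for e in t.exons for ge in g.exons), g.id))
        return category_for_biotype(best.biotype)
    introns = t.introns
    for g in genes:
        if g.chrom != t.chrom:
            continue
        if g.exons and all(
            any(it.start <= ge.start and ge.end <= it.end for it in introns)
            for ge in g.exons
        ):
            return "novel_encompassing"
    def in_intron(e):
        for g in genes:
            if g.chrom != e.chrom:
                continue
            for it in g.introns:
                if it.start <= e.start and e.end <= it.end:
                    return True
        return False
    if all(in_intron(e) for e in t.exons):
        return "novel_intronic"
    def touches_span(e):
        return any(
            g.chrom == e.chrom and g.start < e.end and e.start < g.end
            for g in genes
        )
    if not any(touches_span(e) for e in t.exons):
        return "novel_intergenic"
    return "novel_interleaving"


def test_classification_matches_bruteforce_on_random_transcripts():
    rng = np.random.default_rng(0)
    genes = []
    pos = 1000
    for i in range(30):
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(1, 4))
        pairs, p = [], pos
        for _ in range(n_ex):
            w = int(rng.integers(100, 400))
            pairs.append((p, p + w))
            p += w + int(rng.integers(200, 2000))
        biotype = ["protein_coding", "lincRNA", "pseudogene"][i % 3]
        genes.append(GeneModel(f"g{i}", biotype, strand,
                               tuple(GenomicInterval("chr1", a, b, strand)
                                     for a, b in pairs)))
        pos = p + int(rng.integers(500, 3000))
    ref = ReferenceAnnotation(genes)
    mismatches = []
    for j in range(200):
        strand = rng.choice(["+", "-", "."])
        n_ex = int(rng.integers(1, 4))
        start = int(rng.integers(0, pos))
        pairs, p = [], start
        for _ in range(n_ex):
            w = int(rng.integers(80, 600))
            pairs.append((p, p + w))
            p += w + int(rng.integers(100, 3000))
        t = tx(f"t{j}", pairs, strand=str(strand))
        got, _ = classify_transcript(t, ref)
        want = _oracle_classify(t, genes)
        if got != want:
            mismatches.append((t.id, got, want))
    assert not mismatches, mismatches[:5]


# ---------------------------------------------------------------------------
# catalog assembly
# ---------------------------------------------------------------------------

def test_empty_bundle_gives_empty_catalog(toy_reference):
    cat = build_catalog([], toy_reference)
    assert len(cat) == 0


def test_catalog_categories_match_ground_truth(fixture_bundle, truth):
    models = merge_assemblies(fixture_bundle.assemblies)
    cat = build_catalog(models, fixture_bundle.reference, fixture_bundle.genome)
    # classification partitions the catalog
    assert int(cat.table["category"].value_counts().sum()) == len(cat)
    for tid, row in cat.table.iterrows():
        label = truth.at[tid, "label"]
        if label.startswith("novel_"):
            assert row["category"] == label, tid
        elif label == "annotated":
            gene_biotype = {
                "G_CODING": "protein_coding", "G_LNC": "annotated_ncRNA",
                "G_PSEUDO": "pseudogene", "G_AS": "antisense",
            }[tid.rsplit("_", 1)[0]]
            assert row["category"] == gene_biotype, tid


def test_catalog_gtf_round_trips_without_loss(fixture_bundle, tmp_path):
    models = merge_assemblies(fixture_bundle.assemblies)
    cat = build_catalog(models, fixture_bundle.reference, fixture_bundle.genome)
    cat.write(tmp_path)
    from lncskin.catalog import Catalog

    back = Catalog.read(tmp_path)
    assert len(back) == len(cat)
    for tid, m in cat.models.items():
        b = back.models[tid]
        assert [(e.start, e.end) for e in m.exons] == [(e.start, e.end) for e in b.exons]
        assert b.strand == m.strand
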