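"""Consensus transcript catalog: meta-assembly merging and classification.

Per-sample assemblies are merged into consensus transcript models (identical
intron chain for multi-exon transcripts; >= 1 bp overlap for mono-exon ones),
strand is inferred from canonical GT..AG splice motifs where the assembler
left it unknown, and every consensus transcript is classified against the
reference annotation into one of eight categories:

* annotated: protein_coding, pseudogene, annotated_ncRNA, antisense
* novel (no exonic overlap with the reference): intronic, intergenic,
  interleaving, encompassing

Category precedence when several definitions could match: same-strand
annotated exonic overlap > antisense > encompassing > intronic >
interleaving > intergenic.  "Encompassing" requires a reference gene whose
exons all fall within the intron space of the consensus transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import io as lio
from .core import (
    GenomicInterval,
    ReferenceAnnotation,
    TranscriptModel,
    category_for_biotype,
)
from .synthetic_data import AssemblyBundle


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def merge_assemblies(bundle: AssemblyBundle | Mapping[str, list[TranscriptModel]]) -> list[TranscriptModel]:
    """Merge per-sample transcript models into consensus models.

    Multi-exon transcripts merge when they share chromosome, strand and an
    identical intron chain; mono-exon transcripts merge when they overlap by
    at least 1 bp on the same chromosome and strand.  Consensus exons are the
    union of the merged exon footprints and sample presence is the union of
    contributing samples.  The result is independent of sample input order.
    """
    per_sample = bundle.per_sample if isinstance(bundle, AssemblyBundle) else bundle
    multi: dict[tuple, list[TranscriptModel]] = {}
    mono: dict[tuple, list[TranscriptModel]] = {}
    for sample in sorted(per_sample):
        for tx in per_sample[sample]:
            if len(tx.exons) >= 2:
                key = (tx.chrom, tx.strand, tx.intron_chain())
                multi.setdefault(key, []).append(tx)
            else:
                mono.setdefault((tx.chrom, tx.strand), []).append(tx)

    out: list[TranscriptModel] = []
    for key in sorted(multi, key=lambda k: (k[0], k[1], k[2])):
        out.append(_consensus(multi[key]))
    for key in sorted(mono):
        txs = sorted(mono[key], key=lambda t: (t.start, t.end, t.id))
        cluster: list[TranscriptModel] = []
        cluster_end = None
        for tx in txs:
            if cluster and tx.start < cluster_end:
                cluster.append(tx)
                cluster_end = max(cluster_end, tx.end)
            else:
                if cluster:
                    out.append(_consensus(cluster))
                cluster = [tx]
                cluster_end = tx.end
        if cluster:
            out.append(_consensus(cluster))
    out.sort(key=lambda t: (t.chrom, t.start, t.end, t.id))
    ids = [t.id for t in out]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate consensus transcript ids: {dupes[:5]}")
    return out


def _consensus(members: list[TranscriptModel]) -> TranscriptModel:
    ids = sorted({m.id for m in members})
    cid = ids[0] if len(ids) == 1 else "|".join(ids)
    presence = frozenset().union(*(m.sample_presence for m in members))
    chrom = members[0].chrom
    strand = members[0].strand
    # union of exon footprints; identical intron chains keep gaps intact
    points = sorted(
        (e.start, e.end) for m in members for e in m.exons
    )
    merged: list[list[int]] = []
    for s, e in points:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    exons = tuple(GenomicInterval(chrom, s, e, strand) for s, e in merged)
    return TranscriptModel(cid, exons, strand=strand, sample_presence=presence)


# ---------------------------------------------------------------------------
# Strand inference from splice motifs
# ---------------------------------------------------------------------------

def infer_strand(tx: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Predict strand from canonical splice motifs; applies to >= 2 exons only.

    Returns '+' when every intron reads GT..AG on the forward genomic strand,
    '-' when every intron's reverse complement does (forward CT..AC), and '.'
    otherwise or for mono-exon transcripts.
    """
    if len(tx.exons) < 2:
        return "."
    seq = genome[tx.chrom]
    chrom_len = len(seq)
    if tx.end > chrom_len:
        raise ValueError(
            f"{tx.id}: exon end {tx.end} beyond chromosome {tx.chrom} "
            f"length {chrom_len}"
        )
    fwd = True
    rev = True
    for intron in tx.introns:
        donor = str(seq[intron.start : intron.start + 2]).upper()
        acceptor = str(seq[intron.end - 2 : intron.end]).upper()
        if not (donor == "GT" and acceptor == "AG"):
            fwd = False
        if not (donor == "CT" and acceptor == "AC"):
            rev = False
    if fwd and not rev:
        return "+"
    if rev and not fwd:
        return "-"
    return "."


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_transcript(
    tx: TranscriptModel, ref: ReferenceAnnotation
) -> tuple[str, bool]:
    """Classify one transcript; returns (category, location_only_flag).

    The flag marks unknown-strand transcripts whose exons overlap reference
    exons: they are labelled by location only and antisense is never
    assigned without strand.
    """
    overlapping = []
    for e in tx.exons:
        overlapping.extend(ref.exons_overlapping(e))
    overlapping = {g.id: g for g in overlapping}.values()

    if overlapping:
        if tx.strand in ("+", "-"):
            same = [g for g in overlapping if g.strand == tx.strand]
            if same:
                best = max(same, key=lambda g: (_exonic_overlap(tx, g), g.id))
                return category_for_biotype(best.biotype), False
            return "antisense", False
        best = max(overlapping, key=lambda g: (_exonic_overlap(tx, g), g.id))
        return category_for_biotype(best.biotype), True

    # novel: no exonic overlap with the reference at all
    if _has_encompassed_gene(tx, ref):
        return "novel_encompassing", False
    all_intronic = all(
        any(any(it.contains(e) for it in g.introns) for g in ref.introns_overlapping(e))
        for e in tx.exons
    )
    if all_intronic:
        return "novel_intronic", False
    if not any(ref.spans_overlapping(e) for e in tx.exons):
        return "novel_intergenic", False
    return "novel_interleaving", False


def _exonic_overlap(tx: TranscriptModel, gene) -> int:
    total = 0
    for e in tx.exons:
        for ge in gene.exons:
            total += max(0, min(e.end, ge.end) - max(e.start, ge.start))
    return total


def _has_encompassed_gene(tx: TranscriptModel, ref: ReferenceAnnotation) -> bool:
    if len(tx.exons) < 2:
        return False
    introns = tx.introns
    for g in ref.spans_overlapping(tx.span):
        if all(any(it.contains(ge) for it in introns) for ge in g.exons):
            return True
    return False


# ---------------------------------------------------------------------------
# Catalog assembly
# ---------------------------------------------------------------------------

@dataclass
class Catalog:
    """Consensus transcripts with category labels, serializable to GTF + TSV."""

    table: pd.DataFrame
    models: dict[str, TranscriptModel] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, ids: Iterable[str]) -> "Catalog":
        ids = list(ids)
        return Catalog(
            self.table.loc[ids].copy(), {i: self.models[i] for i in ids}
        )

    def categories(self) -> pd.Series:
        return self.table["category"]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        lio.write_tsv(self.table.reset_index(), outdir / "catalog.tsv")
        lio.write_transcript_gtf(
            [self.models[i] for i in self.table.index], outdir / "catalog.gtf"
        )

    @classmethod
    def read(cls, outdir: str | Path) -> "Catalog":
        outdir = Path(outdir)
        table = lio.read_tsv(outdir / "catalog.tsv").set_index("transcript_id")
        models = {}
        for tx in lio.read_transcript_gtf(outdir / "catalog.gtf"):
            models[tx.id] = tx
        presence = table["n_samples"].to_dict()
        for tid, tx in models.items():
            # sample identities are not stored in the GTF; keep counts only
            tx.sample_presence = frozenset(
                f"s{i}" for i in range(int(presence.get(tid, 0)))
            )
        return cls(table, models)


def build_catalog(
    models: Iterable[TranscriptModel],
    ref: ReferenceAnnotation,
    genome: Mapping[str, str] | None = None,
) -> Catalog:
    """Classify consensus models and assemble the catalog table."""
    rows = []
    kept: dict[str, TranscriptModel] = {}
    for tx in models:
        if tx.id in kept:
            raise ValueError(f"duplicate consensus id {tx.id}")
        strand = tx.strand
        if strand == "." and len(tx.exons) >= 2 and genome is not None:
            strand = infer_strand(tx, genome)
            if strand != ".":
                tx = TranscriptModel(
                    tx.id, tx.exons, strand=strand, sample_presence=tx.sample_presence
                )
        category, location_only = classify_transcript(tx, ref)
        kept[tx.id] = tx
        rows.append(
            {
                "transcript_id": tx.id,
                "category": category,
                "chrom": tx.chrom,
                "start": tx.start,
                "end": tx.end,
                "strand": tx.strand,
                "n_exons": len(tx.exons),
                "mature_length": tx.mature_length,
                "n_samples": len(tx.sample_presence),
                "location_only": location_only,
            }
        )
    if not rows:
        table = pd.DataFrame(
            columns=[
                "transcript_id",
                "category",
                "chrom",
                "start",
                "end",
                "strand",
                "n_exons",
                "mature_length",
                "n_samples",
                "location_only",
            ]
        ).set_index("transcript_id")
        return Catalog(table, {})
    table = pd.DataFrame(rows).set_index("transcript_id")
    return Catalog(table, kept)
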