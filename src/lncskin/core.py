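"""Core genomic domain types shared across the pipeline.

Coordinates are 0-based half-open internally; conversion to/from the 1-based
inclusive GTF convention happens only at I/O boundaries (:mod:`lncskin.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

# Transcript categories used throughout the pipeline.  The first four cover
# transcripts matching the reference annotation; the last four are subtypes of
# unannotated (novel) transcripts defined by where their exons fall relative
# to reference gene structure.
ANNOTATED_CATEGORIES = (
    "protein_coding",
    "pseudogene",
    "annotated_ncRNA",
    "antisense",
)
NOVEL_CATEGORIES = (
    "novel_intronic",
    "novel_intergenic",
    "novel_interleaving",
    "novel_encompassing",
)
ALL_CATEGORIES = ANNOTATED_CATEGORIES + NOVEL_CATEGORIES

#: reference biotypes folded into the annotated_ncRNA category
NONCODING_BIOTYPES = frozenset({"lincRNA", "lncRNA", "ncRNA", "misc_RNA"})

#: categories counted as lncRNA when reporting the expressed-lncRNA set
LNCRNA_CATEGORIES = ("annotated_ncRNA",) + NOVEL_CATEGORIES


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded interval on a chromosome (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval start must precede end: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def _check_exons(exons: Sequence[GenomicInterval]) -> tuple[GenomicInterval, ...]:
    if not exons:
        raise ValueError("at least one exon required")
    exons = tuple(sorted(exons, key=lambda e: e.start))
    chroms = {e.chrom for e in exons}
    if len(chroms) != 1:
        raise ValueError(f"exons span multiple chromosomes: {sorted(chroms)}")
    for a, b in zip(exons, exons[1:]):
        if b.start < a.end:
            raise ValueError(f"overlapping exons at {a.chrom}:{a.end}>{b.start}")
    return exons


@dataclass
class TranscriptModel:
    """A stranded, exon-structured transcript assembled from RNA-seq samples."""

    id: str
    exons: tuple[GenomicInterval, ...]
    strand: str = "."
    sample_presence: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.exons = _check_exons(self.exons)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def mature_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return tuple(out)

    @property
    def tss(self) -> int:
        """Strand-aware 5' start; leftmost coordinate when strand is unknown."""
        return self.end - 1 if self.strand == "-" else self.start

    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple((i.start, i.end) for i in self.introns)


@dataclass
class GeneModel:
    """A reference gene: biotype, strand and exon set (union over isoforms)."""

    id: str
    biotype: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        self.exons = _check_exons(self.exons)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return tuple(out)

    @property
    def tss(self) -> int:
        return self.end - 1 if self.strand == "-" else self.start


class _IntervalIndex:
    """Sorted-array interval index supporting overlap and nearest-gap queries."""

    def __init__(self, intervals: Iterable[tuple[int, int, int]]):
        # intervals: (start, end, payload-index)
        items = sorted(intervals)
        self.starts = np.array([i[0] for i in items], dtype=np.int64)
        self.ends = np.array([i[1] for i in items], dtype=np.int64)
        self.payload = np.array([i[2] for i in items], dtype=np.int64)
        # running max of ends enables overlap scans on sorted starts
        self.max_ends = (
            np.maximum.accumulate(self.ends) if len(self.ends) else self.ends
        )

    def __len__(self) -> int:
        return len(self.starts)

    def overlapping(self, start: int, end: int) -> np.ndarray:
        """Payload indices of intervals overlapping [start, end)."""
        if len(self.starts) == 0:
            return np.empty(0, dtype=np.int64)
        hi = np.searchsorted(self.starts, end, side="left")
        cand = slice(0, hi)
        mask = self.ends[cand] > start
        return self.payload[cand][mask]

    def nearest_gap(self, start: int, end: int, exclude: set[int] | None = None) -> int:
        """Minimum bp gap from [start, end) to any indexed interval (0 if overlap)."""
        best = np.iinfo(np.int64).max
        for s, e, p in zip(self.starts, self.ends, self.payload):
            if exclude and int(p) in exclude:
                continue
            if s < end and start < e:
                return 0
            # half-open: gap between [a,b) and [c,d) with c >= b is c-b
            gap = s - end if s >= end else start - e
            best = min(best, gap)
        return int(best)


class ReferenceAnnotation:
    """Indexed reference gene annotation used for classification and filtering."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: list[GeneModel] = list(genes)
        ids = [g.id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids in reference annotation")
        self.by_id = {g.id: g for g in self.genes}
        self._exon_idx: dict[str, _IntervalIndex] = {}
        self._span_idx: dict[str, _IntervalIndex] = {}
        self._intron_idx: dict[str, _IntervalIndex] = {}
        per_chrom_exons: dict[str, list] = {}
        per_chrom_spans: dict[str, list] = {}
        per_chrom_introns: dict[str, list] = {}
        for gi, g in enumerate(self.genes):
            per_chrom_spans.setdefault(g.chrom, []).append((g.start, g.end, gi))
            for e in g.exons:
                per_chrom_exons.setdefault(g.chrom, []).append((e.start, e.end, gi))
            for it in g.introns:
                per_chrom_introns.setdefault(g.chrom, []).append((it.start, it.end, gi))
        for chrom, items in per_chrom_exons.items():
            self._exon_idx[chrom] = _IntervalIndex(items)
        for chrom, items in per_chrom_spans.items():
            self._span_idx[chrom] = _IntervalIndex(items)
        for chrom, items in per_chrom_introns.items():
            self._intron_idx[chrom] = _IntervalIndex(items)

    def genes_with_biotype(self, biotype: str) -> list[GeneModel]:
        return [g for g in self.genes if g.biotype == biotype]

    def exons_overlapping(self, iv: GenomicInterval) -> list[GeneModel]:
        idx = self._exon_idx.get(iv.chrom)
        if idx is None:
            return []
        gis = sorted(set(int(i) for i in idx.overlapping(iv.start, iv.end)))
        return [self.genes[i] for i in gis]

    def spans_overlapping(self, iv: GenomicInterval) -> list[GeneModel]:
        idx = self._span_idx.get(iv.chrom)
        if idx is None:
            return []
        gis = sorted(set(int(i) for i in idx.overlapping(iv.start, iv.end)))
        return [self.genes[i] for i in gis]

    def introns_overlapping(self, iv: GenomicInterval) -> list[GeneModel]:
        idx = self._intron_idx.get(iv.chrom)
        if idx is None:
            return []
        gis = sorted(set(int(i) for i in idx.overlapping(iv.start, iv.end)))
        return [self.genes[i] for i in gis]

    def exon_arrays(self, chrom: str):
        """(starts, ends, gene_index) arrays of reference exons on a chromosome."""
        idx = self._exon_idx.get(chrom)
        if idx is None:
            return (
                np.empty(0, dtype=np.int64),
                np.empty(0, dtype=np.int64),
                np.empty(0, dtype=np.int64),
            )
        return idx.starts, idx.ends, idx.payload


def category_for_biotype(biotype: str) -> str:
    """Map a reference biotype to the pipeline's annotated category label."""
    if biotype == "protein_coding":
        return "protein_coding"
    if biotype == "pseudogene":
        return "pseudogene"
    if biotype == "antisense":
        return "antisense"
    if biotype in NONCODING_BIOTYPES:
        return "annotated_ncRNA"
    return "annotated_ncRNA"
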