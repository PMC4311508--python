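"""File-format boundaries: GTF, FASTA, bedGraph/wiggle, BED and TSV.

GTF is 1-based inclusive on disk; everything in memory is 0-based half-open.
pyranges handles the conversion for GTF; the simple tabular formats are read
with pandas.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pyranges as pr

from .core import GeneModel, GenomicInterval, ReferenceAnnotation, TranscriptModel

GTF_SOURCE = "lncskin"


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_reference_gtf(path: str | os.PathLike) -> ReferenceAnnotation:
    """Read a reference annotation GTF into an indexed :class:`ReferenceAnnotation`.

    Exon features are grouped by ``gene_id``; the biotype is taken from the
    ``gene_biotype`` attribute.
    """
    df = pr.read_gtf(str(path)).df
    df = df[df["Feature"] == "exon"]
    if df.empty:
        return ReferenceAnnotation([])
    if "gene_biotype" not in df.columns:
        raise ValueError(f"{path}: reference GTF lacks gene_biotype attributes")
    genes = []
    for gene_id, sub in df.groupby("gene_id", sort=True):
        strand = sub["Strand"].iloc[0]
        biotype = sub["gene_biotype"].iloc[0]
        chrom = sub["Chromosome"].iloc[0]
        exons = _merge_touching(
            [
                GenomicInterval(str(chrom), int(s), int(e), str(strand))
                for s, e in zip(sub["Start"], sub["End"])
            ]
        )
        genes.append(GeneModel(str(gene_id), str(biotype), str(strand), tuple(exons)))
    return ReferenceAnnotation(genes)


def _merge_touching(exons: list[GenomicInterval]) -> list[GenomicInterval]:
    exons = sorted(exons, key=lambda e: e.start)
    out = [exons[0]]
    for e in exons[1:]:
        last = out[-1]
        if e.start <= last.end:
            out[-1] = GenomicInterval(last.chrom, last.start, max(last.end, e.end), last.strand)
        else:
            out.append(e)
    return out


def write_reference_gtf(ref: ReferenceAnnotation, path: str | os.PathLike) -> None:
    rows = []
    for g in ref.genes:
        for e in g.exons:
            rows.append(
                {
                    "Chromosome": g.chrom,
                    "Source": GTF_SOURCE,
                    "Feature": "exon",
                    "Start": e.start,
                    "End": e.end,
                    "Strand": g.strand,
                    "gene_id": g.id,
                    "transcript_id": g.id,
                    "gene_biotype": g.biotype,
                }
            )
    _write_gtf_rows(rows, path)


def _write_gtf_rows(rows: list[dict], path: str | os.PathLike) -> None:
    if not rows:
        with open(path, "w") as fh:
            fh.write("")
        return
    df = pd.DataFrame(rows)
    df = df.sort_values(["Chromosome", "Start", "End", "transcript_id"], kind="mergesort")
    pr.PyRanges(df).to_gtf(str(path))


def read_transcript_gtf(
    path: str | os.PathLike, sample_id: str | None = None
) -> list[TranscriptModel]:
    """Read exon-level transcript models (e.g. one sample's assembly) from GTF."""
    df = pr.read_gtf(str(path)).df
    if df.empty:
        return []
    df = df[df["Feature"] == "exon"]
    presence = frozenset([sample_id]) if sample_id else frozenset()
    out = []
    for tid, sub in df.groupby("transcript_id", sort=True):
        strand = str(sub["Strand"].iloc[0])
        exons = tuple(
            GenomicInterval(str(c), int(s), int(e), strand)
            for c, s, e in zip(sub["Chromosome"], sub["Start"], sub["End"])
        )
        out.append(
            TranscriptModel(str(tid), exons, strand=strand, sample_presence=presence)
        )
    return out


def write_transcript_gtf(
    transcripts: Iterable[TranscriptModel], path: str | os.PathLike
) -> None:
    rows = []
    for tx in transcripts:
        for e in tx.exons:
            rows.append(
                {
                    "Chromosome": tx.chrom,
                    "Source": GTF_SOURCE,
                    "Feature": "exon",
                    "Start": e.start,
                    "End": e.end,
                    "Strand": tx.strand,
                    "gene_id": tx.id,
                    "transcript_id": tx.id,
                }
            )
    _write_gtf_rows(rows, path)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Coverage tracks: bedGraph and fixed-step wiggle
# ---------------------------------------------------------------------------

class Track:
    """Piecewise-constant genome track (mappability scores, densities...)."""

    def __init__(self, data: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # per chromosome: (starts, ends, values), sorted, non-overlapping
        self.data = {c: tuple(np.asarray(a) for a in v) for c, v in data.items()}

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean value over [start, end); uncovered bases score 0."""
        if end <= start:
            raise ValueError("empty interval")
        total = 0.0
        if chrom in self.data:
            starts, ends, values = self.data[chrom]
            for s, e, v in zip(starts, ends, values):
                lo, hi = max(int(s), start), min(int(e), end)
                if lo < hi:
                    total += float(v) * (hi - lo)
        return total / (end - start)


def read_track(path: str | os.PathLike) -> Track:
    """Read a bedGraph or fixed-step wiggle file into a :class:`Track`."""
    data: dict[str, list[tuple[int, int, float]]] = {}
    mode = "bedgraph"
    chrom, pos, step, span = "", 0, 1, 1
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            if line.startswith("fixedStep"):
                mode = "fixedstep"
                kv = dict(f.split("=") for f in line.split()[1:])
                chrom = kv["chrom"]
                pos = int(kv["start"]) - 1  # wiggle is 1-based
                step = int(kv.get("step", 1))
                span = int(kv.get("span", step))
                continue
            if mode == "fixedstep":
                data.setdefault(chrom, []).append((pos, pos + span, float(line)))
                pos += step
            else:
                f = line.split("\t")
                data.setdefault(f[0], []).append((int(f[1]), int(f[2]), float(f[3])))
    out = {}
    for c, items in data.items():
        items.sort()
        out[c] = (
            np.array([i[0] for i in items], dtype=np.int64),
            np.array([i[1] for i in items], dtype=np.int64),
            np.array([i[2] for i in items], dtype=float),
        )
    return Track(out)


def write_bedgraph(track: Track, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            starts, ends, values = track.data[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v:g}\n")


# ---------------------------------------------------------------------------
# BED (chromatin-state segmentations)
# ---------------------------------------------------------------------------

def read_bed_states(path: str | os.PathLike) -> pd.DataFrame:
    """Read a 4+ column BED of labelled states (chrom, start, end, state)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "state"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "state": str},
    )
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def write_bed_states(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[["chrom", "start", "end", "state"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# TSV helpers
# ---------------------------------------------------------------------------

def read_tsv(path: str | os.PathLike, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
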