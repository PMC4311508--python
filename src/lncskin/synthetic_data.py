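"""Seeded synthetic fixtures with the structure the pipeline assumes.

The generator emulates a skin RNA-seq cohort of 99 lesional (PP), 27
uninvolved (PN) and 90 normal (NN) biopsies at desk scale: a small genome
(two chromosomes of a few Mb) carrying annotated protein-coding, lincRNA,
pseudogene and antisense genes, planted novel transcripts of the four
location-defined subtypes, and planted artifacts targeted by each QC filter
(premature-mRNA fragments near annotated exons, transcripts in
low-mappability windows, sub-200-bp transcripts).

Everything is deterministic given the configuration (including the seed):
the same config yields byte-identical files.  Ground truth for every planted
entity is emitted in sidecar tables so tests can act as exact oracles.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .core import GeneModel, GenomicInterval, ReferenceAnnotation, TranscriptModel
from .de import CountsMatrix

CELL_LINES = (
    "GM12878",
    "H1-hESC",
    "K562",
    "HepG2",
    "HUVEC",
    "HMEC",
    "HSMM",
    "NHEK",
    "NHLF",
)
ECTODERMAL_LINES = ("NHEK", "HMEC")

NOVEL_SUBTYPES = ("intronic", "intergenic", "interleaving", "encompassing")
ARTIFACT_LABELS = ("artifact_premature", "artifact_lowmap", "artifact_short")


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of the synthetic study; defaults mirror the emulated cohort."""

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length_bp: int = 3_000_000
    n_coding_genes: int = 80
    n_annotated_lncRNAs: int = 30
    n_pseudogenes: int = 12
    n_antisense: int = 8
    n_novel_per_subtype: int = 5
    n_artifacts_premature: int = 6
    n_artifacts_lowmap: int = 6
    n_artifacts_short: int = 6
    n_samples_NN: int = 90
    n_samples_PN: int = 27
    n_samples_PP: int = 99
    de_fraction: float = 0.15
    de_log2fc_range: tuple[float, float] = (1.5, 3.0)
    nb_dispersion: float = 0.05
    n_tissues: int = 17
    skin_specific_fraction: float = 0.8
    n_ontology_terms: int = 24
    terms_per_gene: int = 2
    # presence of planted transcripts across sample assemblies
    annotated_presence_fraction: float = 0.95
    novel_presence_fraction: float = 0.5
    artifact_presence_fraction: float = 0.3
    novel_presence_fractions: tuple[float, ...] | None = None
    # chromatin segmentation sizing
    n_enhancers_base: int = 60
    n_promoters_base: int = 40
    # lncRNAs planted to co-express with an ontology module
    n_lnc_coexpressed: int = 10
    module_sd: float = 0.8

    def __post_init__(self) -> None:
        for name in (
            "n_chromosomes",
            "chrom_length_bp",
            "n_samples_NN",
            "n_samples_PN",
            "n_samples_PP",
            "n_tissues",
            "n_ontology_terms",
            "terms_per_gene",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "n_coding_genes",
            "n_annotated_lncRNAs",
            "n_pseudogenes",
            "n_antisense",
            "n_novel_per_subtype",
            "n_artifacts_premature",
            "n_artifacts_lowmap",
            "n_artifacts_short",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("de_fraction", "skin_specific_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        needed_hosts = (
            2 * self.n_novel_per_subtype  # intronic + interleaving hosts
            + self.n_novel_per_subtype  # encompassing nested genes
            + self.n_artifacts_premature
            + self.n_antisense
        )
        if self.n_coding_genes < needed_hosts:
            raise ValueError(
                f"n_coding_genes={self.n_coding_genes} too small: "
                f"{needed_hosts} coding genes are consumed as hosts for planted "
                "novel transcripts, antisense pairs and premature artifacts"
            )

    @property
    def n_samples(self) -> int:
        return self.n_samples_NN + self.n_samples_PN + self.n_samples_PP

    @property
    def sample_ids(self) -> tuple[str, ...]:
        out = []
        for grp, n in (
            ("NN", self.n_samples_NN),
            ("PN", self.n_samples_PN),
            ("PP", self.n_samples_PP),
        ):
            out.extend(f"{grp}_{i + 1:03d}" for i in range(n))
        return tuple(out)

    @property
    def sample_groups(self) -> pd.Series:
        return pd.Series(
            {s: s.split("_")[0] for s in self.sample_ids}, name="group"
        )


@dataclass
class PlantedTranscript:
    """Ground truth for one planted unannotated transcript."""

    id: str
    label: str  # novel_* subtype or artifact_*
    strand: str
    exons: tuple[GenomicInterval, ...]
    presence_fraction: float
    distance_to_exon: int | None = None  # for premature artifacts

    @property
    def model(self) -> TranscriptModel:
        return TranscriptModel(self.id, self.exons, strand=self.strand)


@dataclass
class Layout:
    """Deterministic genomic plan shared by all generator operations."""

    chrom_names: tuple[str, ...]
    chrom_length: int
    genes: list[GeneModel]
    planted: list[PlantedTranscript]
    lowmap_windows: list[tuple[str, int, int]]

    @property
    def reference(self) -> ReferenceAnnotation:
        return ReferenceAnnotation(self.genes)

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for p in self.planted:
            m = p.model
            rows.append(
                {
                    "transcript_id": p.id,
                    "label": p.label,
                    "chrom": m.chrom,
                    "start": m.start,
                    "end": m.end,
                    "strand": p.strand,
                    "mature_length": m.mature_length,
                    "n_exons": len(p.exons),
                    "presence_fraction": p.presence_fraction,
                    "distance_to_exon": (
                        p.distance_to_exon if p.distance_to_exon is not None else -1
                    ),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Slot templates: relative exon layouts guaranteeing the planted invariants
# (novel transcripts >= 2 kb from annotated exons, artifacts in range of their
# targeted filter, etc.)
# ---------------------------------------------------------------------------

_GAP = 3000  # inter-slot spacing; > the 2 kb premature-fragment distance


def _intervals(chrom: str, strand: str, offset: int, pairs) -> tuple[GenomicInterval, ...]:
    return tuple(
        GenomicInterval(chrom, offset + a, offset + b, strand) for a, b in pairs
    )


class _SlotBuilder:
    def __init__(self, config: FixtureConfig, rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        self.genes: list[GeneModel] = []
        self.planted: list[PlantedTranscript] = []
        self.lowmap: list[tuple[str, int, int]] = []
        self._counters: dict[str, int] = {}

    def _next(self, prefix: str) -> str:
        self._counters[prefix] = self._counters.get(prefix, 0) + 1
        return f"{prefix}_{self._counters[prefix]:04d}"

    def _strand(self) -> str:
        return "+" if self.rng.random() < 0.5 else "-"

    # each slot method places content at `offset` on `chrom` and returns width

    def coding_plain(self, chrom: str, offset: int) -> int:
        s = self._strand()
        exons = _intervals(chrom, s, offset, [(0, 200), (1200, 1400), (2600, 2800)])
        self.genes.append(GeneModel(self._next("G_CODING"), "protein_coding", s, exons))
        return 2800

    def lnc_plain(self, chrom: str, offset: int) -> int:
        s = self._strand()
        exons = _intervals(chrom, s, offset, [(0, 300), (1300, 1600)])
        self.genes.append(GeneModel(self._next("G_LNC"), "lincRNA", s, exons))
        return 1600

    def pseudogene(self, chrom: str, offset: int) -> int:
        s = self._strand()
        exons = _intervals(chrom, s, offset, [(0, 800)])
        self.genes.append(GeneModel(self._next("G_PSEUDO"), "pseudogene", s, exons))
        return 800

    def antisense_pair(self, chrom: str, offset: int) -> int:
        s = self._strand()
        anti = "-" if s == "+" else "+"
        host = _intervals(chrom, s, offset, [(0, 200), (1400, 1600)])
        self.genes.append(GeneModel(self._next("G_CODING"), "protein_coding", s, host))
        as_ex = _intervals(chrom, anti, offset, [(100, 700)])
        self.genes.append(GeneModel(self._next("G_AS"), "antisense", anti, as_ex))
        return 1600

    def intronic_host(self, chrom: str, offset: int) -> int:
        s = self._strand()
        host = _intervals(chrom, s, offset, [(0, 200), (9200, 9400)])
        self.genes.append(GeneModel(self._next("G_CODING"), "protein_coding", s, host))
        ns = self._strand()
        nov = _intervals(chrom, ns, offset, [(3600, 4000), (4600, 5000)])
        self.planted.append(
            PlantedTranscript(
                self._next("NOV_INTRONIC"),
                "novel_intronic",
                ns,
                nov,
                self._presence("novel"),
            )
        )
        return 9400

    def interleaving_host(self, chrom: str, offset: int) -> int:
        s = self._strand()
        host = _intervals(
            chrom, s, offset, [(0, 200), (3000, 3200), (12200, 12400)]
        )
        self.genes.append(GeneModel(self._next("G_CODING"), "protein_coding", s, host))
        ns = self._strand()
        nov = _intervals(chrom, ns, offset, [(5400, 5800), (14600, 15000)])
        self.planted.append(
            PlantedTranscript(
                self._next("NOV_INTERLEAVING"),
                "novel_interleaving",
                ns,
                nov,
                self._presence("novel"),
            )
        )
        return 15000

    def encompassing(self, chrom: str, offset: int) -> int:
        s = self._strand()
        nested = _intervals(chrom, s, offset, [(2700, 2900), (3500, 3700)])
        self.genes.append(
            GeneModel(self._next("G_CODING"), "protein_coding", s, nested)
        )
        ns = self._strand()
        nov = _intervals(chrom, ns, offset, [(0, 400), (6000, 6400)])
        self.planted.append(
            PlantedTranscript(
                self._next("NOV_ENCOMPASSING"),
                "novel_encompassing",
                ns,
                nov,
                self._presence("novel"),
            )
        )
        return 6400

    def intergenic_novel(self, chrom: str, offset: int) -> int:
        ns = self._strand()
        nov = _intervals(chrom, ns, offset, [(0, 400), (1000, 1400)])
        self.planted.append(
            PlantedTranscript(
                self._next("NOV_INTERGENIC"),
                "novel_intergenic",
                ns,
                nov,
                self._presence("novel"),
            )
        )
        return 1400

    def premature_artifact(self, chrom: str, offset: int) -> int:
        s = self._strand()
        host = _intervals(chrom, s, offset, [(0, 200), (1200, 1400)])
        self.genes.append(GeneModel(self._next("G_CODING"), "protein_coding", s, host))
        dist = int(self.rng.integers(300, 1800))
        art = _intervals(chrom, ".", offset, [(1400 + dist, 1800 + dist)])
        self.planted.append(
            PlantedTranscript(
                self._next("ART_PREM"),
                "artifact_premature",
                ".",
                art,
                self.cfg.artifact_presence_fraction,
                distance_to_exon=dist,
            )
        )
        return 1800 + dist

    def lowmap_artifact(self, chrom: str, offset: int) -> int:
        art = _intervals(chrom, ".", offset, [(0, 400)])
        self.planted.append(
            PlantedTranscript(
                self._next("ART_LOWMAP"),
                "artifact_lowmap",
                ".",
                art,
                self.cfg.artifact_presence_fraction,
            )
        )
        self.lowmap.append((chrom, offset, offset + 400))
        return 400

    def short_artifact(self, chrom: str, offset: int) -> int:
        art = _intervals(chrom, ".", offset, [(0, 150)])
        self.planted.append(
            PlantedTranscript(
                self._next("ART_SHORT"),
                "artifact_short",
                ".",
                art,
                self.cfg.artifact_presence_fraction,
            )
        )
        return 150

    _novel_counter = 0

    def _presence(self, kind: str) -> float:
        if kind == "novel" and self.cfg.novel_presence_fractions:
            fr = self.cfg.novel_presence_fractions
            v = fr[self._novel_counter % len(fr)]
            self._novel_counter += 1
            return v
        return self.cfg.novel_presence_fraction


@functools.lru_cache(maxsize=8)
def plan_layout(config: FixtureConfig) -> Layout:
    """Derive the full deterministic genomic plan from the configuration."""
    rng = np.random.default_rng([config.seed, 11])
    b = _SlotBuilder(config, rng)
    slots: list = []
    n_sub = config.n_novel_per_subtype
    n_hosted_coding = 3 * n_sub + config.n_artifacts_premature + config.n_antisense
    slots += [b.intronic_host] * n_sub
    slots += [b.interleaving_host] * n_sub
    slots += [b.encompassing] * n_sub
    slots += [b.intergenic_novel] * n_sub
    slots += [b.premature_artifact] * config.n_artifacts_premature
    slots += [b.lowmap_artifact] * config.n_artifacts_lowmap
    slots += [b.short_artifact] * config.n_artifacts_short
    slots += [b.antisense_pair] * config.n_antisense
    slots += [b.coding_plain] * (config.n_coding_genes - n_hosted_coding)
    slots += [b.lnc_plain] * config.n_annotated_lncRNAs
    slots += [b.pseudogene] * config.n_pseudogenes
    rng.shuffle(slots)

    chrom_names = tuple(f"chr{i + 1}" for i in range(config.n_chromosomes))
    margin = 5000
    cursors = {c: margin for c in chrom_names}
    ci = 0
    for slot in slots:
        placed = False
        for _ in range(config.n_chromosomes):
            chrom = chrom_names[ci % config.n_chromosomes]
            ci += 1
            offset = cursors[chrom]
            # widest slot is ~16 kb; require head room before placing
            if offset + 20000 + margin > config.chrom_length_bp:
                continue
            width = slot(chrom, offset)
            jitter = int(rng.integers(0, 1500))
            cursors[chrom] = offset + width + _GAP + jitter
            placed = True
            break
        if not placed:
            raise ValueError(
                f"chrom_length_bp={config.chrom_length_bp} too short to place "
                f"{len(slots)} gene/transcript slots on {config.n_chromosomes} "
                "chromosomes; increase chromosome length or reduce gene counts"
            )
    return Layout(
        chrom_names=chrom_names,
        chrom_length=config.chrom_length_bp,
        genes=sorted(b.genes, key=lambda g: (g.chrom, g.start, g.id)),
        planted=sorted(b.planted, key=lambda p: (p.exons[0].chrom, p.exons[0].start)),
        lowmap_windows=sorted(b.lowmap),
    )


# ---------------------------------------------------------------------------
# Reference annotation + genome
# ---------------------------------------------------------------------------

def generate_reference(config: FixtureConfig) -> tuple[ReferenceAnnotation, dict[str, str]]:
    """Reference gene annotation and a genome with canonical splice motifs.

    The genome is random sequence except that every intron of every planted
    multi-exon transcript (annotated or novel) carries the canonical GT..AG
    donor/acceptor motif on its transcribed strand, so splice-site strand
    inference works exactly as on real data.
    """
    layout = plan_layout(config)
    rng = np.random.default_rng([config.seed, 13])
    bases = np.frombuffer(b"ACGT", dtype="S1")
    genome = {
        c: bases[rng.integers(0, 4, layout.chrom_length)].copy()
        for c in layout.chrom_names
    }

    def stamp(chrom: str, strand: str, istart: int, iend: int) -> None:
        seq = genome[chrom]
        if strand == "+":
            seq[istart : istart + 2] = [b"G", b"T"]
            seq[iend - 2 : iend] = [b"A", b"G"]
        elif strand == "-":
            seq[istart : istart + 2] = [b"C", b"T"]
            seq[iend - 2 : iend] = [b"A", b"C"]

    for g in layout.genes:
        for it in g.introns:
            stamp(g.chrom, g.strand, it.start, it.end)
    for p in layout.planted:
        for it in p.model.introns:
            stamp(p.exons[0].chrom, p.strand, it.start, it.end)
    genome_str = {c: genome[c].tobytes().decode("ascii") for c in layout.chrom_names}
    return layout.reference, genome_str


# ---------------------------------------------------------------------------
# Per-sample assemblies
# ---------------------------------------------------------------------------

@dataclass
class AssemblyBundle:
    """Per-sample assembled transcript models plus the ground-truth sidecar."""

    per_sample: dict[str, list[TranscriptModel]]
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sample, models in self.per_sample.items():
            lio.write_transcript_gtf(models, outdir / f"{sample}.gtf")
        lio.write_tsv(self.truth, outdir / "assembly_truth.tsv")

    @classmethod
    def read(cls, outdir: str | Path) -> "AssemblyBundle":
        outdir = Path(outdir)
        per_sample = {}
        for p in sorted(outdir.glob("*.gtf")):
            per_sample[p.stem] = lio.read_transcript_gtf(p, sample_id=p.stem)
        truth = lio.read_tsv(outdir / "assembly_truth.tsv")
        return cls(per_sample, truth)


def generate_sample_assemblies(
    config: FixtureConfig,
    reference: ReferenceAnnotation,
    genome: dict[str, str] | None = None,
) -> AssemblyBundle:
    """One assembled transcript set per sample.

    Annotated genes are re-assembled in most samples; planted novel
    transcripts and artifacts appear in their configured fraction of samples.
    Mono-exon unannotated transcripts carry unknown strand, as an assembler
    without splice sites would report.
    """
    layout = plan_layout(config)
    rng = np.random.default_rng([config.seed, 17])
    samples = list(config.sample_ids)
    n = len(samples)

    entries: list[tuple[TranscriptModel, float, str]] = []
    for g in reference.genes:
        tx = TranscriptModel(g.id, g.exons, strand=g.strand)
        entries.append((tx, config.annotated_presence_fraction, "annotated"))
    for p in layout.planted:
        entries.append((p.model, p.presence_fraction, p.label))

    per_sample: dict[str, list[TranscriptModel]] = {s: [] for s in samples}
    truth_rows = []
    truth = layout.truth_table()
    presence_counts = {}
    for tx, frac, label in entries:
        n_present = int(round(frac * n))
        if n_present < 1:
            raise ValueError(
                f"presence fraction {frac} yields no samples for {tx.id}"
            )
        chosen = rng.choice(n, size=n_present, replace=False)
        for si in sorted(chosen):
            s = samples[si]
            per_sample[s].append(
                TranscriptModel(
                    tx.id, tx.exons, strand=tx.strand, sample_presence=frozenset([s])
                )
            )
        presence_counts[tx.id] = n_present
        if label == "annotated":
            truth_rows.append(
                {
                    "transcript_id": tx.id,
                    "label": "annotated",
                    "chrom": tx.chrom,
                    "start": tx.start,
                    "end": tx.end,
                    "strand": tx.strand,
                    "mature_length": tx.mature_length,
                    "n_exons": len(tx.exons),
                    "presence_fraction": frac,
                    "distance_to_exon": -1,
                }
            )
    truth = pd.concat([truth, pd.DataFrame(truth_rows)], ignore_index=True)
    truth["n_samples_present"] = truth["transcript_id"].map(presence_counts)
    truth = truth.sort_values("transcript_id").reset_index(drop=True)
    for s in per_sample:
        per_sample[s].sort(key=lambda t: (t.chrom, t.start, t.id))
    return AssemblyBundle(per_sample, truth)


# ---------------------------------------------------------------------------
# Mappability tracks
# ---------------------------------------------------------------------------

def simulate_mappability(config: FixtureConfig) -> tuple[lio.Track, lio.Track]:
    """Uniqueness (35-mer analogue) and alignability (75-mer analogue) tracks.

    Both score 1.0 genome-wide except over the planted low-mappability
    windows, which score 0.5 in both tracks.
    """
    layout = plan_layout(config)
    data: dict[str, list[tuple[int, int, float]]] = {}
    for chrom in layout.chrom_names:
        windows = [(s, e) for c, s, e in layout.lowmap_windows if c == chrom]
        segs = []
        pos = 0
        for s, e in sorted(windows):
            if pos < s:
                segs.append((pos, s, 1.0))
            segs.append((s, e, 0.5))
            pos = e
        if pos < layout.chrom_length:
            segs.append((pos, layout.chrom_length, 1.0))
        data[chrom] = segs
    arrays = {
        c: (
            np.array([x[0] for x in v], dtype=np.int64),
            np.array([x[1] for x in v], dtype=np.int64),
            np.array([x[2] for x in v], dtype=float),
        )
        for c, v in data.items()
    }
    return lio.Track(arrays), lio.Track(dict(arrays))


# ---------------------------------------------------------------------------
# Read counts
# ---------------------------------------------------------------------------

def gene_table(config: FixtureConfig) -> pd.DataFrame:
    """Catalog of all annotated genes plus planted transcripts for simulation."""
    layout = plan_layout(config)
    rows = []
    for g in layout.genes:
        rows.append(
            {
                "gene_id": g.id,
                "truth_category": _biotype_category(g.biotype),
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "length": sum(len(e) for e in g.exons),
            }
        )
    for p in layout.planted:
        m = p.model
        rows.append(
            {
                "gene_id": p.id,
                "truth_category": p.label,
                "chrom": m.chrom,
                "start": m.start,
                "end": m.end,
                "strand": p.strand,
                "length": m.mature_length,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id").sort_index()


def _biotype_category(biotype: str) -> str:
    from .core import category_for_biotype

    return category_for_biotype(biotype)


def simulate_counts(
    config: FixtureConfig,
    catalog: pd.DataFrame,
    module_assignments: dict[str, str] | None = None,
) -> tuple[CountsMatrix, pd.DataFrame]:
    """Negative-binomial read counts with planted DE genes and library sizes.

    ``catalog`` needs a ``length`` column indexed by gene id.  PP means carry
    the planted log2 fold changes; PN means equal NN means (the emulated
    cohort showed essentially no NN/PN differences).  Library-size
    multipliers span a >= 2-fold range.  Genes sharing a co-expression module
    (``module_assignments``) receive a shared per-sample latent factor so
    functional coherence holds.

    Returns the counts matrix and the ground-truth DE table (planted genes
    only; empty when ``de_fraction`` is 0).
    """
    if config.nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    rng = np.random.default_rng([config.seed, 19])
    genes = list(catalog.index)
    n_genes = len(genes)
    samples = list(config.sample_ids)
    groups = config.sample_groups
    n = len(samples)

    is_lnc = catalog["truth_category"].isin(
        ["annotated_ncRNA"] + [f"novel_{s}" for s in NOVEL_SUBTYPES]
    ).values if "truth_category" in catalog.columns else np.zeros(n_genes, bool)
    base = np.exp(rng.normal(np.log(80.0), 0.8, n_genes))
    base[is_lnc] = np.exp(rng.normal(np.log(15.0), 0.8, int(is_lnc.sum())))
    base = np.clip(base, 5.0, None)

    # geometric grid of library-size multipliers guarantees >= 2-fold spread
    mult = 0.65 * (2.2 ** (np.arange(n) / max(n - 1, 1)))
    rng.shuffle(mult)

    n_de = int(round(config.de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    lo, hi = config.de_log2fc_range
    l2fc = np.zeros(n_genes)
    if n_de:
        mags = rng.uniform(lo, hi, n_de)
        signs = rng.choice([-1.0, 1.0], n_de)
        l2fc[de_idx] = mags * signs

    group_arr = groups.loc[samples].values
    fc = np.ones((n_genes, n))
    fc[:, group_arr == "PP"] = 2.0 ** l2fc[:, None]

    latent = np.zeros((n_genes, n))
    if module_assignments:
        terms = sorted(set(module_assignments.values()))
        z = {t: rng.normal(0.0, config.module_sd, n) for t in terms}
        gi = {g: i for i, g in enumerate(genes)}
        for g, t in module_assignments.items():
            if g in gi:
                latent[gi[g]] = z[t]

    mu = base[:, None] * fc * np.exp(latent) * mult[None, :]
    alpha = config.nb_dispersion
    r = 1.0 / alpha
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)

    cm = CountsMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        groups=groups,
        lengths=catalog["length"].astype(int),
    )
    truth_de = pd.DataFrame(
        {
            "gene_id": [genes[i] for i in sorted(de_idx)],
            "log2fc": [l2fc[i] for i in sorted(de_idx)],
        }
    )
    return cm, truth_de


def simple_gene_table(n_genes: int, seed: int = 0) -> pd.DataFrame:
    """Minimal simulation catalog (ids + lengths) for counts-only fixtures."""
    rng = np.random.default_rng([seed, 23])
    lengths = rng.integers(400, 4000, n_genes)
    return pd.DataFrame(
        {
            "length": lengths,
            "truth_category": "protein_coding",
            "chrom": "chr1",
            "start": np.arange(n_genes) * 5000,
            "end": np.arange(n_genes) * 5000 + lengths,
            "strand": "+",
        },
        index=pd.Index([f"G{i + 1:05d}" for i in range(n_genes)], name="gene_id"),
    )


# ---------------------------------------------------------------------------
# Multi-tissue expression panel
# ---------------------------------------------------------------------------

TISSUE_NAMES = (
    "adipose", "adrenal", "brain", "breast", "colon", "heart", "kidney",
    "liver", "lung", "lymph_node", "ovary", "prostate", "muscle", "testis",
    "thyroid", "white_blood_cells",
)
SKIN_REPLICATES = ("skin_PN_1", "skin_PN_2", "skin_PN_3")


def simulate_tissue_panel(
    config: FixtureConfig, catalog: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """RPKM panel over 16 non-skin tissues plus three uninvolved-skin replicates.

    Returns the raw panel (genes x 19 columns; skin is averaged downstream)
    and the list of planted skin-specific gene ids (expression only in the
    skin replicate columns).
    """
    rng = np.random.default_rng([config.seed, 29])
    genes = list(catalog.index)
    n_genes = len(genes)
    cols = list(TISSUE_NAMES) + list(SKIN_REPLICATES)
    base = np.exp(rng.normal(np.log(10.0), 0.7, n_genes))
    vals = base[:, None] * np.exp(rng.normal(0.0, 0.5, (n_genes, len(cols))))

    cat = (
        catalog["truth_category"]
        if "truth_category" in catalog.columns
        else pd.Series("protein_coding", index=catalog.index)
    )
    novel_mask = cat.str.startswith("novel_").values
    novel_ids = [g for g, m in zip(genes, novel_mask) if m]
    n_spec = int(round(config.skin_specific_fraction * len(novel_ids)))
    spec_ids = sorted(
        rng.choice(novel_ids, size=n_spec, replace=False).tolist()
    ) if n_spec else []
    spec_set = set(spec_ids)
    for i, g in enumerate(genes):
        if g in spec_set:
            vals[i, : len(TISSUE_NAMES)] = 0.0
    panel = pd.DataFrame(vals, index=pd.Index(genes, name="gene_id"), columns=cols)
    return panel, spec_ids


# ---------------------------------------------------------------------------
# Chromatin-state segmentations
# ---------------------------------------------------------------------------

@dataclass
class SegmentationBundle:
    """Per-cell-line chromatin-state BED tables plus planted-element truth."""

    tracks: dict[str, pd.DataFrame]
    planted_enhancers: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for line, df in self.tracks.items():
            lio.write_bed_states(df, outdir / f"{line}.bed")
        lio.write_tsv(self.planted_enhancers, outdir / "segmentation_truth.tsv")

    @classmethod
    def read(cls, outdir: str | Path) -> "SegmentationBundle":
        outdir = Path(outdir)
        tracks = {
            p.stem: lio.read_bed_states(p) for p in sorted(outdir.glob("*.bed"))
        }
        truth = lio.read_tsv(outdir / "segmentation_truth.tsv")
        return cls(tracks, truth)


def simulate_segmentations(config: FixtureConfig) -> SegmentationBundle:
    """Chromatin-state BEDs for nine cell lines.

    The two ectodermally-derived lines (NHEK, HMEC) receive enhancers planted
    near the starts of the planted novel transcripts; element counts differ
    across cell lines by construction (enhancers: base + 6*i, promoters:
    base + 4*i for the i-th line).
    """
    layout = plan_layout(config)
    rng = np.random.default_rng([config.seed, 31])
    novel_starts = [
        (p.exons[0].chrom, p.model.start)
        for p in layout.planted
        if p.label.startswith("novel_")
    ]
    tracks = {}
    planted_rows = []
    for i, line in enumerate(CELL_LINES):
        n_enh = config.n_enhancers_base + 6 * i
        n_pro = config.n_promoters_base + 4 * i
        rows = []
        if line in ECTODERMAL_LINES:
            for chrom, start in novel_starts:
                d = int(rng.integers(200, 1500))
                s = max(0, start - d - 600)
                rows.append((chrom, s, s + 600, "Strong_Enhancer"))
                planted_rows.append(
                    {
                        "cell_line": line,
                        "chrom": chrom,
                        "start": s,
                        "end": s + 600,
                        "near_gene_start": start,
                    }
                )
        n_random_enh = n_enh - len([r for r in rows if r[3] == "Strong_Enhancer"])
        if n_random_enh < 0:
            raise ValueError(
                "n_enhancers_base too small for the planted ectodermal enhancers"
            )
        for _ in range(n_random_enh):
            chrom = layout.chrom_names[int(rng.integers(0, len(layout.chrom_names)))]
            s = int(rng.integers(0, layout.chrom_length - 600))
            rows.append((chrom, s, s + 600, "Strong_Enhancer"))
        for _ in range(n_pro):
            chrom = layout.chrom_names[int(rng.integers(0, len(layout.chrom_names)))]
            s = int(rng.integers(0, layout.chrom_length - 400))
            rows.append((chrom, s, s + 400, "Active_Promoter"))
        # filler states so the files look like real segmentations
        for _ in range(30):
            chrom = layout.chrom_names[int(rng.integers(0, len(layout.chrom_names)))]
            s = int(rng.integers(0, layout.chrom_length - 5000))
            rows.append((chrom, s, s + 5000, "Heterochrom"))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
        tracks[line] = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    return SegmentationBundle(tracks, pd.DataFrame(planted_rows))


# ---------------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------------

def simulate_ontology(
    config: FixtureConfig, catalog: pd.DataFrame
) -> tuple[list[tuple[str, str]], dict[str, set[str]], dict[str, str]]:
    """Rooted ontology DAG, coding-gene annotations, and module assignments.

    Returns ``(edges, annotations, modules)`` where ``edges`` are
    (child, parent) pairs forming a rooted acyclic graph, ``annotations``
    maps coding genes to their direct leaf terms (lncRNAs are left
    unannotated, as in real databases), and ``modules`` maps each annotated
    gene -- plus ``n_lnc_coexpressed`` planted lncRNAs -- to the single leaf
    term whose latent expression factor it shares in ``simulate_counts``.
    """
    rng = np.random.default_rng([config.seed, 37])
    root = "T_ROOT"
    n_mid = 4
    mids = [f"T_MID_{i + 1}" for i in range(n_mid)]
    leaves = [f"T_LEAF_{i + 1:03d}" for i in range(config.n_ontology_terms)]
    edges = [(m, root) for m in mids]
    for i, leaf in enumerate(leaves):
        edges.append((leaf, mids[i % n_mid]))
        if i % 5 == 0:  # occasional multi-parent term
            edges.append((leaf, mids[(i + 1) % n_mid]))

    cat = (
        catalog["truth_category"]
        if "truth_category" in catalog.columns
        else pd.Series("protein_coding", index=catalog.index)
    )
    coding = [g for g in catalog.index if cat[g] == "protein_coding"]
    lncs = [
        g
        for g in catalog.index
        if cat[g] == "annotated_ncRNA" or str(cat[g]).startswith("novel_")
    ]
    annotations: dict[str, set[str]] = {}
    modules: dict[str, str] = {}
    for i, g in enumerate(coding):
        primary = leaves[i % len(leaves)]
        extra = rng.choice(leaves, size=max(0, config.terms_per_gene - 1), replace=False)
        annotations[g] = {primary, *extra.tolist()}
        modules[g] = primary
    n_cox = min(config.n_lnc_coexpressed, len(lncs))
    chosen = sorted(rng.choice(lncs, size=n_cox, replace=False).tolist()) if n_cox else []
    for j, g in enumerate(chosen):
        modules[g] = leaves[j % len(leaves)]
    return edges, annotations, modules


# ---------------------------------------------------------------------------
# Orchestrated fixture bundle
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    """Everything a full pipeline run consumes, generated from one config."""

    config: FixtureConfig
    reference: ReferenceAnnotation
    genome: dict[str, str]
    assemblies: AssemblyBundle
    uniqueness: lio.Track
    alignability: lio.Track
    counts: CountsMatrix
    truth_de: pd.DataFrame
    tissue_panel: pd.DataFrame
    skin_specific: list[str]
    segmentations: SegmentationBundle
    ontology_edges: list[tuple[str, str]]
    annotations: dict[str, set[str]]
    modules: dict[str, str]
    catalog_truth: pd.DataFrame = field(default_factory=pd.DataFrame)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        lio.write_reference_gtf(self.reference, outdir / "reference.gtf")
        lio.write_fasta(self.genome, outdir / "genome.fa")
        self.assemblies.write(outdir / "assemblies")
        lio.write_bedgraph(self.uniqueness, outdir / "uniqueness.bedgraph")
        lio.write_bedgraph(self.alignability, outdir / "alignability.bedgraph")
        self.counts.write(
            outdir / "counts.tsv", outdir / "groups.tsv", outdir / "lengths.tsv"
        )
        lio.write_tsv(self.truth_de, outdir / "truth_de.tsv")
        self.tissue_panel.to_csv(outdir / "tissue_panel.tsv", sep="\t")
        pd.Series(self.skin_specific, name="gene_id").to_csv(
            outdir / "truth_skin_specific.tsv", sep="\t", index=False
        )
        self.segmentations.write(outdir / "segmentations")
        pd.DataFrame(self.ontology_edges, columns=["child", "parent"]).to_csv(
            outdir / "ontology_edges.tsv", sep="\t", index=False
        )
        rows = [
            {"gene_id": g, "term": t}
            for g in sorted(self.annotations)
            for t in sorted(self.annotations[g])
        ]
        pd.DataFrame(rows).to_csv(outdir / "gene2term.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"gene_id": g, "module": m} for g, m in sorted(self.modules.items())]
        ).to_csv(outdir / "truth_modules.tsv", sep="\t", index=False)
        lio.write_tsv(self.catalog_truth, outdir / "catalog_truth.tsv")


def generate_fixture(config: FixtureConfig) -> Fixture:
    """Run every generator stage in order and return the in-memory bundle."""
    reference, genome = generate_reference(config)
    assemblies = generate_sample_assemblies(config, reference, genome)
    uniq, align = simulate_mappability(config)
    catalog = gene_table(config)
    edges, annotations, modules = simulate_ontology(config, catalog)
    counts, truth_de = simulate_counts(config, catalog, module_assignments=modules)
    panel, skin_specific = simulate_tissue_panel(config, catalog)
    segmentations = simulate_segmentations(config)
    return Fixture(
        config=config,
        reference=reference,
        genome=genome,
        assemblies=assemblies,
        uniqueness=uniq,
        alignability=align,
        counts=counts,
        truth_de=truth_de,
        tissue_panel=panel,
        skin_specific=skin_specific,
        segmentations=segmentations,
        ontology_edges=edges,
        annotations=annotations,
        modules=modules,
        catalog_truth=catalog.reset_index(),
    )
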