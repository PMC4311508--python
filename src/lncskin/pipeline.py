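"""End-to-end orchestration: catalog -> filters -> DE -> tissue ->
proximity -> function inference -> region enrichment.

Each stage reads the serialized outputs of earlier stages, writes its own
TSVs under the output directory and records them in a manifest with sha256
checksums.  A rerun with ``resume=True`` skips stages whose outputs are
present and checksum-clean, and recomputes any stage whose files were
tampered with or removed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pyfaidx
import yaml

from . import catalog as cat_mod
from . import de as de_mod
from . import inference as inf_mod
from . import io as lio
from . import proximity as prox_mod
from . import qc as qc_mod
from . import regions as reg_mod
from . import tissue as tis_mod
from .synthetic_data import AssemblyBundle, SegmentationBundle, ECTODERMAL_LINES

logger = logging.getLogger(__name__)

STAGES = (
    "catalog",
    "filter",
    "de",
    "tissue",
    "proximity",
    "infer",
    "regions",
)


@dataclass
class PipelineConfig:
    """Paths and thresholds for one full run."""

    input_dir: str
    output_dir: str
    seed: int = 0
    min_fraction: float = 0.05
    distance_threshold: float = 2000.0
    min_mappability: float = 0.9
    min_length: int = 200
    de_max_fdr: float = 0.1
    de_min_abs_log2fc: float = 1.0
    expressed_rpkm: float = 0.1
    elnc_window: float = 5000.0
    rho2_cutoff: float = 0.5
    beta: float = 5.0
    n_samplings: int = 10_000
    loci_file: str | None = None
    comparisons: tuple[tuple[str, str], ...] = (
        ("NN", "PP"),
        ("PN", "PP"),
        ("NN", "PN"),
    )

    def __post_init__(self) -> None:
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")
        if self.distance_threshold < 0 or self.min_length < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0 <= self.de_max_fdr <= 1:
            raise ValueError("de_max_fdr must be in [0, 1]")
        if not Path(self.input_dir).is_dir():
            raise FileNotFoundError(f"input directory missing: {self.input_dir}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "comparisons" in raw:
            raw["comparisons"] = tuple(
                tuple(c.split(":")) for c in raw["comparisons"]
            )
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data: dict[str, dict[str, str]] = {}
        if path.exists():
            self.data = json.loads(path.read_text())

    def stage_clean(self, stage: str, outdir: Path) -> bool:
        files = self.data.get(stage)
        if not files:
            return False
        for rel, digest in files.items():
            p = outdir / rel
            if not p.exists() or _sha256(p) != digest:
                return False
        return True

    def record(self, stage: str, outdir: Path, files: list[Path]) -> None:
        self.data[stage] = {
            str(p.relative_to(outdir)): _sha256(p) for p in files
        }
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict:
    """Execute all stages in order; returns a summary of headline numbers."""
    ind = Path(config.input_dir)
    outd = Path(config.output_dir)
    outd.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(outd / "manifest.json")
    summary: dict = {}

    # --- stage 1: consensus catalog --------------------------------------
    stage_dir = outd / "catalog"
    if not (resume and manifest.stage_clean("catalog", outd)):
        logger.info("stage catalog: merging assemblies and classifying")
        reference = lio.read_reference_gtf(ind / "reference.gtf")
        genome = pyfaidx.Fasta(str(ind / "genome.fa"))
        bundle = AssemblyBundle.read(ind / "assemblies")
        consensus = cat_mod.merge_assemblies(bundle)
        catalog = cat_mod.build_catalog(consensus, reference, genome)
        catalog.write(stage_dir)
        manifest.record(
            "catalog", outd, [stage_dir / "catalog.tsv", stage_dir / "catalog.gtf"]
        )
    reference = lio.read_reference_gtf(ind / "reference.gtf")
    catalog = cat_mod.Catalog.read(stage_dir)
    summary["n_raw_transcripts"] = len(catalog)

    # --- stage 2: QC cascade ---------------------------------------------
    stage_dir = outd / "filter"
    counts = de_mod.CountsMatrix.read(
        ind / "counts.tsv", ind / "groups.tsv", ind / "lengths.tsv"
    )
    if not (resume and manifest.stage_clean("filter", outd)):
        logger.info(
            "stage filter: cascade with distance>=%g, mappability>=%g, length>=%d",
            config.distance_threshold, config.min_mappability, config.min_length,
        )
        uniq = lio.read_track(ind / "uniqueness.bedgraph")
        align = lio.read_track(ind / "alignability.bedgraph")
        result = qc_mod.run_cascade(
            catalog, reference, uniq, align, counts,
            min_fraction=config.min_fraction,
            distance_threshold=config.distance_threshold,
            min_score=config.min_mappability,
            min_len=config.min_length,
        )
        stage_dir.mkdir(parents=True, exist_ok=True)
        result.catalog.write(stage_dir)
        lio.write_tsv(result.report.reset_index(), stage_dir / "filter_report.tsv")
        removals = pd.DataFrame(
            sorted(result.removal_stage.items()),
            columns=["transcript_id", "removed_at"],
        )
        lio.write_tsv(removals, stage_dir / "removals.tsv")
        manifest.record(
            "filter", outd,
            [stage_dir / "catalog.tsv", stage_dir / "catalog.gtf",
             stage_dir / "filter_report.tsv", stage_dir / "removals.tsv"],
        )
    filtered = cat_mod.Catalog.read(stage_dir)
    expressed_lnc = filtered.table.index[
        filtered.table["category"].isin(
            ["annotated_ncRNA"] + [c for c in filtered.table["category"].unique()
                                   if str(c).startswith("novel_")]
        )
    ]
    summary["n_expressed_transcripts"] = len(filtered)
    summary["n_expressed_lncRNAs"] = int(len(expressed_lnc))

    # --- stage 3: differential expression --------------------------------
    stage_dir = outd / "de"
    if not (resume and manifest.stage_clean("de", outd)):
        logger.info("stage de: %d comparisons", len(config.comparisons))
        stage_dir.mkdir(parents=True, exist_ok=True)
        files = []
        tables = {}
        for a, b in config.comparisons:
            res = de_mod.nb_test(counts, a, b)
            res = de_mod.call_degs(res, config.de_max_fdr, config.de_min_abs_log2fc)
            path = stage_dir / f"de_{a}_{b}.tsv"
            lio.write_tsv(res.reset_index(), path)
            files.append(path)
            tables[f"{a}_vs_{b}"] = res
        summary_tab = de_mod.summarize_degs(tables, filtered.table["category"])
        lio.write_tsv(summary_tab, stage_dir / "de_summary.tsv")
        files.append(stage_dir / "de_summary.tsv")
        manifest.record("de", outd, files)
    de_tables = {
        f"{a}_vs_{b}": lio.read_tsv(stage_dir / f"de_{a}_{b}.tsv").set_index("gene_id")
        for a, b in config.comparisons
    }
    nn_pp = de_tables.get("NN_vs_PP")
    de_lnc = set()
    if nn_pp is not None:
        de_lnc = set(nn_pp.index[nn_pp["is_de"]]) & set(expressed_lnc)
    summary["n_de_lncRNAs_NN_PP"] = len(de_lnc)

    # --- stage 4: tissue specificity --------------------------------------
    stage_dir = outd / "tissue"
    if not (resume and manifest.stage_clean("tissue", outd)):
        logger.info("stage tissue: specificity over 17 tissues")
        raw_panel = pd.read_csv(ind / "tissue_panel.tsv", sep="\t", index_col="gene_id")
        panel = tis_mod.average_skin_replicates(raw_panel)
        ts = tis_mod.specificity_index(panel)
        props = tis_mod.expressed_proportions(
            panel, filtered.table["category"], config.expressed_rpkm
        )
        stage_dir.mkdir(parents=True, exist_ok=True)
        ts.to_csv(stage_dir / "specificity.tsv", sep="\t")
        lio.write_tsv(props.reset_index(), stage_dir / "expressed_proportions.tsv")
        manifest.record(
            "tissue", outd,
            [stage_dir / "specificity.tsv", stage_dir / "expressed_proportions.tsv"],
        )
    ts = pd.read_csv(stage_dir / "specificity.tsv", sep="\t", index_col="gene_id")

    # --- stage 5: regulatory proximity ------------------------------------
    stage_dir = outd / "proximity"
    if not (resume and manifest.stage_clean("proximity", outd)):
        logger.info("stage proximity: 9 cell-line segmentations")
        segs = SegmentationBundle.read(ind / "segmentations")
        stage_dir.mkdir(parents=True, exist_ok=True)
        files = []
        lnc_table = filtered.table.loc[
            filtered.table.index.intersection(expressed_lnc)
        ]
        for element in ("enhancer", "promoter"):
            tracks = [
                prox_mod.ElementTrack.from_bed(df, line, element)
                for line, df in segs.tracks.items()
            ]
            dists = prox_mod.distance_table(filtered.table, tracks)
            path = stage_dir / f"distances_{element}.tsv"
            dists.to_csv(path, sep="\t", index_label="transcript_id")
            files.append(path)
            for ecto in ECTODERMAL_LINES:
                rel = prox_mod.relative_distance(dists, ecto)
                summ = prox_mod.summarize_relative_distance(
                    rel["relative"], filtered.table["category"]
                )
                p2 = stage_dir / f"relative_{element}_{ecto}.tsv"
                lio.write_tsv(summ.reset_index(), p2)
                files.append(p2)
        enh = pd.read_csv(
            stage_dir / "distances_enhancer.tsv", sep="\t", index_col="transcript_id"
        )
        pro = pd.read_csv(
            stage_dir / "distances_promoter.tsv", sep="\t", index_col="transcript_id"
        )
        calls = prox_mod.classify_elnc_plnc(
            enh.loc[lnc_table.index, "NHEK"],
            pro.loc[lnc_table.index, "NHEK"],
            config.elnc_window,
        )
        p3 = stage_dir / "elnc_plnc.tsv"
        calls.rename("class").to_csv(p3, sep="\t", index_label="transcript_id")
        files.append(p3)
        manifest.record("proximity", outd, files)

    # --- stage 6: function inference --------------------------------------
    stage_dir = outd / "infer"
    if not (resume and manifest.stage_clean("infer", outd)):
        logger.info("stage infer: calibration with %d samplings", config.n_samplings)
        dag = inf_mod.OntologyDAG.from_tsv(ind / "ontology_edges.tsv")
        g2t = lio.read_tsv(ind / "gene2term.tsv")
        annotations: dict[str, set[str]] = {}
        for _, r in g2t.iterrows():
            annotations.setdefault(str(r["gene_id"]), set()).add(str(r["term"]))
        propagated = inf_mod.propagate_ancestors(dag, annotations)
        sf = de_mod.size_factors(counts.counts, pseudo_reference=True)
        nn_pp_samples = [
            s for s in counts.samples if counts.groups[s] in ("NN", "PP")
        ]
        expr = inf_mod.log_normalized_expression(
            counts.counts[nn_pp_samples], sf.loc[nn_pp_samples]
        )
        coding = [g for g in expr.index if g in propagated]
        lncs = [g for g in expressed_lnc if g in expr.index]
        calib = inf_mod.calibrate_cutoff(
            expr.loc[coding], annotations, dag=dag,
            n_samplings=config.n_samplings, beta=config.beta, seed=config.seed,
        )
        rho2 = inf_mod.correlation_matrix(expr.loc[lncs], expr.loc[coding])
        positions = filtered.table[["chrom", "start", "end"]]
        inferred = inf_mod.transfer_functions(
            rho2, propagated, cutoff=config.rho2_cutoff, positions=positions
        )
        full, display = (pd.DataFrame(), pd.DataFrame())
        if inferred:
            full, display = inf_mod.inferred_function_enrichment(inferred, de_lnc)
        stage_dir.mkdir(parents=True, exist_ok=True)
        lio.write_tsv(calib.to_frame(), stage_dir / "calibration.tsv")
        inf_rows = pd.DataFrame(
            [
                {
                    "lnc_id": f.lnc_id,
                    "max_rho2": f.max_rho2,
                    "is_cis": f.is_cis,
                    "sources": ",".join(f.sources),
                    "terms": ",".join(sorted(f.terms)),
                }
                for f in inferred
            ]
        )
        lio.write_tsv(inf_rows, stage_dir / "inferred_functions.tsv")
        lio.write_tsv(full, stage_dir / "enrichment_full.tsv")
        lio.write_tsv(display, stage_dir / "enrichment_display.tsv")
        meta = {
            "auc": calib.auc,
            "chosen_cutoff": calib.chosen_cutoff,
            "n_inferred": len(inferred),
        }
        (stage_dir / "calibration_meta.json").write_text(json.dumps(meta, indent=2))
        manifest.record(
            "infer", outd,
            [stage_dir / "calibration.tsv", stage_dir / "inferred_functions.tsv",
             stage_dir / "enrichment_full.tsv", stage_dir / "enrichment_display.tsv",
             stage_dir / "calibration_meta.json"],
        )
    meta = json.loads((stage_dir / "calibration_meta.json").read_text())
    summary["calibration_auc"] = meta["auc"]
    summary["n_lncRNAs_with_inferred_function"] = meta["n_inferred"]

    # --- stage 7: region enrichment ---------------------------------------
    stage_dir = outd / "regions"
    if not (resume and manifest.stage_clean("regions", outd)):
        logger.info("stage regions: census, density and enrichment")
        stage_dir.mkdir(parents=True, exist_ok=True)
        files = []
        genome = pyfaidx.Fasta(str(ind / "genome.fa"))
        chrom_lengths = {name: len(genome[name]) for name in genome.keys()}
        density, mean_per_mb = reg_mod.density_track(filtered.table, chrom_lengths)
        lio.write_tsv(density, stage_dir / "density.tsv")
        files.append(stage_dir / "density.tsv")
        summary["lncRNAs_per_Mb"] = mean_per_mb
        if config.loci_file:
            loci = reg_mod.read_loci_tsv(config.loci_file)
        else:
            loci = [
                reg_mod.RegionSpec(
                    "demo_region", sorted(chrom_lengths)[0], 0,
                    min(1_000_000, sorted(chrom_lengths.values())[0]),
                )
            ]
        enrich = pd.concat(
            [reg_mod.region_novelty_enrichment(filtered.table, lc) for lc in loci],
            ignore_index=True,
        )
        lio.write_tsv(enrich, stage_dir / "region_enrichment.tsv")
        files.append(stage_dir / "region_enrichment.tsv")
        cat_tab = reg_mod.susceptibility_catalog(filtered.table, de_lnc, loci)
        lio.write_tsv(cat_tab, stage_dir / "locus_catalog.tsv")
        files.append(stage_dir / "locus_catalog.tsv")
        manifest.record("regions", outd, files)

    (outd / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
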