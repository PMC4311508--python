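# lncskin

Discovery and characterization of long non-coding RNAs (lncRNAs) in bulk
RNA-seq of normal and psoriatic skin — a tested, reusable re-implementation
of the analysis pipeline behind a 216-sample skin cohort study
(99 lesional psoriatic **PP**, 27 uninvolved psoriatic **PN**, 90 normal
**NN** biopsies), exercisable end to end on seeded synthetic data.

It is aimed at computational biologists who want the pipeline's statistical
machinery — not the read alignment/assembly steps, which are taken as given
in the form of per-sample transcript models (GTF).

## What it computes

1. **Consensus catalog** — per-sample assemblies are merged (identical
   intron chain for multi-exon transcripts, ≥1 bp overlap for mono-exon),
   strands are predicted from canonical GT..AG splice motifs, and each
   transcript is classified against the reference annotation into
   protein-coding / pseudogene / annotated ncRNA / antisense, or one of
   four novel subtypes by exon location: **intronic**, **intergenic**,
   **interleaving** (exons in both intronic and intergenic space) and
   **encompassing** (a reference gene nested in the transcript's introns).
2. **Artifact-filter cascade** with a per-category attrition report:
   presence in ≥5% of samples (≥11 of 216); distance ≥2 kb from annotated
   exons (novel transcripts only, removing premature-mRNA fragments);
   mappability ≥0.9 in both uniqueness and alignability tracks; mature
   length ≥200 bp; and ≥1 read per sample on average.
3. **Differential expression** between skin groups with a negative-binomial
   read-count model: median-of-ratios size factors
   s_j = median_g k_gj / (Π_j k_gj)^{1/m}, method-of-moments dispersions
   shrunk to a fitted a₀ + a₁/µ trend (per-gene maximum, conservative), and
   an exact-style two-sided test on group sums. DE is called at
   FDR ≤ 0.1 and |log₂FC| ≥ 1; cytokine responses at FDR ≤ 0.1 with
   FC > 2 (enhanced) or FC < 0.5 (repressed).
4. **Tissue specificity** over 17 tissues: T_s = RPKM_s / Σ_t RPKM_t, with
   the skin column averaged from three uninvolved-skin replicates, plus
   expressed-proportion summaries and the T_s > 0.4 high-specificity set.
5. **Regulatory proximity** over nine chromatin-state segmentations:
   distance from each gene's TSS to the nearest strong enhancer / active
   promoter, the ectodermal relative distance D_ecto/D_average (outliers
   beyond 1.5×IQR trimmed), and elncRNA/plncRNA calls (<5 kb from an
   enhancer but not a promoter, and conversely).
6. **Function inference** by guilt-by-association: lncRNAs inherit the
   ancestry-propagated ontology terms of their most-correlated coding
   gene(s) at squared Spearman ρ² ≥ 0.5; the cutoff is calibrated by
   100,000 samplings of same-function vs random gene pairs, maximizing
   F_β = (1+β²)ρϒ/(ρβ² + ϒ) with β = 5 (recall-weighted), with ROC AUC
   reported. Inferred functions enriched among DE lncRNAs are found by a
   hypergeometric upper-tail test with BH FDR and observed/expected ratios.
7. **Region enrichment** — censuses and hypergeometric novelty enrichment
   for regions such as the EDC and MHC, susceptibility-locus catalogs
   (±500 kb flanks, ±3 Mb for MHC), per-Mb density, and cytokine-signature
   enrichment among up/down-regulated lncRNAs.

The `synthetic_data` module generates the complete input bundle — reference
GTF, genome FASTA with planted splice motifs, 216 per-sample assembly GTFs,
mappability bedGraphs, counts/groups TSVs, a 17-tissue panel, nine
segmentation BEDs and an ontology — with ground-truth sidecars, so every
stage can be validated against planted truth.

## Worked example

```bash
lncskin simulate --seed 11 --out fixture
cat > pipeline.yaml <<EOF
input_dir: fixture
output_dir: results
seed: 11
EOF
lncskin run --config pipeline.yaml
```

prints

```
calibration_auc	0.8949203599350188
lncRNAs_per_Mb	8.333333333333334
n_de_lncRNAs_NN_PP	10
n_expressed_lncRNAs	50
n_expressed_transcripts	150
n_lncRNAs_with_inferred_function	14
n_raw_transcripts	168
```

Reading: of 168 consensus transcripts (130 annotated genes, 20 planted
novels, 18 planted artifacts), the cascade removes exactly the 18 artifacts;
the 50 expressed lncRNAs are the 30 annotated lincRNAs plus all 20 true
novels; 10 lncRNAs are differentially expressed between normal and lesional
skin; and the co-expression calibration separates same-function from random
gene pairs with AUC ≈ 0.89 on this small coherent fixture. Stage outputs
(filter attrition, per-comparison DE tables, specificity, proximity,
calibration and enrichment TSVs) land under `results/`, with checksums in
`results/manifest.json`; rerunning with `--resume` recomputes only stages
whose files changed.

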