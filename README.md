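# hzga — homeolog-resolved zygotic genome activation analysis

`hzga` is a Python library for analyzing the first wave of embryonic
transcription in an allotetraploid genome, where every gene may exist as two
diverged homeologous copies (here called L and S, grouped by "gene page").
It is aimed at researchers working on the maternal-to-zygotic transition in
*Xenopus laevis*-like systems who have exon/intron count matrices, chromatin
coverage tracks (bedGraph), ATAC summit intervals and an L↔S pairwise
alignment (UCSC chain), and who want reproducible, threshold-explicit calls
for:

- **activated and first-wave genes** — joint exon + intron negative-binomial
  testing, so genes whose large maternal mRNA store masks their exonic
  change are still detected through intron (nascent pre-mRNA) signal;
- **L/S activation symmetry** — which homeolog drives activation, with a
  2-fold bias rule;
- **predicted enhancers** — 500 bp summit-centered windows with pooled and
  per-replicate H3K27ac/ATAC enrichment tiers over a no-antibody control;
- **homeologous enhancer conservation** — two-pass chain liftOver
  (500 bp window at 10% minimum match, then a flanked 5 kb rescue) with
  5-gene synteny validation;
- **transcription-factor binding association** — RPM/fold gates in 200 bp
  windows, binding-proximity and enhancer-density statistics;
- **dosage maintenance** — whether the combined L+S output tracks an
  ancestral diploid outgroup better than either subgenome alone.

A fully ground-truthed synthetic allotetraploid generator
(`hzga.synthetic_data`) produces every input the pipeline consumes —
annotation, chains, counts, tracks, summits, outgroup table — so each stage
is testable end to end without any sequencing data.

## The statistics at the core

**Activation calling.** Exon and intron raw counts are separate rows per
gene (intron rows prefixed `i_`). After prefiltering (exon RPM < 0.5 in all
samples removes the gene; intron rows with raw count ≤ 10 or RPKM < 0.25 in
all samples are dropped; biotypes restricted to protein_coding / lncRNA /
pseudogene), each contrast is tested with a negative-binomial Wald test:
median-of-ratios size factors *s_j*, method-of-moments dispersions shrunk
toward a fitted mean–dispersion trend α(μ) = a₀ + a₁/μ, Wald statistic on
log fold change with BH adjustment per contrast. A gene is significant in a
contrast when **any** of its rows has adjusted p < 0.05 and log2FC ≥ 1.5;
*activated* requires the transcription-inhibitor (triptolide) contrast in
both batches plus stage 9 vs stage 5; *first-wave* additionally the
cycloheximide contrast; genes are *maternal* when average stage-5 exon
TPM ≥ 1.

**Enhancer prediction.** For a 500 bp window centered on an ATAC summit,
fold = (signal RPKM + 0.1)/(background RPKM + 0.1). Putative: pooled
H3K27ac fold ≥ 2, pooled H3K27ac ≥ 1 RPKM, pooled no-antibody < 1 RPKM.
High-confidence (`hi`): additionally ≥ 3 individual H3K27ac and ≥ 3 ATAC
replicates each ≥ 2-fold; otherwise `lo`. TF-bound: ≥ 0.5 RPM and ≥ 2-fold
in a 200 bp window.

**LiftOver.** A region maps through the chain with the most aligned source
bases when its aligned-base fraction is at least `min_match` (default 0.10,
the UCSC `-minMatch` semantics); the image spans the first to last aligned
base, strand-aware. Elements failing pass 1 are retried with a 5 kb window
whose two 2.5 kb halves must map and flank the 5 kb image.

**Dosage maintenance.** For ortholog triples, log2 TPM of non-zero genes
are Z-normalized per transcriptome; single-subgenome TPMs are scaled 2×.
Spearman ρ(outgroup, composite L+S) is compared with ρ(outgroup, 2·L) and
ρ(outgroup, 2·S), and gene-wise residuals Z_outgroup − Z_laevis are compared
by paired Wilcoxon signed-rank on |residuals|.

## Worked example

```python
from hzga import activation as act, homeolog_symmetry as hs
from hzga.synthetic_data import SimConfig, simulate_dataset

ds = simulate_dataset(SimConfig(seed=7))
biotypes = {g.gene_id: g.biotype for g in ds.annot.genes.values()}
exp = act.prefilter(ds.counts, biotypes)
results = act.run_standard_contrasts(exp)
calls = act.classify_activation(results, exp)
pairs = hs.classify_symmetry(hs.build_pairs(ds.genepages, calls))
df = hs.pairs_frame(pairs)

print(f"genes analyzed:   {len(calls.calls)}")
print(f"activated:        {len(calls.activated_ids())}")
print(f"first-wave:       {len(calls.first_wave_ids())}")
print(df["symmetry_class"].value_counts().to_string())
```

prints

```
genes analyzed:   1137
activated:        381
first-wave:       199
symmetry_class
not_activated     316
both_symmetric    100
L_only             50
S_only             47
singleton_S        31
singleton_L        25
both_L_biased      17
both_S_biased      14
```

1137 genes survive the prefilter; 381 are called activated at stage 9
(inhibitor-controlled in both batches), of which 199 remain activated under
translation blockade and are therefore first-wave. Each of the 600 gene
pages receives exactly one symmetry label: 50 pages activate only the L
homeolog, 47 only S, 100 activate both sides within 2-fold, and 31 pages
show a >2-fold homeolog bias.

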