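# Methods

This note documents the models, rules and numerical choices behind `hzga`,
and what the synthetic data generator does and does not emulate.

## Coordinate and normalization conventions

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive) is
converted on read and write, BED/bedGraph pass through unchanged. Coverage
tracks are step functions; the mass of a window is Σ(value × overlap bp),
and RPM/RPKM are mass-based: RPM = 10⁶·mass/N, RPKM = 10⁹·mass/(N·len),
with the library size N supplied externally (a sample sheet), never
inferred from track mass, so normalization matches mapped-fragment counts.
For count matrices, RPM = 10⁶·c/N and RPKM = 10⁹·c/(N·len) with N the
per-sample total **exon** count; TPM renormalizes per-base rates to 10⁶ per
sample over exon features only. Intron rows are reported as RPKM — a TPM
for an intron row is not meaningful because intron "transcripts" are not a
sampling unit of the library.

## Intron feature construction

Nascent transcription is read from intron-overlapping signal, which is only
interpretable where the intron is clean. Starting from the union of each
gene's transcript introns, four subtractions are applied per base:

- (a) maternal (pre-activation) RNA-seq coverage strictly above a cutoff
  (default 2, raw per-base coverage), same strand as the gene. The maternal
  track is pooled across replicates. An unstranded track is rejected.
- (b) bases overlapping any annotated exon, same strand by default
  (configurable). Antisense exons do not contaminate stranded intron
  counts, hence the strand restriction; a switch allows the unstranded
  variant.
- (c) repeat/transposon intervals, regardless of strand.
- (d) bases in introns of more than one distinct gene (same-gene isoform
  sharing allowed), regardless of strand.

No minimum retained-fragment length is imposed. The retained set is
idempotent under re-application and monotone in every exclusion set; both
properties are tested, as is base-for-base agreement with an exhaustive
per-base oracle on random instances.

## Differential activation model

Exon and intron rows are tested jointly in one matrix. The test is a
self-contained negative-binomial Wald test:

- size factors by median-of-ratios over features positive in all samples;
- per-feature dispersion by method of moments on normalized counts,
  α̂ = (s² − μ)/μ², pooled within groups; a parametric trend
  α(μ) = a₀ + a₁/μ is fitted by two-pass least squares (features far above
  the first fit are dropped once — they carry signal, not noise);
- gene-wise estimates are shrunk toward the trend in log space with weight
  (m−2)/(m+8) for m samples. The weight was selected by null-simulation
  calibration at the pipeline's own two-replicate design: empirical type-I
  error ≈ 0.06 at nominal 0.05. With one replicate per group the trend is
  used alone and the result is flagged;
- group means are total-count ratios (a zero group total falls back to a
  half count so folds stay finite); the Wald SE comes from the NB GLM
  information w = μ/(1 + αμ), and the statistic is referred to a standard
  normal; BH adjustment is applied across all rows of a contrast jointly —
  exon and intron rows share one multiple-testing family, the conservative
  reading of an otherwise open choice.

Classification: a gene is significant in a contrast when any of its rows
passes adjusted p < 0.05 and log2FC ≥ 1.5 (the point estimate, not a
shrunken value). Activated = significant (positive) in the
inhibitor-vs-control contrast in both batches and in stage 9 vs stage 5;
first-wave = activated and significant in the cycloheximide contrast
(cycloheximide vs triptolide by default; the CHX+triptolide reference is
available); morphant effect = signed significant call of either morpholino
contrast on an activated gene. Batches are handled by separate per-batch
contrasts with an AND rule, not a covariate — this is what "in both
batches" means operationally, and it is robust to batch-specific maternal
variation. Magnitude (for sorting/graphing) is the larger of the absolute
log2 fold of average exon TPM and of average intron RPKM between stage 9
and the inhibitor, with a 0.1 pseudocount.

For effect-size *comparisons* (homeolog bias), the Wald point estimate is
too noisy when the baseline is near zero, so a moderated fold change
log2((μ_B + c)/(μ_A + c)) with c = 4 normalized counts is carried
alongside — a shallow-replication analogue of posterior LFC shrinkage. It
is never used for significance.

## Homeolog symmetry

Every gene page receives exactly one label. Both sides activated: biased
when the difference of activation log2 fold changes exceeds 1 (the 2-fold
rule), else symmetric. The difference is computed within a matched feature
channel — intron folds on both sides when available, else exon folds —
because exonic folds of maternal-zygotic genes are compressed by the
maternal store and are not comparable with intronic folds. One side
activated: L_only/S_only, including when the partner gene exists but fails
the call (the expressed-pattern reading). Singletons keep their own labels.
Category proportions are compared by Pearson chi-squared of homogeneity
without continuity correction; lineage concordance cross-tabulates the
driving homeolog (same / different / mixed) for pages activated in at
least two condition sets.

## Enhancer prediction and TF binding

Elements are 500 bp windows centered on ATAC summits (truncated at
chromosome ends; RPKM uses the actual window length). Pooling is
depth-weighted: summed mass over summed library size. All fold enrichments
use a 0.1 pseudocount, which bounds the fold and keeps zero background
defined; deepTools-style ratio tracks conventionally use the same constant,
and it is applied uniformly to every fold computation rather than deciding
zero-handling case by case. The no-antibody gate
(< 1 RPKM) uses the pooled background — per-replicate background gating is
an open alternative; pooled was chosen because the background is flat by
construction and per-replicate gates would multiply the false-reject rate.
Distal/proximal is > 1 kb / ≤ 1 kb from the nearest representative TSS (the
most upstream, i.e. 5′-most, TSS with non-zero stage-9 coverage at its
base, else the most upstream TSS). TF binding uses a 200 bp window, ≥ 0.5
RPM and ≥ 2-fold over background. Distances for proximity statistics are
TSS-to-nearest-element-summit, unstranded; genes on chromosomes with no
bound element get a censored distance (the chromosome length) and are
flagged.

## Homeologous liftOver and conservation

A region maps through the chain with the most aligned source bases over it
(ties: score, then id) when its aligned-base fraction ≥ min_match (0.10
default; fraction of bases inside aligned blocks, not sequence identity —
the UCSC `-minMatch` semantics, since no sequence is consulted). The mapped
span runs from the image of the first to the last aligned base,
strand-aware. Pass 2 for failed elements lifts a 5 kb summit-centered
window plus its two 2.5 kb halves, and retains the candidate only when both
halves map to the same chromosome and bracket the midpoint of the 5 kb
image; a strictness switch additionally requires the halves within 10 kb of
the image ends. An element whose partner region overlaps a *putative*
element of the other subgenome is conserved, else subgenome-specific;
elements failing both passes are unmapped. Synteny takes the k (default 5)
nearest genes up- and downstream of both regions and requires a shared gene
page on each side; a side with no annotated genes on both regions
(chromosome end) is vacuously satisfied and the neighbor count is reported.

## Dosage maintenance

Single-subgenome TPMs are doubled because TPM is normalized to the whole
allotetraploid transcriptome. log2 values of each vector's non-zero genes
are Z-normalized independently; correlations are Spearman on the
intersection of non-zero genes (rank-based ρ is unaffected by the
Z-normalization; the Z values feed the residuals). Residuals are
Z_outgroup − Z_laevis per gene over genes non-zero in all four vectors, and
the composite is compared against each single subgenome by a paired
two-sided Wilcoxon signed-rank on absolute residuals — the null of "equally
good a predictor" concerns magnitudes; a switch runs the signed variant.
log2 uses no pseudocount since only non-zero genes enter.

## The synthetic generator

The generator emulates the *structure* of an allotetraploid early-embryo
study with exact ground truth; it does not attempt sequence realism.

- **Genomes.** Two chromosome pairs (~1.2 Mb each), 600 gene pages laid out
  co-linearly, one 3-exon gene model per page side; 5% L-singletons and 5%
  S-singletons. The S chromosome derives from L through indels placed in
  intergenic gaps (2×10⁻⁵/bp, 20–200 bp), emitted block-exactly as
  reciprocal chains. Real subgenomes also differ by inversions,
  translocations and gene loss beyond singletons; those are absent, so
  liftOver failure modes are exercised by constructed cases in the tests,
  not by the default genome.
- **Counts.** Conditions stage 5/8/9 × {DMSO, triptolide, CHX,
  CHX+triptolide, MO, MO+CHX} × 2 batches × 2 replicates, NB with shared
  dispersion 0.05. Maternal genes draw 2^N(8, 1.5) mean exon counts;
  strictly zygotic genes draw maternal means just below the 1-TPM line to
  exercise the threshold. Activation adds a controlled gain of
  (2^4 − 1) × 8 exon counts (half that for introns) — a fixed effect, so
  truth classes are separated by design; a spread parameter exists but
  defaults to 0. Homeolog bias classes: L-only, S-only, both-symmetric,
  both-asymmetric (2⁴-fold vs 2²-fold, i.e. a 2-unit log2 offset).
  Triptolide removes all zygotic signal, CHX spares first-wave genes (50%
  of activated), the morpholino removes zygotic signal of a 30% target
  subset. Batch "b" multiplies the maternal contribution by 1.3; per-sample
  depth varies lognormally (sd 0.2 log2).
- **Tracks.** Flat background 0.5 with Gaussian bumps (sd 100 bp, amplitude
  4) at active elements: all 3 H3K27ac and ATAC replicates for `hi`-truth
  elements, exactly 2 for `lo`-truth (placing the ≥3-replicate boundary
  under test from both sides), none for inactive partners. TF tracks add
  amplitude-8 bumps at active elements of morpholino-target pages.
  Bin-level Gaussian noise (sd 0.2 per 50 bp). Library sizes are constant
  (10⁹) — chosen jointly with the background so the 1-RPKM and 0.5-RPM
  gates fall between the truth classes; real coverage distributions are
  heavy-tailed and uneven, which this does not model, so the tier recalls
  measured here certify the rule logic, not robustness to real-data noise.
- **Outgroup.** One diploid ortholog per page, expression = expected L+S
  stage-9 output × lognormal noise (sd 0.25 log2); a homeolog split within
  a page never changes the composite, which is exactly the
  dosage-maintenance structure the analysis is meant to detect.

Everything derives from a single seed through stage-local generators;
outputs are byte-identical across runs and independent of call order.

## Problem sizes and runtime

Defaults (600 pages, 2×~1.2 Mb, 32 samples, ~2,300 feature rows, 1,200
candidate elements) run the full pipeline in a few seconds; the test suite
(including per-base oracles over ≥1000 random liftOver regions and a
2,500-feature null calibration) completes in well under a minute. These
sizes were chosen so every category stays populated (tens of pages per
symmetry class) while iteration stays fast.

## Known limitations

- The DE engine is deliberately not DESeq2-numerics-equivalent (no GLM
  IRLS, no Cox–Reid adjustment, no LFC shrinkage of the tested estimate);
  it is calibrated at the shallow designs this pipeline targets and is
  pluggable behind the per-feature (lfc, p, padj) contract.
- Intron counting from reads, peak calling, motif analysis and chain
  construction are out of scope: count matrices, summits and chains are
  inputs.
- With a single no-antibody replicate set and flat synthetic background,
  pooled-vs-per-replicate background gating cannot be distinguished
  empirically here.
- Cross-species (multi-hop) liftOver is reduced to the same pairing
  machinery; no chain stitching is implemented.
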