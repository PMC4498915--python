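# Methods

This note documents the models, defaults and design choices behind each
stage, what the synthetic data does and does not emulate, and the numerical
conventions used throughout.

## Coordinate and format conventions

All internal coordinates are 0-based half-open (BED-native). GFF3's 1-based
closed coordinates are converted at the I/O boundary and nowhere else. The
strand-aware promoter window around a TSS *t* is `[t−500, t+50)` on the +
strand and `[t−50, t+500)` on the − strand: always 550 bp, always containing
the TSS, with the 500-bp side upstream in the transcription frame. Every
output table has a header and a fixed column order, and all floats are
written with a fixed format, so identical configurations produce
byte-identical outputs.

## Synthetic data: what it emulates

The generator plays the role of the real study inputs. One master seed feeds
named substreams (SHA-256 of the stream name mixed into a `SeedSequence`),
so any component can be regenerated independently and reruns are exact.

- **Genome/annotation.** Genes are packed into fixed 4-kb slots (2-kb span,
  three exons) on four chromosomes, guaranteeing non-overlap and room for
  every promoter window; strands are ~50/50. Background sequence is i.i.d.
  uniform ACGT, which keeps chance-motif rates analytic; there is no GC
  skew, repeat structure or isoform complexity.
- **Regulon.** `n_targets` genes (default 200) receive exactly one X-box
  instance in their promoter; default consensus `GTTGCCATGGCAAC`, a perfect
  14-bp inverted repeat of the kind RFX factors bind. Planted offsets are
  drawn from a truncated normal (mean −100, sd 120, clipped to
  [−480, +36] relative to the TSS) to mirror the concentration of real
  binding sites near the TSS. Sites are the exact consensus by default
  (`exact_sites=False` samples from a consensus-dominated PWM instead).
- **ChIP coverage.** Input bins are Poisson(depth); IP bins are
  Poisson(depth × enrichment) where a bin overlaps a planted site. Defaults
  depth 30/bin, enrichment 10×, 50-bp bins, two IP replicates. There is no
  fragment-size smearing; enrichment is confined to site-overlapping bins.
- **RNA-seq counts.** NB with dispersion α = 0.1 and per-gene baselines
  2^N(6.5, 1.5²) (median ≈ 90 counts). Knockout effects are ±2 log₂ units
  applied in KO samples only: always at P30, at P21 with probability 0.5;
  80% of regulon genes are repressed (down in the KO), 20% activated, and
  100 additional "indirect" genes carry effects without binding sites.
  Three replicates per genotype × age.
- **Developmental profiles.** The regulator-like reference trajectory is a
  logistic rise 1 + 49/(1 + e^−(t−19)/1.2) over postnatal days
  {7, 14, 17, 21, 30}: a sharp increase between days 17 and 21 with
  half-maximum before day 21. Repressed regulon genes follow it; activated
  regulon genes decline; background genes are mostly flat; all carry
  multiplicative log-normal noise (σ = 0.2), and 10% of background genes
  are scaled below the reliability floor to exercise the not-evaluable
  path.
- **Cilia evidence.** Gold-list membership and low/medium/high citation
  counts; regulon genes are cilia-positive at rate 0.6 (background 0.05),
  and every positive gene satisfies the calling rule by construction.

Passing tests on this data demonstrate the pipeline's statistical
calibration, power and joining logic under a faithful but idealised
generative model; they say nothing about mappability artefacts, GC bias,
batch effects or annotation error in real data.

## Differential expression

Size factors are median-of-ratios against the per-gene geometric mean over
all-positive genes, rescaled to geometric mean 1. Dispersion is estimated
per gene by method of moments on normalized counts pooled within groups,
with the correction Var(y/s) = μ·E[1/s] + αμ²; the mean-dispersion trend is
the average of *unclipped* raw estimates within 20 mean-expression bins
(clipping negative estimates before averaging would bias the trend upward
and make the test conservative), each gene is shrunk toward the trend with
20 prior degrees of freedom against its ~4 residual df, and the result is
floored at 10⁻⁸. The exact test conditions group totals (NB with effective
size = summed size factors, which is exact for equal factors) on the pooled
total and sums allocations no more likely than the observed one; dispersions
below 10⁻¹⁰ switch to the Poisson limit. Fold-changes come from normalized
group means with a 0.5 pseudocount, never from the test statistic. Set calls
threshold on raw p < 0.01 with nested 2×/3×/10× tiers; BH-adjusted q-values
are reported alongside but deliberately do not gate the calls, matching the
raw-p convention of the headline thresholds.

## Peak calling and annotation

Per bin, λ = input count × (IP depth / input depth), floored at the
genome-wide rescaled input mean so zero-input bins cannot produce spurious
significance; bin p = Poisson upper tail of the IP count; BH within the
replicate at q ≤ 0.05; significant bins merged across gaps of ≤ 1 bin.
Summit = center of the max-IP bin, peak p = min bin p, enrichment =
IP/λ summed over the peak. Reproducibility anchors on the replicate with
most peaks and requires ≥ 50% reciprocal overlap (of both lengths) with a
peak in every other replicate; kept coordinates are the union of anchor and
partners. Peaks are classified by their *center* with precedence
promoter > exon > intron > intergenic, which makes the classes an exact
partition; a center in several promoter windows goes to the nearest TSS and
exact ties flag all tied genes as ambiguous. Signed TSS distances flip sign
on the − strand so negative always means upstream.

## Motif analysis

PWMs use additive pseudocounts ((count + pc/4)/(n + pc)). Scanning scores
log₂(p/background) over both strands — the reverse strand via the
reverse-complement matrix — against a 0-order background estimated from the
scanned set; the default hit threshold is 60% of the maximum achievable
score, a deliberately permissive binary "contains an X-box" call. Windows
containing non-ACGT bases are skipped.

ZOOPS-EM treats each sequence as background-only (probability 1−γ) or
carrying one site at a uniform (offset, strand). The M-step is the
pseudocounted expected-count update, so the monotone EM objective is the
data log-likelihood plus (pc/4)·Σ log θ; that penalized objective is what
the returned trajectory records, and it never decreases. Convergence is an
objective change < 10⁻⁶ (max 500 iterations); five restarts are seeded from
random data windows, and the winner is refined by restarting EM from
column-shifted variants of its matrix (±1..3, padded with background) —
the standard escape from EM's phase local optima. The inverted-repeat score
(mean column-wise Pearson r between the PWM and its reverse complement) is
1.0 for a perfect palindrome.

Motif enrichment between disjoint gene sets is the hypergeometric upper
tail on motif-containing promoter counts, equivalent to one-sided Fisher.

## Integration

"Consistent with activation by the regulator" is operationalized as Pearson
r ≥ 0.8 against the reference trajectory AND a ≥ 4-fold rise from first to
last timepoint; genes whose peak RPKM is below 1 are not evaluable
(unreliably low read values). All three thresholds are config. The cilia
rule is gold-list membership OR ≥ 1 high-confidence citation; genes missing
from evidence tables are false, never errors, mirroring incomplete
databases. The universe for hypergeometric set comparisons is genes with
mean normalized WT expression ≥ 1 (expression-matched background), not the
whole annotation. Direct target = ChIP target ∧ DE at either age; on
synthetic runs, precision/recall against the planted regulon (restricted to
regulon genes with a non-zero planned effect) are appended to the summary.

## Problem sizes and known limitations

Default analyses run at 2 000 genes / 200 targets on an ~8-Mb genome —
large enough for stable calibration estimates (the 99% binomial band at
α = 0.01, n = 2000 is ±0.57 percentage points) while a full pipeline run
completes in well under a minute. The acceptance script uses the same
sizes. Known limitations: the exact test enumerates allocations of the
pooled total (fine at these depths, quadratic-free but linear in T); peak
resolution is bounded by the 50-bp bin; the EM background is 0-order; the
reproducibility rule is a reciprocal-overlap heuristic, not IDR; and no
attempt is made to model read-level artefacts.
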