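# ciliareg

Integrative ChIP-seq/RNA-seq calling of **direct transcription-factor target
genes**, built around the regulatory logic of RFX-family factors and their
ciliary regulons in the differentiating male germ line, and exercised end to
end on synthetic data with planted ground truth.

RFX transcription factors bind a ~14-bp inverted-repeat DNA motif (the
**X-box**) in the promoters of genes required to build cilia and flagella.
Identifying which genes a factor controls *directly* requires joining several
genome-scale measurements:

1. **Binding** — ChIP-seq peaks called against an input-DNA control, with a
   gene counted as a ChIP target when a reproducible peak center falls in its
   strand-aware promoter window, TSS − 500 bp to TSS + 50 bp.
2. **Regulation** — RNA-seq contrasts of knockout vs wild-type testis at two
   postnatal ages (P21, P30), tested gene-by-gene with an exact conditional
   negative-binomial test and thresholded at p < 0.01 with nested 2×/3×/10×
   fold-change tiers.
3. **Sequence** — de novo recovery of the X-box from peak sequences by
   ZOOPS-EM (zero-or-one occurrence per sequence), plus log₂-odds PWM
   scanning of every promoter and hypergeometric enrichment tests.
4. **Context** — consistency of each gene's developmental expression
   trajectory with activation by a rising regulator, and membership in
   cilia reference lists (gold-standard list OR ≥ 1 high-confidence
   citation).

A gene is a **direct target** when it is a ChIP target *and* differentially
expressed at either age. Because the underlying real datasets are not
redistributable, the package ships a first-class synthetic-data module that
emulates every input — a compact genome with non-overlapping gene models,
planted X-box instances, Poisson ChIP coverage, NB counts with planted
knockout effects, developmental profiles and cilia evidence — and records the
planted truth so every stage can be scored.

## The statistics at the core

For gene *g* with counts *y₍gs₎*, size factors *s₍s₎* (median-of-ratios) and
dispersion *α₍g₎* (method-of-moments, shrunk toward a mean-dispersion trend
with 20 prior df), group totals are modelled as NB with effective sizes
*M = Σs*. Conditioning on the pooled total *T*, the two-sided p-value sums
the probability of every allocation of *T* between the groups that is no more
likely than the observed one — a small-sample exact test that needs no
asymptotics at n = 3 per group.

Peak calling is windowed Poisson: per 50-bp bin, λ = depth-rescaled input
(floored at the genome-wide mean), p = upper tail of the IP count,
Benjamini–Hochberg within replicate, significant bins merged, and peaks kept
only when reciprocally overlapping (≥ 50%) a peak in every replicate.

Motif discovery maximises the ZOOPS likelihood by EM over PWM, background
and occurrence rate, with restarts and phase-shift refinement; scanning
scores both strands in log₂-odds against a 0-order background with a
threshold of 60% of the maximum achievable score.

## Worked example

```bash
ciliareg all --seed 0 --workspace ws
python - <<'EOF'
import json
s = json.load(open("ws/integration_summary.json"))
m = json.load(open("ws/motif_summary.json"))
print("direct targets:", s["n_direct_targets"],
      "precision:", s["truth"]["precision"],
      "recall:", round(s["truth"]["recall"], 3))
print("discovered motif:", m["consensus"],
      "inverted-repeat score:", round(m["inverted_repeat_score"], 2))
print("cilia fraction among direct targets:",
      round(s["cilia_fraction_direct"], 3))
EOF
```

On the default configuration (2 000 genes, a 200-gene planted regulon,
4-fold knockout effects, 10× ChIP enrichment) this prints:

```
direct targets: 191 precision: 1.0 recall: 0.955
discovered motif: GTTGCCATGGCAAC inverted-repeat score: 1.0
cilia fraction among direct targets: 0.613
```

i.e. 191 of the 200 planted regulon genes are recovered as direct targets
with no false positives, the EM rediscovers the planted 14-bp palindromic
X-box exactly, and the direct-target set is enriched for cilia-annotated
genes at the simulated rate (0.6). The workspace also contains every
intermediate table: per-age DE results with fold tiers and cross-age Venn
counts, reproducible peaks with region classes and TSS-distance histograms,
promoter X-box hits with positions, per-gene profile classifications, and a
master table joining all of it (one row per ChIP-target or DE gene).

Each pipeline stage (`simulate`, `dge`, `peaks`, `motifs`, `integrate`,
`report`) can also be run individually on the same workspace, and all
thresholds live in a YAML config (`--config`).

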