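# Methods

This note documents the statistical model behind `mirlag`, the synthetic
study design used to verify it, the numerical choices that are not forced
by the science, and the known limitations.

## Study design and data model

The pipeline targets a two-genotype (rd10 mutant vs wild-type), three-
timepoint (P13, P15, P17) design with three biological replicates per
group, chosen around the onset of photoreceptor apoptosis (between P15.5
and P16 in the rd10 retina). Expression arrives as linear-scale
feature-by-sample signal matrices with per-array present/absent detection
calls; sample identity is encoded in the column name
(`<genotype>_<timepoint>_<rep>`).

Signals are modelled on the log2 scale, where array noise is approximately
additive and homoscedastic. The synthetic generator draws each expressed
feature's baseline log2 mean uniformly from [8.5, 13], adds planted
genotype×timepoint effects, and adds i.i.d. Gaussian replicate noise
(`noise_sd`, default 0.25 log2 units — a typical replicate SD for pooled
retina samples on expression arrays). Background probes are drawn from
N(`background_mu`=6, `background_sd`=0.5) on log2; a probe is called
present in an array iff its signal exceeds the 0.95 quantile of that
background model. Matrices are exported linear.

## Preprocessing

Features never detected above background in any array are removed (a
feature detected in a single array is kept), optionally intersected with a
species annotation. Quantile normalization forces every sample onto the
mean-of-sorted-columns distribution; ties within a sample receive the mean
of the quantile values they span (the dense variant), which preserves
within-sample rank order and keeps tied inputs tied. Each platform (miRNA,
mRNA) is normalized separately. In the orchestrated pipeline,
normalization precedes the detection filter so that the never-detected
probes remain available to anchor the background-level estimate.

## Differential expression

Per feature and comparison: Welch's two-sample t-test on log2 signals
(robust to unequal variances; standard for n = 3 arrays), BH adjustment
across the features of that comparison, and a signed fold change computed
from linear group means (r if r ≥ 1 else −1/r, so |FC| ≥ 1, with sign as
direction). Candidate filters: |FC| ≥ 1.5 (miRNA) or ≥ 1.3 (mRNA) and
adjusted p < 0.05. Degenerate zero-variance features receive p = 1 when
the group means agree (and p = 0 otherwise) rather than NaN.

Quality exclusions drop candidates whose median normalized signal is below
`background_margin` (default 1.2) times the background level — estimated
as the median signal of features absent in every array, falling back to
the matrix-wide 5% quantile when no such feature exists — and candidates
whose linear-scale replicate CV exceeds `cv_max` (default 0.5) in either
comparison group. Both defaults are conventions, configurable because no
standard exists.

**Power at genome scale.** With n = 3 per side the Welch statistic has
~3–4 degrees of freedom, so even a 2.8-fold planted change (1.5 log2,
noise 0.25; t ≈ 7.4) rarely yields raw p below ~1e-3. BH control at FDR
0.05 across ~1900 features therefore has very low per-feature power (a few
percent), although the same effect is detected by an unadjusted t-test
with ~97% power. This is a genuine property of triplicate array designs,
not an implementation artifact; moderated-variance (empirical-Bayes)
testing, which mitigates it, is deliberately out of scope. Consequences:
full-scale synthetic runs honestly report low DE recall, and power
assessments (below) use targeted repetition designs where FDR adjustment
is not confounded with panel composition.

## Temporal grouping

Group A (pre-onset): significant — i.e. passing the full candidate
filters, never raw p — at P15 against both the age-matched WT and the
rd10 P13 baseline, or already at P13 vs WT. The P13 clause is read
disjunctively by default because the baseline comparison is undefined at
P13 itself; a conjunctive reading (`require_p13=True`) is available.
Group B (post-onset only): significant at P17 against both references
with no filter-passing differential expression at any earlier stage. The
previous-stage exclusion uses the same filters as inclusion. A and B are
mutually exclusive by construction.

**Classification power.** Assessed per planted assay: one simulated
miRNA carrying the A (or B) temporal template, tested in all five
comparisons and classified, repeated over 200 seeds — the design under
which BH is the identity, mirroring how single candidates are followed up
by targeted assays. At the default conditions (effect 1.5 log2, noise
0.25, n = 3) the measured recovery is ≈ 99% for group A and ≈ 97% for
group B; global-null panels (100 × 100 features) keep the fraction of
adjusted-significant features well below 5%.

## Target networks

Edges (m, g) of the three networks (A@P15, A@P17, B@P17) require: the
pair predicted with ≥ 2 supporting algorithms; m in the group's filtered
DE set, with its fold change anchored at the group-defining vs-WT
comparison (P15 for group A, P17 for group B); g in the filtered mRNA DE
set at the network's timepoint (DE membership, not merely opposite sign);
g detected in at least one array; and opposite fold-change signs. No
extra magnitude threshold is applied on the mRNA side beyond the ±1.3
candidate filter. Node sets are exactly the edge endpoints. Construction
is verified against exhaustive cross-product filtering on random
instances.

The generator plants the time lag explicitly: group-A regulators are
active from P15 but their targets (opposite sign, 0.6 log2 by default)
respond only at P17, so the A@P15 network is structurally empty of true
regulations and the delayed A@P17 network carries them. Prediction tables
contain all true pairs (support 2–4) plus spurious pairs at a configurable
density whose support count is skewed low (60% single-algorithm), so
raising the minimum-support threshold k trades recall for precision. The
delayed-network study (60 seeds, dense predictions at rate 0.3 — real
prediction databases list hundreds of targets per miRNA — and a
target-rich panel so false-edge counts at k = 4 remain in the tens)
measures recall equal to the joint miRNA×mRNA DE power and strictly
increasing precision in k (≈ 0.36/0.57/0.73/0.83 for k = 1..4).

## Enrichment

Hypergeometric upper-tail over-representation (via `scipy.stats.hypergeom`)
of the inversely expressed gene set against GMT terms, BH across terms.
The universe is the set of detection-filtered mRNA features — an
expressed-in-retina background — rather than the whole annotation, to
avoid expression-bias inflation. Terms with fewer than `min_term_size`
(default 3) universe genes are not tested.

## qPCR validation

Reference assays are ranked by the SD of their mean (over technical
triplicates) Ct across biological samples; the most stable pair is chosen
and all pairwise r² of candidate Ct profiles are reported. ΔCt is the
target's mean Ct minus the arithmetic mean of the reference Cts
(equivalent to a geometric mean of linear reference quantities); ΔΔCt is
mean ΔCt(case) − mean ΔCt(control); the linear ratio is 2^(−ΔΔCt) with
amplification efficiency fixed at 2.0 (no standard-curve correction). The
per-candidate p comes from a Welch test on per-sample ΔCt values. A
candidate is confirmed when array and qPCR fold changes agree in sign and
the qPCR p is below alpha (0.05); direction-only confirmation is available
by raising alpha. Confirmation percentages are reported separately for
up- and down-regulated candidates and overall.

The synthetic Ct model is Ct = intercept (32) − log2(true expression) +
biological noise (`noise_sd`) + technical noise (`ct_tech_sd`, 0.1),
triplicate technical replicates; with both noises at zero the recovered
signed FC equals the planted ratio to machine precision, which the tests
assert at 1e-9.

## Synthetic design choices

- Planted DE fractions default to 3% (group A) + 5% (group B) of 1900
  miRNA features, i.e. 152 planted DE miRNAs, matching the scale of DE
  calls reported for this design; direction is ± with equal probability.
- Each DE miRNA regulates `targets_per_mirna` (8) distinct genes; a gene
  is assigned to at most one regulator so planted effects never collide.
- 20% of features on each panel are background probes.
- Pooled-retina replicates are collapsed to "replicate = one sample"; the
  pooling affects only the effective noise magnitude, absorbed in
  `noise_sd`.
- Annotation: 5 planted terms (80% of members drawn from responding
  target genes) plus 50 random decoy terms of size 25.
- All generators are pure functions of (config, seed); distinct
  generator stages use distinct seed streams derived from the same seed.

## What the simulations do and do not show

The generator reproduces the design's group structure, detection
behaviour, temporal templates, delayed inverse responses, noisy
predictions and Ct arithmetic. It does not model probe-level effects,
cross-hybridization, batch effects, correlated noise between features,
partial repression (every true target responds with the full planted
effect), or secondary/indirect regulation. Passing tests therefore
demonstrate that the pipeline recovers what its model class plants under
realistic noise — not that the biological conclusions of any particular
real dataset would be recovered.

## Known limitations

- No moderated-variance testing; genome-wide FDR power at n = 3 is low
  (see above) and the package reports it honestly rather than masking it.
- The exact statistic/adjustment used by vendor array software is not
  reproduced; Welch + BH is the documented stand-in.
- Enrichment is a plain hypergeometric ORA — no GO-graph propagation or
  term–term clustering.
- Amplification efficiency is fixed at 2.0; no melt-curve QC.
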