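# Methods

This note documents the models, numerical choices and open design
decisions behind `cnvprog`, and what the synthetic-data tests do and do
not establish about real array-CGH data.

## Measurement model and preprocessing

A probe's log2 ratio (L2R) is log2 of tumor over reference fluorescence.
For a clonal single-copy event at tumor-cell fraction (purity) `p`, the
expected L2R is `log2((2 + p·Δ)/2)` with Δ = +1 (gain) or −1 (loss): at
purity 1 a gain sits at +0.585 and a loss at −1.0. Probe noise is modeled
as i.i.d. Gaussian; dye bias, GC waves and batch effects are out of scope.

**Normalization** subtracts the per-sample median (a half-sample-mode
alternative is available via `method="mode"`); both are pure shifts, so
probe contrasts and all difference-based statistics are unchanged.

**DLRS** (derivative log ratio spread) estimates probe noise from lag-1
differences between genomically consecutive probes of the same
chromosome: differencing cancels the piecewise-constant copy-number
signal, and `IQR(diffs) / (1.349·√2)` is a robust, segmentation-free
estimate of the per-probe sd (1.349 is the IQR of a standard normal; √2
the sd inflation of a difference). Samples with DLRS > 0.47 are excluded;
LOH calling additionally requires DLRS < 0.3. Both boundaries are strict,
so a sample exactly at a threshold is kept/eligible.

**Centralization.** Median centering misplaces the baseline when more
than half the genome is altered — common in the most disrupted lactotroph
tumors, where the median lands on the *gained* level. The original study
anchored such profiles with FISH; without external ground truth we infer
the copy-neutral level from the segmentation itself. Segment means are
grouped into levels (0.1 log2 bins, genomic-span weights); each level is
tried as the neutral candidate, and the candidate whose competitor levels
best fit the integer copy-dosage ladder `log2((2 + p·k)/2), k ∈ {−1..2}`
(span-weighted absolute misfit) wins. For a two-level profile 0.585
apart this always picks the lower level: "neutral below gain" fits the
ladder, "neutral above a −0.585 loss" does not (a one-copy loss sits at
−1.0). A lone dominant level maps to neutral, preserving the
length-weighted-mode intuition. The step only fires when an altered
segment spans ≥ 5 Mb, the applied offset is recorded per sample, and it
is a pure shift — applied after segmentation to the segment means, which
is exact because the segmentation statistic is shift-invariant.

## Circular binary segmentation

Per chromosome, the algorithm searches all arcs `(c1, c2]` of the
circularized probe series (widths between `min_probes` = 3 and
n − 3) for the maximal two-sample t statistic comparing the arc mean
against the complement, with pooled variance. Ties in |t| break toward
the shorter arc, then the leftmost. An accepted arc contributes its one
or two interior cut points and recursion continues on the sub-segments;
the result is always a tiling.

**Acceptance at α = 10⁻⁶** cannot be decided by raw permutation (it
would need > 10⁶ permutations per test). The decision is a hybrid with
three regimes, ordered by cost:

- the single-arc t tail probability is a *lower* bound on the
  max-statistic p-value; if it already exceeds α the change-point is
  rejected outright;
- a Bonferroni bound over all candidate arcs is an *upper* bound; if it
  is below α the change-point is accepted — this analytic tail is what
  makes 10⁻⁶ operational, and for planted shifts of 0.585 at noise
  sd 0.15 it is decisively below α;
- only when the two bounds bracket α does a seeded permutation screen
  (default 100 permutations) run; at α = 10⁻⁶ this zone effectively
  always rejects, while at user-set larger α the permutation estimate
  decides.

The Bonferroni route is conservative, which is the desired direction for
false-positive control: on pure-noise genomes (10⁴ probes, sd 0.1) the
pipeline accepts essentially zero spurious change-points.

**Degenerate input.** When a segment's lag-1 differences are majority
exactly zero — only possible for noise-free piecewise-constant data,
never for continuous noise — the Gaussian tail model does not apply and
any nonzero arc statistic is treated as a certain change-point. This is
what makes exact truth recovery on noise-free synthetic profiles hold on
small chromosomes, where the pooled-t tail alone is (correctly, under
its own model) underpowered.

**State calling** is thresholded on the segment mean: gain iff
mean ≥ +0.25, loss iff mean ≤ −0.25 (inclusive boundaries). ±0.25
detects a one-copy event down to roughly 40% tumor-cell fraction; the
thresholds are configurable since the study relied on expert review
rather than a published cutoff.

**cnLOH** is called as maximal runs of homozygous SNP probes (defaults:
≥ 25 SNPs and ≥ 10 Mb) restricted to copy-neutral probes — a deletion
already explains homozygosity — for samples passing the DLRS < 0.3 gate.
This is a surrogate for a proprietary vendor caller; the run minima were
chosen so that at the generator's baseline homozygosity (0.65 per SNP)
chance runs are rare (0.65²⁵ ≈ 2·10⁻⁵ per start).

## Instability, clustering, association

The instability burden is the exact probe-count fraction altered
(deleted + gained), with gained-only, deleted-only, cnLOH-only and
CNV + cnLOH variants kept separate. Whole-chromosome (arm) events are
declared when ≥ 90% of the unit's probes share one direction, a
whole-chromosome call suppressing the matching arm calls; the threshold
is exposed because the source analysis states no rule.

Clustering uses the Jaccard distance between sets of altered probes
(any-direction binarization by default; a three-state encoding where
discordant directions do not intersect is optional). Two fully quiet
tumors are at distance 0 so they co-cluster. Ward agglomeration applies
the Lance–Williams update to *squared* distances (the ward.D2
convention) — Ward on a non-Euclidean Jaccard matrix is formally
improper, so the convention is recorded in the assignment metadata; ties
merge the lowest cluster indices first, making the hierarchy
reproducible and equal to an exhaustive hand computation.

Group comparisons use Wilcoxon rank-sum (two groups, normal
approximation with tie correction) or Kruskal–Wallis, switching to
exhaustive enumeration when the pooled sample size is ≤ 10. Fisher tests
are exact for 2×2 and Monte-Carlo (Patefield sampling of tables with
fixed margins, seeded, 10⁵ tables) for r×c.

## Prognosis models

Recurrence is modeled by logistic regression fit with IRLS (deviance
tolerance 10⁻⁸, iteration cap 100). Complete/quasi-complete separation
is detected (diverging linear predictor, or every observation classified
with residual probability < 10⁻⁶) and *flagged*, never silently
reported; the LRT against the reduced model remains finite and is still
reported. Wald 95% intervals accompany odds ratios even though
significance uses the likelihood-ratio test, matching standard reporting
practice; at n ≈ 200 Wald intervals can undercover slightly (~93–95%
observed in simulation), a known small-sample property.

The burden predictor is `log2(altered probe count + 1)`, so exp(β) is an
OR per doubling; the pseudo-count (configurable) accommodates CNV-free
tumors, on which the source analysis is silent. Multivariate models add
tumor type (whole cohort only), grade, age (entered in decades so the
coefficient reads per 10 years) and sex; within-type analyses merge
grades 1a and 1b, 1b being rare.

Genome-wide scans enter probe status as a categorical factor with
reference "normal" (df = observed non-reference levels); constant probes
are skipped and flagged, and BY adjustment runs over the actually-tested
probes. Identical status columns — probes inside one CNV region — are
fit once and broadcast, which is what keeps a 10⁴-probe scan tractable;
adjustment still counts every tested probe. Gene status is the state of
the overlapping altered segment(s) (any overlap; mixed overlaps resolve
to the larger covered fraction, exact ties flagged ambiguous and
resolved to loss for determinism); per-gene scans binarize
altered-vs-not and use BH, with within-lineage covariates age, sex,
grade (1a+1b merged). Whether the source used a three-level gene coding
is unstated; binarization is the default here.

## Expression integration

Fold changes are ratios of group means on the linear intensity scale,
sign-encoded (−x means a 1/x ratio); t-tests run on log2 values with
equal variances (config-exposed). The DE gate is |FC| ≥ 2 and p ≤ 0.05,
both inclusive. The signal-to-noise ranking floors each group sd at
0.2·|mean| (0.2 absolute at zero mean), the canonical GSEA convention,
keeping near-constant genes finite and mid-list. Preranked GSEA scores a
set by the weighted Kolmogorov–Smirnov running sum (hit mass ∝ |metric|,
miss step 1/(N−k)); a sign tie in the maximal deviation resolves to the
positive peak. The null permutes gene-set *labels* (random same-size
sets, seeded) rather than phenotypes, appropriate for a preranked list;
NES divides ES by the mean same-sign null |ES|, the nominal p is
one-sided within sign, and FDR q is the ratio-of-tails estimator over
the pooled normalized null. Significance is p < 0.05 and q < 0.25.

## Synthetic cohort generator

The generator emulates the study conditions rather than any particular
dataset: five lineages with cohort sizes 56/11/56/39/33; per-type
probability of carrying any CNV (0.43, 0.18, 0.66, 0.87, 0.73) and
marginal burden medians (0%, 0%, 4.8%, 11.1%, 38.3% of probes) with
maxima up to ~97%; gain shares of 0.7/0.5/0.8/0.9/0.7 reproducing the
reported gain excess (per-type gain:loss ratios are not published
precisely; these defaults are tuned to the reported medians only, and
set once). Burdens are drawn from a zero-inflated logit-normal whose
location is solved so the marginal median hits its target whenever fewer
than half the tumors are CNV-free. Events mix whole-chromosome (0.35),
whole-arm (0.20) and focal 1–20 Mb scopes, laid down in probe-index
space with a minimum of 5 probes per event and 3 copy-neutral probes
between events — the narrowest configuration the 3-probe segmentation
minimum can resolve, so noise-free recovery is exact by construction.
Focal events within 3 probes of a chromosome end snap to the end rather
than leave an unresolvable sliver.

Recurrence labels come from a logistic model with per-type intercepts
solved numerically so each lineage hits its target recurrence rate
(59/45/71/72/55%), grade effects OR 1.5/4.3/8.7 (1b/2a/2b vs 1a), an age
effect of OR 0.6 per 10 years, no sex effect, and — in lactotroph tumors
only — OR 1.3 per doubling of altered probes. cnLOH intervals (10–30 Mb)
are placed on CNV-free runs at the per-type observed LOH frequencies;
the homozygosity channel reads 0.65 baseline per SNP and ~1 inside
cnLOH/deletions. Expression is log-normal per gene, scaled by copy
dosage (×1.5 gain, ×0.5 loss) and by planted recurrence effects.

What passing these tests shows: the pipeline's inference is correct
under its own measurement model, at the study's dimensions and planted
effect sizes. What it does not show: robustness to wave artifacts,
probe-specific biases, subclonal heterogeneity (purity is a single
global parameter, default 1.0 — deliberately exposed so threshold
sensitivity can be probed), or mis-specified clinical confounding.

## Problem sizes and determinism

Default analysis scale is 10,000 probes — the probe-map generator
reproduces the full 99,659-probe catalog layout when asked, and all
algorithms are density-agnostic — with 195 samples; the recovery
experiments use 10 planted-signal and 10 pure-noise genomes and a
2,000-tumor lactotroph arm for parameter recovery. Every source of
randomness descends from a single seed via hashed sub-seeds, and reruns
are bit-identical.
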