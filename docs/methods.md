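# Methods

This note documents the statistical machinery implemented in `bimodalgene`:
the models and estimators, the numerical choices, what the synthetic cohorts
do and do not emulate, and the limitations a user should know about.

## Clustering and mixture model

**Univariate k-means (k = 2).** Initial centres are the minimum and the
maximum observed value of the gene, which makes the algorithm deterministic
and orients the split along the expression axis; assignment and centre
updates alternate until the labels stabilise. A point equidistant from both
centres joins the lower centre. The resulting partition carries the exact
decomposition TSS = BSS + WSS (cluster means are recomputed from the final
labels so the identity holds to machine precision). Note the min/max
initialisation is a deliberate scientific choice, not a global optimiser: on
noisy unimodal genes it can stop in a local WSS optimum, which is fine for a
screening score but means VRS is an upper bound on the globally minimal
WSS/TSS.

**Two-component normal mixture.** The density is
π·φ(μ₁,σ₁²) + (1−π)·φ(μ₂,σ₂²), fitted by EM from the k-means hard labels
(responsibilities 0/1). Convergence: |Δ log L| < 1e-8 or 500 iterations.
The unequal-variance likelihood is unbounded (a component can collapse onto
one point), so a variance floor of 1e-6 × the overall sample variance is
enforced; if a component hits the floor or empties, the model is refitted
with a single shared variance and flagged `equal_variance_used` — exactly the
regime of genes with a lone extreme outlier. If EM ends below the
one-component log-likelihood (a rare bad local optimum), the one-component
point of the mixture family is reported instead, which keeps the likelihood
ratio non-negative. The one-component log-likelihood uses the MLE variance
(divisor n) so the two models are properly nested.

The bimodality index always uses the shared-variance fit (its δ̂ = |μ̂₁−μ̂₂|/σ̂
presumes one σ); the likelihood ratio always uses the unequal-variance fit.
Hard group assignments take the component with the larger posterior, ties to
the lower-mean component.

Because the likelihood ratio and the bimodality index derive from the same
deterministically initialised EM, their gene ranks are more strongly coupled
here than in analyses where the two fits come from different software with
different initialisation. The rank correlation structure of the scores on
synthetic data reflects that: the outlier sum is among the closest partners
of the log likelihood ratio, but not always the single closest.

## Dip statistic

The dip of a sample is the smallest sup-norm distance between its empirical
CDF and any unimodal CDF (convex up to the mode, concave after, an atom
permitted at the mode). It is computed exactly by the modal-interval
iteration: over the current candidate interval, fit the greatest convex
minorant (through the lower jump corners of the ECDF) and the least concave
majorant (through the upper corners); the largest cross-distance between the
two fits — evaluated at the touch points of the opposite fit, in count
units — measures the slack needed to bridge the convex branch to the concave
branch. While it exceeds the deviations accumulated so far, the interval
shrinks to the chord endpoints achieving it and the one-sided hull
deviations of the stripped-off flanks are folded in. The dip is half the
final maximum, never below 1/(2n); tie runs absorbed by the mode's atom
terminate the iteration. The implementation was validated against an exact
linear-programming oracle (minimisation over piecewise-linear unimodal CDFs
with an atom at the mode) on several hundred random small samples including
tied values, and its simulated null percentage points at n = 50–1000 match
the published tables of the dip test (e.g. 0.037 at n = 200, α = 0.05).

P-values come from a Monte-Carlo null table of uniform samples (the
asymptotically least favourable unimodal case), with the (b+1)/(B+1)
estimator and linear interpolation in 1/√n between tabulated sizes. The
shipped table covers n ∈ {50, 100, 200, 500, 1000} at 2,000 replicates
(seed 20100525) — compact on purpose; `bimodalgene simulate-dip-null`
regenerates it at any replicate count.

## Scores: conventions that matter

* **WVRS** uses (n_j − 1)-divisor within-cluster variances and the
  (n − 1)-divisor overall variance; a singleton cluster contributes variance
  0. This is what sends one-outlier genes to the top of the WVRS list.
* **Kurtosis** is the standard unbiased excess-kurtosis estimator
  K̂ = [n(n+1)/((n−1)(n−2)(n−3))]·Σ((xᵢ−x̄)/s)⁴ − 3(n−1)²/((n−2)(n−3)).
* **Outlier sum** standardises by median and MAD (consistency-scaled by
  1.4826 by default; configurable to raw). If the MAD is zero the mean
  absolute deviation from the median substitutes. Fences are the standard
  q25 − IQR and q75 + IQR of the standardised values; a `literal` variant
  (IQR − q25, IQR + q75) is selectable — the two coincide on the upper fence
  and differ only for low outliers. The ranked score is the winning side's
  absolute sum; the signed statistic and outlier mask are kept for the
  survival split.
* **Ranking.** VRS and WVRS rank ascending, dip/log LR/BI/outlier sum
  descending, kurtosis both ways. Ties and missing scores are broken by gene
  id; unscorable genes (constant rows, fewer than 4 observations) get the
  worst ranks.

## Survival testing

The two-group logrank statistic is evaluated over distinct event times with
at least two subjects at risk (times with one subject contribute nothing),
with the hypergeometric variance term (Yᵢ−dᵢ)/(Yᵢ−1). Censored subjects at a
time remain at risk for events at that time. Because bimodal splits can
place fewer than five patients in a group, asymptotic normal p-values are
never emitted; significance is a two-sided permutation p-value over group
labels with fixed group sizes, with the +1 correction. Degenerate splits
(everyone in one group — possible for the mixture and outlier rules) are
assigned p = 1 without testing: such genes behave unimodally. Each gene's
permutation stream is seeded from (master seed, gene index) so results do not
depend on scan order or parallelism. A permutation floor of 100 guards
against meaningless p-values. The genome scan evaluates, per score family,
the grouping rule that belongs to it (k-means for VRS/WVRS/dip, mixture
posterior for kurtosis/log LR/BI, outlier-vs-main for the outlier sum).

Kaplan-Meier curves are delegated to `lifelines.KaplanMeierFitter` and
re-exported as step data with censoring marks.

## Enrichment

The N₁ prognostic genes are those with the smallest permutation p-values
(ties by gene id); the set is recomputed per grouping family. Three tests
relate them to a bimodality-ranked list of m genes:

* one-sided KS: D⁺ = maxⱼ (j/n − r₍ⱼ₎/m) against the uniform-rank null,
  exact (Smirnov) for n ≤ 40, asymptotic exp(−2nD⁺²) beyond;
* hypergeometric tail tests of the overlap with the top k (defaults
  k ∈ {200, 1000});
* the running-sum trace (+N₀ at prognostic genes, −N₁ elsewhere), which
  telescopes to 0 and whose maximal deviation localises the enrichment.

Benjamini-Hochberg q-values are computed by the step-up recursion
q₍m₎ = p₍m₎, q₍ᵢ₎ = min(q₍ᵢ₊₁₎, m·p₍ᵢ₎/i); Bonferroni-Holm by the usual
step-down with monotonicity enforcement. Both are cross-checked against
statsmodels in the test suite.

Score comparison computes 7×7 Pearson and Spearman matrices (likelihood
ratio on the log scale) over genes with complete scores and clusters the
scores by average linkage on 1 − C, exporting the merge tree as a linkage
matrix and a Newick string.

## Synthetic cohorts

Defaults emulate a single-batch microarray cohort on the log2 scale:
2,000 genes × 200 samples; baseline per-gene μ ~ U(4, 12), σ ~ U(0.2, 0.8);
90% unimodal gaussian genes and 2.5% each of

* balanced bimodal (π ∈ [0.45, 0.55], separation δ = 6σ),
* unbalanced bimodal (π ∈ [0.05, 0.2], δ = 6σ),
* single-outlier (noise-floor bulk with μ ~ U(4, 6), σ ~ U(0.1, 0.3), and
  1–2 samples at one shared overexpression level ~ U(8, 12) — the recurrent
  amplification phenotype),
* heavy-tail (t₃ noise).

Twenty prognostic genes are unbalanced-bimodal genes whose high component is
a single shared latent subgroup of 15% of patients. The sharing is
deliberate: with twenty independent high groups nearly every patient would
belong to some high group and the per-gene hazard contrast would vanish,
whereas co-expressed marker genes of one biological subgroup (the way
ESR1- or erbB2-driven groups behave) preserve it. Survival is exponential
with hazard 0.1 per time unit, multiplied by a hazard ratio of 3 for
subgroup members; censoring is independent uniform on (0, u) with u solved
so the marginal censoring fraction matches the requested rate (default 0.5).
A batch-offset option adds per-batch global shifts to reproduce, on purpose,
the pooling artifact in which concatenated datasets fake bimodality.

What the generator does **not** emulate: gene-gene correlation beyond the
prognostic subgroup, probe-level noise, skewed or batch-confounded
distributions of real RMA output. Passing recovery tests on these cohorts
therefore demonstrates correctness of the statistical machinery under the
stated generative model, not performance guarantees on any real cohort.

Problem sizes in the test and acceptance suites (e.g. 2,000-permutation
scans on 1,000–2,000 gene cohorts, 10,000-replicate dip null tables) were
chosen as the smallest sizes at which the Monte-Carlo error is comfortably
below the tolerances being checked.

## Numerical and API conventions

* Group 1 is always the lower-expression group; Z > 0 means more events in
  it than expected.
* All writers emit pandas' shortest round-trip float representation, so a
  write/read cycle is exact and identical seeds yield byte-identical output
  files.
* Randomised routines take explicit integer seeds; nothing reads global RNG
  state.
* Errors are typed (`DegenerateInputError`, `InsufficientDataError`,
  `DegenerateGroupError`, `ConfigError`, `ParseError`, `ValidationError`,
  `AlignmentError`, `ExtrapolationError`) so the genome-wide drivers can
  distinguish "skip this gene" from "abort".

## Known limitations

* The permutation test assumes exchangeability of patients under the null;
  confounded cohorts (batch, treatment) violate it.
* The likelihood-ratio null distribution depends on the EM configuration
  (variance floor, initialisation); its values are comparable within a run
  but not across tools.
* The outlier-sum split can produce one-patient groups; their p-values are
  valid permutation p-values but have a high floor (small groups bound how
  extreme |Z| can get).
* KS enrichment p-values below ~1e-16 underflow the asymptotic formula and
  are reported as 0.
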