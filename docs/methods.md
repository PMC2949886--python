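# Methods

## Problem and model

Two groups of independent samples (sizes nX, nY) are profiled on m features
(genes, probes); per feature the null hypothesis H0i: μiA = μiB of no
differential expression is tested two-sidedly.  Before testing, practitioners
often *filter*: score each feature with a statistic W and keep only those
with W ≥ w, hoping a smaller m buys a weaker multiple-testing penalty and
more power.  FDR procedures, however, assume null p-values are uniform on
[0, 1].  Writing Vi = 1 for null features and Ri = 1{W(Zi) ≥ w} for retained
ones, the retained-null p-value cdf is

    G0W(u) = Pr{Pi ≤ u | Vi = 1, Ri = 1},

and FDR estimates stay unbiased iff G0W(u) = u for all u — i.e. iff the
filter removes null features with equal probability from the whole p-value
range.  A filter associated with the test statistic (fold change with a t
test) violates this; filters independent of it (average signal in a balanced
design) do not.  This package quantifies the violation three ways: exactly
(distribution theory), empirically (simulation), and inferentially on real
data (a permutation test).

## Filter statistics

For each feature with group means X̄, Ȳ and all-sample variance S²:

| name        | W(Z)            | notes                                   |
|-------------|-----------------|-----------------------------------------|
| signal      | (X̄ + Ȳ)/2      | average intensity over both groups       |
| fold_change | \|X̄ − Ȳ\|      | absolute (log-scale) fold change         |
| variance    | S²              | overall sample variance, n−1 denominator |
| best        | oracle          | removes nulls first (simulation only)    |
| random      | none            | uniform random removal (simulation only) |

Experiments parameterise by the fraction removed (so every filter removes
exactly the same count, `round(fraction_out·m)`); w is derived as the
smallest retained value.  Ties at the cut are broken by original feature
order (earlier features retained first), which makes the retained count
exact — the convention matters only for degenerate inputs.  The variance
filter uses the variance pooled across all n samples about the grand mean
(the genefilter convention); a within-group pooling would be a different
statistic and is not offered.

## Tests

The pooled two-sample t statistic T = (X̄ − Ȳ)/(Sp·√(1/nX + 1/nY)) with
Sp² = [(nX−1)SX² + (nY−1)SY²]/ν, ν = nX + nY − 2, assumes equal group
variances; its two-sided p-value is P = 2[1 − F0(|T|)] with F0 the central
t cdf.  Welch's variant is deliberately absent so that the distribution
theory below applies to the same statistic the pipeline computes.  Constant
features raise an error rather than receiving an arbitrary p-value.  A
Wilcoxon rank-sum alternative (exact null distribution for
min(nX, nY) ≤ 10 without ties, normal approximation with continuity
correction otherwise) supports robustness checks.

## FDR procedures

All step-up procedures are implemented through one primitive: with Gm the
empirical cdf of the p-values, reject every Pi ≤ u* where
u* = max{u : g(u, ϕ) ≤ Gm(u)}.  The g-forms are u/ϕ (BH), π̂0·u/ϕ (adaptive
BH) and BH at level ϕ/c(m), c(m) = Σ_{j≤m} 1/j (BY).  Classical
order-statistic implementations exist alongside and are asserted equal on
randomized inputs, with statsmodels as a further independent cross-check.
The adaptive π̂0 uses the lowest-slope estimator — slopes
S_i = (1 − P_(i))/(m + 1 − i) scanned to the first decrease, then
m̂0 = min(m, 1/S_j + 1) — with Storey's λ-based estimator available as a
plug-in.  Storey's q-value procedure uses fixed λ = 0.5 by default (the
original software's spline smoother is intentionally not reimplemented) and
refuses inputs whose p-values do not reach beyond λ: after fold-change
filtering the p-value range is truncated away from 1 and the π̂0 estimator
degenerates, which is why that combination is invalid.  Bonferroni is
included as a comparison baseline.  With no qualifying order statistic,
u* = 0 and nothing is rejected — the convention the achieved-FDR
bookkeeping relies on (FDP = 0 when no rejections).

## Distribution theory after filtering

With c = √(1/nX + 1/nY), the mean difference D = X̄ − Ȳ ~ N(Δ, (σc)²) is
independent of Sp = σ·χν/√ν, and T = D/(cSp); Δ = δσc links the effect to
the t noncentrality δ.  Each filter's retention event is a region in
(D, Sp):

* fold change: |D| ≥ w;
* variance: the within/between decomposition (n−1)S² = νSp² + D²/c² is an
  identity, so S² ≥ w becomes |D| ≥ c·√((n−1)w − νSp²)₊ — the exact
  statistic is conditioned on, not a within-group approximation;
* signal: M = (X̄ + Ȳ)/2 is independent of (D, Sp) when nX = nY, so
  conditioning changes nothing — the analytic core of the signal filter's
  neutrality.  Unbalanced designs are rejected rather than approximated.

Conditional cdfs/densities of T are one-dimensional adaptive quadratures
over Sp against closed-form Gaussian expressions in D (absolute tolerance
1e−8; every returned density integrates to 1 within 1e−6).  Thresholds are
solved from the fraction removed under the null/alternative *mixture* law
of W (π0 null + (1 − π0) alternative, effect signs ±δ with equal
probability), mirroring the empirical pipeline which cuts one pooled
statistic vector.  P-value laws follow through P = 2[1 − F0(|T|)].

The asymptotic BH operating point after filtering solves
GaW(u) = [1/(1 − π0W)]·[u/ϕ − π0W·G0W(u)], i.e. GmW(u) = u/ϕ, for the
largest u ∈ (0, 1] (log-grid bracketing plus bisection to 1e−10); power is
GaW(u*).  When no positive root exists the procedure reports (0, 0): the
asymptotic BH run rejects a vanishing fraction.  This happens at the
standard weak-signal conditions (δ = 1, π0 = 0.8, ϕ = 0.05, ν = 8), where
lim GaW(u)/u ≈ 68 gives (1 − π0)·68 < 1/ϕ − π0; a 10⁶-feature Monte-Carlo
BH run confirms essentially zero power there.  Finite-m power at those
conditions is a fluctuation effect, measured by the simulation engine, not
by this asymptotic construction.

Reference curves for the retained null proportion are closed-form:
best filter π0(x) = max(0, (π0 − x)/(1 − x)), random filter π0(x) = π0.

## The FDR-bias permutation test

`FdrBiasTest(dataset, filter_name, fraction_out, ...).fit(seed)` estimates
G0W without knowing which features are null: permute the sample-to-group
labels (making every feature null while preserving the filter–test
association), recompute **both** the filter statistic and the p-values on
the permuted data, filter, and test the retained p-values against U[0, 1]
with a one-sample Kolmogorov-Smirnov test, giving q.  Repeating N0 times
yields Gq, itself KS-tested against U[0, 1]; a small final p-value means
the filter biases FDR estimation on these data.

Numerical choices:

* Per-round check: one-sided KS on D⁺ = sup(ecdf − u) by default (the
  surplus of small p-values is what inflates the FDR; less conservative
  than two-sided), with the minimum BH-adjusted p-value (Simes) as an
  alternative mode.  Exact KS null distribution for n ≤ 100, asymptotic
  above.
* N0 defaults to 100; the meta-test needs N0 ≥ 20.
* Distinct-permutation sampling: with nX = nY = 5 only C(10,5)/2 = 126
  label splits are distinct (every statistic here is invariant under the
  A/B swap).  Drawing rounds with replacement would duplicate ~30 of 100 q
  values, and the tied atoms make the meta KS test anticonservative even on
  pure-null data.  When the split space is enumerable and at least N0
  large, rounds therefore sample distinct assignments without replacement;
  independent random permutations are the fallback for large designs.
* Sub-seeding: all randomness derives from one `SeedSequence(seed)`, so
  reports are bit-reproducible.

## Simulation engine

`generate_dataset` draws Gaussian values with s.d. σ: `round(π0·m)` null
features have both group means 0; alternatives shift group A by ±Δ
(Δ = δσc, sign per feature with equal probability), so δ is exactly the t
noncentrality of alternative features.  The defaults — m = 1000, π0 = 0.8,
nX = nY = 5 (ν = 8), δ = 1, σ = 1, ϕ = 0.05, 200 replicate datasets —
are the standard study conditions throughout this package; 200 replicates
roughly doubles the Monte-Carlo s.e. of a 1000-replicate run in exchange
for a five-fold cheaper default.  What the generator does *not* emulate:
per-feature baseline intensity differences (all baselines are 0, so the
signal statistic carries only noise plus half the effect shift),
inter-feature correlation, heavy-tailed noise, and a spread of effect
sizes (one symmetric δ rather than a continuous mixture).  Passing tests
therefore demonstrate the methodology under idealised independence, not
robustness to correlated or heteroskedastic data.

`run_grid` measures per (filter × fraction × FDR method) cell: achieved FDR
(null fraction among rejections, 0 when none), observed power (rejected
alternatives over *all* alternatives of the original dataset — filtered-out
alternatives count against power, so the achievable maximum can be below
1), and the retained null proportion, each with Monte-Carlo standard
errors.  Cells share the simulated datasets, so comparisons between cells
should be made on paired per-dataset differences.  `post_fdr_filter`
models the separate practice of shortening an already-FDR-corrected
discovery list by a filter, recomputing the within-list false-positive
fraction.

## Known limitations

* Two-group designs only; no correlated-feature theory or resampling-based
  FDR variants.
* The asymptotic power construction has no Wilcoxon counterpart (use the
  simulation engine with `test="wilcoxon"`).
* The q-value implementation is the plain λ-estimator form, adequate for
  the comparisons here but not a replacement for the full qvalue software.
* The bias test's meta-KS inherits the usual permutation-test granularity:
  in tiny designs (fewer distinct splits than N0) rounds repeat
  permutations and the final p-value becomes conservative-to-erratic.
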