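# filterfdr

Feature filtering before differential-expression testing — dropping probes
with low signal, small fold change, or low variance — is meant to soften the
multiple-testing penalty and buy power.  But every FDR procedure in routine
use (Benjamini–Hochberg and relatives, q-values) assumes null p-values are
uniform on [0, 1], and a filter whose statistic is associated with the test
statistic breaks that assumption for the features it keeps.  The result is a
*biased* FDR: a list advertised at 5% false discoveries can carry
substantially more.

`filterfdr` is for analysts of two-group high-dimensional studies
(microarray-style expression matrices) who want to know whether their filter
is safe.  It provides:

* the common filter statistics — signal (X̄+Ȳ)/2, fold change |X̄−Ȳ|,
  overall variance S² — with fraction-based filtering, plus oracle
  best/random reference filters for simulations;
* per-feature pooled t and Wilcoxon rank-sum tests;
* FDR procedures in the unified step-up form
  u\* = max{u : g(u, ϕ) ≤ Gm(u)} (BH, adaptive BH with the lowest-slope π̂0,
  BY, Storey q-values, Bonferroni), where Gm is the empirical p-value cdf;
* exact post-filter distribution theory for the t statistic: conditional
  cdfs/densities given {W ≥ w}, p-value densities after filtering, and the
  asymptotic BH power via the cdf intersection
  GaW(u) = [1/(1−π0W)][u/ϕ − π0W·G0W(u)];
* a simulation engine measuring achieved FDR, observed power and retained
  null proportion across filter × fraction × method grids;
* **the FDR-bias permutation test**: permute group labels (every feature
  becomes null, filter–test association preserved), re-filter, KS-test the
  retained p-values against U[0,1], repeat N0 times, and meta-KS-test the
  round p-values — a data-driven verdict on whether a given filter biases
  FDR estimation, no truth labels needed.

## Worked example

```python
from filterfdr import SimulationConfig, generate_dataset, FdrBiasTest

cfg = SimulationConfig(seed=1)              # m=1000, pi0=0.8, nX=nY=5, delta=1
dataset, truth = generate_dataset(cfg, 20100907)

print(FdrBiasTest(dataset, "fold_change", fraction_out=0.3,
                  n_permutations=100).fit(seed=0).summary())
```

```
FDR-bias permutation test
======================================================
filter statistic:     fold_change
fraction filtered out: 0.3
test statistic:       t
permutation rounds:   100 (seed 0)
per-round check:      one-sided KS (D+)
------------------------------------------------------
round p-values q:     min 4.31e-58, median 1.67e-45, max 1.19e-31
final p-value:        0
verdict (alpha=0.05):  filtering BIASES the null p-value distribution (FDR estimates unreliable)
```

Every permutation round finds the fold-change-filtered "null" p-values
wildly non-uniform (median round p ≈ 1.7e−45): this filter invalidates the
FDR correction.  The same test with the signal filter returns a final
p-value of 0.2734 — no evidence of bias.  The simulation engine shows what
that bias does to realised error rates (means over 200 simulated datasets,
nominal FDR 5%):

```python
from filterfdr import run_grid
print(run_grid(SimulationConfig(seed=1, filters=("fold_change", "variance"),
                                fractions=(0.0, 0.5))))
```

```
     filter  fraction_out  achieved_fdr_mean  achieved_fdr_se  power_mean  pi0_retained_mean
fold_change           0.0            0.05000         0.015038    0.000400            0.80000
fold_change           0.5            0.08875         0.018578    0.001150            0.74290
   variance           0.0            0.05000         0.015038    0.000400            0.80000
   variance           0.5            0.03250         0.011797    0.000575            0.77194
```

Unfiltered BH realises its nominal 5%; removing half the features by fold
change inflates the achieved FDR to ~8.9%, while the variance filter stays
on the safe side (~3.3%).

A `filterfdr` command-line tool mirrors the library
(`filter`, `test`, `fdr`, `bias-test`, `theory`, `simulate` subcommands;
every run writes a JSON manifest with its seed and configuration).
Real data enter as a tab-delimited feature × sample matrix plus a
two-column sample/group phenotype file — see
`filterfdr bias-test --help`.

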