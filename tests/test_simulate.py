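import numpy as np
import pytest
from scipy import special, stats

from filterfdr import (SimulationConfig, achieved_fdr, bh, generate_dataset,
                       observed_power, pi0_retained, pooled_t, post_fdr_filter,
                       run_grid)
from filterfdr.filters import foldchange_statistic, oracle_best_filter


class TestGenerator:
    def test_pure_null_pvalues_uniform(self):
        cfg = SimulationConfig(m=10000, pi0=1.0, n_datasets=1, seed=0)
        ds, truth = generate_dataset(cfg, 3)
        assert truth.all()
        assert stats.kstest(pooled_t(ds).pvalue, "uniform").pvalue > 0.01

    def test_zero_delta_alternatives_behave_as_null(self):
        cfg = SimulationConfig(m=5000, pi0=0.0, delta=0.0, n_datasets=1, seed=0)
        ds, truth = generate_dataset(cfg, 4)
        assert not truth.any()
        assert stats.kstest(pooled_t(ds).pvalue, "uniform").pvalue > 0.01

    def test_alternative_t_moment_matches_noncentrality(self):
        """|E[T]| for alternative features equals the mean of a noncentral t
        with delta=1: delta*sqrt(v/2)*Gamma((v-1)/2)/Gamma(v/2)."""
        from scipy import integrate
        cfg = SimulationConfig(m=10000, pi0=0.8, n_datasets=1, seed=0)
        ds, truth = generate_dataset(cfg, 9)
        t_alt = pooled_t(ds).statistic[~truth]
        # effect signs are +/- with equal probability, so compare E|T| with
        # the first absolute moment of nct(v=8, delta=1) by quadrature
        expected = integrate.quad(lambda t: abs(t) * stats.nct.pdf(t, 8, 1.0),
                                  -np.inf, np.inf, limit=200)[0]
        observed = np.abs(t_alt).mean()
        se = np.abs(t_alt).std(ddof=1) / np.sqrt(t_alt.size)
        assert abs(observed - expected) < 3 * se

    def test_null_count_exact(self):
        cfg = SimulationConfig(m=1000, pi0=0.8, n_datasets=1, seed=0)
        _, truth = generate_dataset(cfg, 1)
        assert truth.sum() == 800


class TestMetrics:
    def test_achieved_fdr_counting(self):
        truth = np.array([True, False, False, True])
        rejected = np.array([True, True, True, False])
        assert achieved_fdr(rejected, truth) == pytest.approx(1 / 3)
        assert achieved_fdr(np.zeros(4, bool), truth) == 0.0
        with pytest.raises(ValueError):
            achieved_fdr(rejected[:3], truth)

    def test_observed_power_counting(self):
        truth = np.array([True] + [False] * 4)
        rejected = np.array([False, True, True, False, False])
        assert observed_power(rejected, truth) == pytest.approx(0.5)
        assert observed_power(np.zeros(5, bool), truth) == 0.0

    def test_power_denominator_is_original_alternative_count(self):
        """Filtered-out alternatives still count in the denominator, so the
        maximum achievable power after filtering can be below 1."""
        truth = np.zeros(10, bool)
        truth[:5] = True                      # 5 nulls, 5 alternatives
        rejected = np.zeros(10, bool)
        rejected[5:7] = True                  # 2 of 5 alternatives
        assert observed_power(rejected, truth) == pytest.approx(0.4)

    def test_metrics_match_set_arithmetic_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            truth = rng.random(60) < 0.7
            rejected = rng.random(60) < 0.2
            nulls = set(np.flatnonzero(truth))
            rej = set(np.flatnonzero(rejected))
            alts = set(np.flatnonzero(~truth))
            exp_fdr = len(rej & nulls) / len(rej) if rej else 0.0
            exp_pow = len(rej & alts) / len(alts) if alts else 0.0
            assert achieved_fdr(rejected, truth) == pytest.approx(exp_fdr)
            assert observed_power(rejected, truth) == pytest.approx(exp_pow)

    def test_pi0_retained_guards_empty(self):
        with pytest.raises(ValueError):
            pi0_retained(np.zeros(3, bool), np.ones(3, bool))


class TestRunGrid:
    def test_bit_reproducible(self):
        cfg = SimulationConfig(m=200, n_datasets=5, seed=77,
                               filters=("fold_change", "random"),
                               fractions=(0.0, 0.3))
        a, b = run_grid(cfg), run_grid(cfg)
        assert a.equals(b)

    def test_best_filter_pi0_deterministic(self):
        cfg = SimulationConfig(m=500, n_datasets=3, seed=1, filters=("best",),
                               fractions=(0.5,))
        table = run_grid(cfg)
        assert table["pi0_retained_mean"].iloc[0] == pytest.approx(0.6)
        assert table["pi0_retained_se"].iloc[0] == 0.0

    def test_qvalue_foldchange_combination_rejected(self):
        with pytest.raises(ValueError, match="q-value"):
            SimulationConfig(fdr_methods=("qvalue",), filters=("fold_change",))

    def test_wilcoxon_swap_same_qualitative_fdr_ordering(self):
        """The fold-change filter inflates the achieved FDR under the
        rank-sum test just as under the t test."""
        cfg = SimulationConfig(m=300, n_datasets=25, seed=33, test="wilcoxon",
                               filters=("fold_change",), fractions=(0.0, 0.5))
        table = run_grid(cfg).set_index("fraction_out")
        assert (table.loc[0.5, "achieved_fdr_mean"]
                >= table.loc[0.0, "achieved_fdr_mean"])


class TestPostFdrFilter:
    def _setup(self, seed=0):
        cfg = SimulationConfig(m=800, pi0=0.8, delta=2.0, n_datasets=1, seed=0)
        ds, truth = generate_dataset(cfg, seed)
        res = bh(pooled_t(ds).pvalue, 0.2)
        return ds, truth, res

    def test_fraction_zero_identity(self):
        ds, truth, res = self._setup()
        fc = foldchange_statistic(ds)
        assert post_fdr_filter(res, fc, 0.0, truth) == (
            achieved_fdr(res.rejected, truth), observed_power(res.rejected, truth))

    def test_shortened_list_power_never_increases(self):
        ds, truth, res = self._setup()
        fc = foldchange_statistic(ds)
        base_power = observed_power(res.rejected, truth)
        for frac in (0.1, 0.3, 0.6):
            _, power = post_fdr_filter(res, fc, frac, truth)
            assert power <= base_power + 1e-12

    def test_no_rejections_yield_zeros(self):
        ds, truth, _ = self._setup()
        from filterfdr.fdr import FdrResult
        empty = FdrResult("bh", 0.05, 0.0, np.zeros(800, bool))
        assert post_fdr_filter(empty, foldchange_statistic(ds), 0.3, truth) == (0.0, 0.0)

    def test_foldchange_postfilter_shifts_list_fdr(self):
        """Prioritising an FDR list by fold change changes the within-list
        false-positive fraction relative to the nominal level."""
        cfg = SimulationConfig(m=800, pi0=0.8, delta=2.0, n_datasets=1, seed=0)
        before, after = [], []
        for child in np.random.SeedSequence(44).spawn(60):
            ds, truth = generate_dataset(cfg, child)
            res = bh(pooled_t(ds).pvalue, 0.2)
            if res.n_rejected == 0:
                continue
            before.append(achieved_fdr(res.rejected, truth))
            after.append(post_fdr_filter(res, foldchange_statistic(ds), 0.5, truth)[0])
        diff = np.array(after) - np.array(before)
        se = diff.std(ddof=1) / np.sqrt(diff.size)
        assert abs(diff.mean()) > 3 * se
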