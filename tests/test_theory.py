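import numpy as np
import pytest
from scipy import integrate, stats

from filterfdr.theory import (ModelSpec, analytic_power_after_filter,
                              conditional_t_cdf, filter_stat_cdf,
                              pi0_reference_curves, pvalue_density_after_filter,
                              solve_filter_threshold)

T_GRID = np.linspace(-4.0, 4.0, 9)


def _draw_null_components(n, seed):
    """(D, Sp, T) draws under the null of the standard balanced model
    (sigma=1, nX=nY=5: c^2=0.4, v=8) — the MC oracle shared below."""
    rng = np.random.default_rng(seed)
    d = rng.normal(0.0, np.sqrt(0.4), n)
    sp = np.sqrt(stats.chi2.rvs(8, size=n, random_state=rng) / 8)
    return d, sp, d / (np.sqrt(0.4) * sp)


class TestConditionalTCdf:
    def test_no_filtering_recovers_unconditional_cdf(self):
        null = conditional_t_cdf(ModelSpec(delta=0.0), "fold_change", -np.inf, T_GRID)
        np.testing.assert_allclose(null.cdf, stats.t.cdf(T_GRID, 8), atol=1e-8)
        alt = conditional_t_cdf(ModelSpec(delta=1.0), "fold_change", 0.0, T_GRID)
        np.testing.assert_allclose(alt.cdf, stats.nct.cdf(T_GRID, 8, 1.0), atol=1e-8)

    def test_signal_filter_leaves_t_law_unchanged(self):
        """Analytic independence of (X-bar+Y-bar)/2 from T in balanced designs."""
        for w in (0.1, 0.5):
            cond = conditional_t_cdf(ModelSpec(delta=1.0), "signal", w, T_GRID)
            np.testing.assert_allclose(cond.cdf, stats.nct.cdf(T_GRID, 8, 1.0),
                                       atol=1e-8)

    def test_signal_independence_confirmed_by_sampling(self):
        """Empirical check that conditioning on high average signal does not
        move the t distribution (balanced Gaussian samples)."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=(200000, 5))
        y = rng.normal(size=(200000, 5))
        d = x.mean(1) - y.mean(1)
        sp = np.sqrt((4 * x.var(1, ddof=1) + 4 * y.var(1, ddof=1)) / 8)
        t = d / (sp * np.sqrt(0.4))
        m_stat = (x.mean(1) + y.mean(1)) / 2
        keep = m_stat >= np.quantile(m_stat, 0.5)
        ks = stats.ks_2samp(t[keep], t[~keep])
        assert ks.pvalue > 0.01

    def test_foldchange_conditioning_matches_monte_carlo(self):
        model = ModelSpec(delta=0.0)
        w = solve_filter_threshold(model, "fold_change", 0.25)
        d, _, t = _draw_null_components(400000, seed=5)
        keep = np.abs(d) >= w
        curve = conditional_t_cdf(model, "fold_change", w, T_GRID)
        emp = np.array([(t[keep] <= ti).mean() for ti in T_GRID])
        se = np.sqrt(np.maximum(emp * (1 - emp), 1e-12) / keep.sum())
        assert np.all(np.abs(curve.cdf - emp) <= 3 * se)

    def test_variance_conditioning_matches_monte_carlo(self):
        """Conditioning uses the exact overall-variance decomposition
        (n-1) S^2 = v Sp^2 + D^2/c^2."""
        model = ModelSpec(delta=0.0)
        w = solve_filter_threshold(ModelSpec(delta=1.0), "variance", 0.25)
        d, sp, t = _draw_null_components(400000, seed=6)
        s2 = (8 * sp**2 + d**2 / 0.4) / 9
        keep = s2 >= w
        curve = conditional_t_cdf(model, "variance", w, T_GRID)
        emp = np.array([(t[keep] <= ti).mean() for ti in T_GRID])
        se = np.sqrt(np.maximum(emp * (1 - emp), 1e-12) / keep.sum())
        assert np.all(np.abs(curve.cdf - emp) <= 3 * se)

    def test_cdf_monotone(self):
        model = ModelSpec(delta=1.0)
        w = solve_filter_threshold(model, "fold_change", 0.4)
        curve = conditional_t_cdf(model, "fold_change", w, np.linspace(-6, 6, 25))
        assert np.all(np.diff(curve.cdf) >= -1e-10)


class TestThresholdSolver:
    @pytest.mark.parametrize("filter_name", ["fold_change", "variance", "signal"])
    @pytest.mark.parametrize("fraction", [0.1, 0.25, 0.5])
    def test_mixture_quantile_inverts(self, filter_name, fraction):
        model = ModelSpec(delta=1.0, pi0=0.8)
        w = solve_filter_threshold(model, filter_name, fraction)
        mix = (0.8 * filter_stat_cdf(model, filter_name, w, 0.0)
               + 0.2 * filter_stat_cdf(model, filter_name, w, 1.0))
        assert mix == pytest.approx(fraction, abs=1e-9)


class TestPvalueDensity:
    def test_unfiltered_null_density_is_uniform(self):
        curve = pvalue_density_after_filter(ModelSpec(delta=0.0), "fold_change", 0.0,
                                            np.linspace(0.05, 0.95, 7))
        np.testing.assert_allclose(curve.density, 1.0, atol=1e-8)

    def test_foldchange_depletes_large_null_pvalues(self):
        """The fold-change filter removes permuted-null features with p near 1
        and enriches small p — the density crosses 1 downward."""
        curve = pvalue_density_after_filter(ModelSpec(delta=0.0, pi0=0.8),
                                            "fold_change", 0.25,
                                            np.array([0.02, 0.98]))
        assert curve.density[0] > 1.0
        assert curve.density[1] < 1.0

    def test_variance_filter_removes_more_small_pvalues_than_fold_change(self):
        """Among removed alternative features the variance filter discards
        far more small p-values than the fold-change filter: the fold-change
        filter's retained-set enrichment at small p dwarfs the variance
        filter's (which is mild — a 2M-draw MC confirms the direction)."""
        model = ModelSpec(delta=1.0, pi0=0.8)
        grid = np.array([0.005, 0.02])
        base = pvalue_density_after_filter(model, "variance", 0.0, grid,
                                           component="alternative").density
        var = pvalue_density_after_filter(model, "variance", 0.25, grid,
                                          component="alternative").density
        fc = pvalue_density_after_filter(model, "fold_change", 0.25, grid,
                                         component="alternative").density
        assert np.all(fc > var)          # fold change enriches small p far more
        assert np.all(var < 1.2 * base)  # variance filter's effect is mild

    def test_null_density_integrates_to_one(self):
        model = ModelSpec(delta=0.0, pi0=0.8)
        f = lambda p: pvalue_density_after_filter(model, "fold_change", 0.25,
                                                  [p]).density[0]
        total, err = integrate.quad(f, 1e-9, 1 - 1e-9, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)


class TestAnalyticPower:
    def test_supercritical_operating_point_matches_monte_carlo(self):
        """At delta=2, pi0=0.5, phi=0.1 the asymptotic BH run rejects a
        positive fraction; the intersection solution must match a large-m
        mixture simulation."""
        from filterfdr.fdr import bh
        model = ModelSpec(delta=2.0, pi0=0.5)
        u_star, power = analytic_power_after_filter(model, "fold_change", 0.0, 0.1)
        assert u_star > 0
        rng = np.random.default_rng(11)
        n = 400000
        null = rng.random(n) < 0.5
        delta = np.where(null, 0.0, 2.0) * rng.choice([-1.0, 1.0], n)
        d = rng.normal(delta * np.sqrt(0.4), np.sqrt(0.4))
        sp = np.sqrt(stats.chi2.rvs(8, size=n, random_state=rng) / 8)
        p = 2 * stats.t.sf(np.abs(d / (np.sqrt(0.4) * sp)), 8)
        rej = bh(p, 0.1).rejected
        power_mc = (rej & ~null).sum() / (~null).sum()
        se = np.sqrt(power_mc * (1 - power_mc) / (~null).sum())
        assert abs(power - power_mc) <= 3 * se

    def test_filter_power_ordering_fold_change_best(self):
        """Fold change boosts the asymptotic power most; signal costs power
        (it removes down-shifted alternatives, raising the retained pi0)."""
        model = ModelSpec(delta=2.0, pi0=0.5)
        _, p_none = analytic_power_after_filter(model, "fold_change", 0.0, 0.1)
        _, p_fc = analytic_power_after_filter(model, "fold_change", 0.25, 0.1)
        _, p_var = analytic_power_after_filter(model, "variance", 0.25, 0.1)
        _, p_sig = analytic_power_after_filter(model, "signal", 0.25, 0.1)
        assert p_fc > p_var > p_none > p_sig

    def test_subcritical_standard_conditions_power_zero(self):
        """At the weak standard signal (delta=1, pi0=0.8, phi=0.05) the
        asymptotic BH intersection has no positive root: power 0."""
        u_star, power = analytic_power_after_filter(ModelSpec(delta=1.0, pi0=0.8),
                                                    "fold_change", 0.0, 0.05)
        assert (u_star, power) == (0.0, 0.0)

    def test_power_vanishes_as_phi_shrinks(self):
        model = ModelSpec(delta=2.0, pi0=0.5)
        powers = [analytic_power_after_filter(model, "fold_change", 0.0, phi)[1]
                  for phi in (0.1, 0.02, 0.002)]
        assert powers[0] > 0
        assert powers[0] >= powers[1] >= powers[2]
        assert powers[2] == 0.0


class TestPi0ReferenceCurves:
    def test_counting_values(self):
        curves = pi0_reference_curves(0.8, [0.0, 0.5, 0.8])
        np.testing.assert_allclose(curves["best"], [0.8, 0.6, 0.0], atol=1e-12)
        np.testing.assert_allclose(curves["random"], [0.8, 0.8, 0.8])

    def test_domain_validation(self):
        with pytest.raises(ValueError):
            pi0_reference_curves(1.2, [0.1])
        with pytest.raises(ValueError):
            pi0_reference_curves(0.8, [1.0])
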