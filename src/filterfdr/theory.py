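"""Analytic/numerical distribution theory for the two-sample t after filtering.

Model: two groups of Gaussian samples with common within-group s.d. sigma,
group sizes nX, nY.  Write c = sqrt(1/nX + 1/nY), v = nX + nY − 2.  The mean
difference D = X̄ − Ȳ is N(Delta, (sigma c)^2) with Delta = delta·sigma·c
(delta is the noncentrality of T), independent of the pooled s.d.
Sp = sigma·chi_v/sqrt(v), and T = D / (c·Sp).

The filter statistics are functions of (D, Sp, M):

* fold change   |D|
* variance      S² = (v·Sp² + D²/c²)/(n − 1)   (overall sample variance;
  the within/between decomposition makes it an exact function of (D, Sp))
* signal        M = (X̄ + Ȳ)/2, independent of (D, Sp) when nX = nY — the
  analytic reason the signal filter cannot distort the null p-value
  distribution in a balanced design.

Conditioning T on {W >= w} therefore restricts (D, Sp) to a region of the
form {|D| >= d0(Sp)} and all post-filter laws follow by one-dimensional
adaptive quadrature over Sp against closed-form Gaussian expressions in D.
The p-value laws follow through P = 2·[1 − F0(|T|)] with F0 the central t
cdf at v degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, stats

__all__ = [
    "ModelSpec",
    "DistributionCurve",
    "conditional_t_cdf",
    "pvalue_density_after_filter",
    "analytic_power_after_filter",
    "solve_filter_threshold",
    "filter_stat_cdf",
    "pi0_reference_curves",
]

_QUAD_OPTS = dict(epsabs=1e-11, epsrel=1e-10, limit=200)
_MIN_COND_PROB = 1e-12


@dataclass
class ModelSpec:
    """Two-group Gaussian model for one feature class.

    delta is the t noncentrality under the alternative (0 under the null);
    the group-mean difference Delta = delta*sigma*sqrt(1/nX+1/nY) is derived.
    pi0 is the null proportion used when thresholds are solved under the
    null/alternative mixture.
    """

    nX: int = 5
    nY: int = 5
    sigma: float = 1.0
    delta: float = 1.0
    pi0: float = 0.8

    def __post_init__(self):
        if self.nX < 2 or self.nY < 2:
            raise ValueError("need nX, nY >= 2")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 < self.pi0 < 1.0:
            raise ValueError("pi0 must be in (0, 1)")

    @property
    def n(self) -> int:
        return self.nX + self.nY

    @property
    def df(self) -> int:
        return self.nX + self.nY - 2

    @property
    def c(self) -> float:
        return float(np.sqrt(1.0 / self.nX + 1.0 / self.nY))

    @property
    def mean_difference(self) -> float:
        """Delta = delta * sigma * c."""
        return self.delta * self.sigma * self.c

    def sp_dist(self):
        """Distribution of the pooled s.d. Sp (scaled chi)."""
        return stats.chi(df=self.df, scale=self.sigma / np.sqrt(self.df))


@dataclass
class DistributionCurve:
    """A density and/or cdf evaluated on a grid, with its conditioning."""

    grid: np.ndarray
    density: np.ndarray | None = None
    cdf: np.ndarray | None = None
    conditioning: dict = field(default_factory=dict)


# -- geometry of the conditioning region ------------------------------------


def _d0_fn(model: ModelSpec, filter_name: str, w: float):
    """Lower bound d0(s) on |D| imposed by {W >= w}, as a function of s=Sp."""
    c, v, n = model.c, model.df, model.n
    if filter_name == "fold_change":
        return lambda s: w
    if filter_name == "variance":
        return lambda s: c * np.sqrt(max(0.0, (n - 1) * w - v * s * s))
    if filter_name == "signal":
        if model.nX != model.nY:
            raise NotImplementedError(
                "signal-filter conditioning implemented for balanced designs only "
                "(M is independent of (D, Sp) when nX = nY)"
            )
        return lambda s: 0.0
    raise ValueError(f"no conditional law for filter {filter_name!r}")


def _abs_d_sf(model: ModelSpec, delta: float, a: float) -> float:
    """Pr{|D| >= a} for D ~ N(delta*sigma*c, (sigma*c)^2)."""
    if a <= 0:
        return 1.0
    sc = model.sigma * model.c
    mu = delta * sc
    return float(stats.norm.sf((a - mu) / sc) + stats.norm.cdf((-a - mu) / sc))


def _retained_prob(model: ModelSpec, filter_name: str, w: float, delta: float) -> float:
    """Pr{W >= w} under the given component (closed forms)."""
    if filter_name == "fold_change":
        return _abs_d_sf(model, delta, w)
    if filter_name == "variance":
        if w <= 0:
            return 1.0
        x = (model.n - 1) * w / model.sigma**2
        # (n-1) S^2 / sigma^2 = chi2_v + noncentral chi2_1(delta^2) = ncx2_{n-1}(delta^2)
        if delta == 0:
            return float(stats.chi2.sf(x, model.n - 1))
        return float(stats.ncx2.sf(x, model.n - 1, delta**2))
    if filter_name == "signal":
        # M ~ N(mu_M, (sigma c / 2)^2); under the simulation convention the
        # baseline is 0 and alternatives shift group A by +/-Delta
        sd = model.sigma * model.c / 2.0
        if delta == 0:
            return float(stats.norm.sf(w / sd))
        h = delta * model.sigma * model.c / 2.0
        return float(0.5 * stats.norm.sf((w - h) / sd) + 0.5 * stats.norm.sf((w + h) / sd))
    raise ValueError(f"unknown filter {filter_name!r}")


def filter_stat_cdf(model: ModelSpec, filter_name: str, w, delta: float) -> float:
    """Pr{W <= w} for one mixture component (delta=0: null)."""
    return 1.0 - _retained_prob(model, filter_name, w, delta)


def solve_filter_threshold(model: ModelSpec, filter_name: str, fraction_out: float) -> float:
    """Threshold w removing ``fraction_out`` of features under the mixture law
    pi0 * (null component) + (1 − pi0) * (alternative component) of W."""
    if not 0.0 <= fraction_out < 1.0:
        raise ValueError("fraction_out must be in [0, 1)")
    if fraction_out == 0.0:
        return -np.inf

    def mix_cdf(w):
        return (model.pi0 * filter_stat_cdf(model, filter_name, w, 0.0)
                + (1 - model.pi0) * filter_stat_cdf(model, filter_name, w, model.delta))

    lo, hi = 0.0, max(1.0, model.sigma**2, abs(model.mean_difference)) * 2
    while mix_cdf(hi) < fraction_out:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - defensive
            raise RuntimeError("threshold bracket failed")
    if filter_name == "signal":
        lo = -hi
        while mix_cdf(lo) > fraction_out:
            lo *= 2.0
    return float(optimize.brentq(lambda w: mix_cdf(w) - fraction_out, lo, hi,
                                 xtol=1e-12))


# -- conditional laws of T ----------------------------------------------------


def _cond_tail(model: ModelSpec, filter_name: str, w: float, delta: float,
               t_abs: float) -> float:
    """Pr{|T| >= t_abs | W >= w} for one component (t_abs >= 0)."""
    if filter_name == "signal" or w == -np.inf or (filter_name == "fold_change" and w <= 0):
        if delta == 0:
            return float(2 * stats.t.sf(t_abs, model.df))
        return float(stats.nct.sf(t_abs, model.df, delta)
                     + stats.nct.cdf(-t_abs, model.df, delta))
    d0 = _d0_fn(model, filter_name, w)
    sp = model.sp_dist()
    c = model.c

    def integrand(s):
        return sp.pdf(s) * _abs_d_sf(model, delta, max(d0(s), t_abs * c * s))

    num = integrate.quad(integrand, 0, np.inf, **_QUAD_OPTS)[0]
    denom = _retained_prob(model, filter_name, w, delta)
    if denom < _MIN_COND_PROB:
        raise ValueError("filter removes essentially every feature (Pr{W>=w} ~ 0)")
    return min(num / denom, 1.0)


def _cond_cdf_scalar(model: ModelSpec, filter_name: str, w: float, delta: float,
                     t: float) -> float:
    """F_T^W(t) = Pr{T <= t, W >= w} / Pr{W >= w} for one component."""
    if filter_name == "signal" or w == -np.inf or (filter_name == "fold_change" and w <= 0):
        if delta == 0:
            return float(stats.t.cdf(t, model.df))
        return float(stats.nct.cdf(t, model.df, delta))
    d0 = _d0_fn(model, filter_name, w)
    sp = model.sp_dist()
    sc = model.sigma * model.c
    mu = delta * sc
    c = model.c

    def gauss_cdf(a):
        return stats.norm.cdf((a - mu) / sc)

    def integrand(s):
        a = t * c * s
        b = d0(s)
        if b <= 0:
            mass = gauss_cdf(a)
        else:
            mass = gauss_cdf(min(a, -b)) + max(0.0, gauss_cdf(a) - gauss_cdf(b))
        return sp.pdf(s) * mass

    num = integrate.quad(integrand, 0, np.inf, **_QUAD_OPTS)[0]
    denom = _retained_prob(model, filter_name, w, delta)
    if denom < _MIN_COND_PROB:
        raise ValueError("filter removes essentially every feature (Pr{W>=w} ~ 0)")
    return float(min(num / denom, 1.0))


def _cond_pdf_scalar(model: ModelSpec, filter_name: str, w: float, delta: float,
                     t: float) -> float:
    """Conditional density of T at t for one component."""
    if filter_name == "signal" or w == -np.inf or (filter_name == "fold_change" and w <= 0):
        if delta == 0:
            return float(stats.t.pdf(t, model.df))
        return float(stats.nct.pdf(t, model.df, delta))
    c, v, n = model.c, model.df, model.n
    sp = model.sp_dist()
    sc = model.sigma * model.c
    mu = delta * sc
    if filter_name == "fold_change":
        if t == 0.0 and w > 0:
            return 0.0
        s_lo = w / (c * abs(t)) if t != 0 else np.inf
    else:  # variance
        s_lo = np.sqrt((n - 1) * w / (t * t + v)) if w > 0 else 0.0
    if not np.isfinite(s_lo):
        return 0.0

    def integrand(s):
        return sp.pdf(s) * c * s * stats.norm.pdf((t * c * s - mu) / sc) / sc

    num = integrate.quad(integrand, s_lo, np.inf, **_QUAD_OPTS)[0]
    denom = _retained_prob(model, filter_name, w, delta)
    if denom < _MIN_COND_PROB:
        raise ValueError("filter removes essentially every feature (Pr{W>=w} ~ 0)")
    return float(num / denom)


def conditional_t_cdf(model: ModelSpec, filter_name: str, w: float, t) -> DistributionCurve:
    """Conditional cdf of T given the filter retains the feature ({W >= w}).

    The component evaluated is the one selected by ``model.delta`` (set
    delta=0 for the null law).  For the signal filter in a balanced design
    the conditional law equals the unconditional one (independence).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    delta = model.delta
    cdf = np.array([_cond_cdf_scalar(model, filter_name, w, delta, ti) for ti in t])
    return DistributionCurve(grid=t, cdf=cdf,
                             conditioning={"filter": filter_name, "threshold": w,
                                           "delta": delta})


def pvalue_density_after_filter(
    model: ModelSpec,
    filter_name: str,
    fraction_out: float,
    p_grid,
    component: str = "null",
) -> DistributionCurve:
    """Density of the two-sided t p-value among retained features.

    The threshold w is solved from ``fraction_out`` under the null/alternative
    MIXTURE law of the filter statistic (as in the empirical pipeline, which
    cuts a pooled statistic vector); the returned density is that of the
    requested component (``"null"``: delta=0, ``"alternative"``: model.delta)
    conditional on retention.

    Derivation: with t_p = F0^{-1}(1 − p/2), the p-value density is
    f_P(p) = [f_T^W(t_p) + f_T^W(−t_p)] / (2·f0(t_p)).
    """
    p_grid = np.atleast_1d(np.asarray(p_grid, dtype=float))
    if np.any((p_grid <= 0) | (p_grid >= 1)):
        raise ValueError("p_grid must lie strictly inside (0, 1)")
    if component not in ("null", "alternative"):
        raise ValueError("component must be 'null' or 'alternative'")
    delta = 0.0 if component == "null" else model.delta
    w = solve_filter_threshold(model, filter_name, fraction_out)
    v = model.df
    t_p = stats.t.isf(p_grid / 2.0, v)
    dens = np.empty_like(p_grid)
    for i, (p, tp) in enumerate(zip(p_grid, t_p)):
        f_plus = _cond_pdf_scalar(model, filter_name, w, delta, tp)
        f_minus = _cond_pdf_scalar(model, filter_name, w, delta, -tp)
        dens[i] = (f_plus + f_minus) / (2.0 * stats.t.pdf(tp, v))
    return DistributionCurve(
        grid=p_grid, density=dens,
        conditioning={"filter": filter_name, "threshold": w,
                      "fraction_out": fraction_out, "component": component},
    )


def pvalue_cdf_after_filter(model: ModelSpec, filter_name: str, w: float,
                            delta: float, u: float) -> float:
    """Cdf of the p-value among retained features for one component:
    Pr{P <= u | retained} = Pr{|T| >= t_u | W >= w}."""
    if u <= 0:
        return 0.0
    if u >= 1:
        return 1.0
    t_u = stats.t.isf(u / 2.0, model.df)
    return _cond_tail(model, filter_name, w, delta, t_u)


def analytic_power_after_filter(
    model: ModelSpec, filter_name: str, fraction_out: float, phi: float
) -> tuple[float, float]:
    """Asymptotic BH operating point after filtering, by cdf intersection.

    With G0W, GaW the null/alternative p-value cdfs after filtering and
    pi0W the post-filter null proportion, the BH rejection threshold solves
    GaW(u) = [1/(1 − pi0W)]·[u/phi − pi0W·G0W(u)], i.e. GmW(u) = u/phi; the
    largest root u* in (0, 1] is found by grid bracketing and bisection, and
    the power is GaW(u*).  When no positive root exists, (0, 0) is returned —
    asymptotically BH rejects nothing.
    """
    if not 0.0 < phi < 1.0:
        raise ValueError("phi must be in (0, 1)")
    w = solve_filter_threshold(model, filter_name, fraction_out)
    pr0 = _retained_prob(model, filter_name, w, 0.0) if w != -np.inf else 1.0
    pra = _retained_prob(model, filter_name, w, model.delta) if w != -np.inf else 1.0
    pi0w = model.pi0 * pr0 / (model.pi0 * pr0 + (1 - model.pi0) * pra)

    def g0w(u):
        return pvalue_cdf_after_filter(model, filter_name, w, 0.0, u)

    def gaw(u):
        return pvalue_cdf_after_filter(model, filter_name, w, model.delta, u)

    def h(u):
        return pi0w * g0w(u) + (1 - pi0w) * gaw(u) - u / phi

    # scan from u=1 downward for the first bracket where GmW crosses u/phi
    grid = np.logspace(0, -8, 65)
    h_prev = h(grid[0])  # h(1) = 1 - 1/phi < 0
    for u_lo, u_hi in zip(grid[1:], grid[:-1]):
        h_lo = h(u_lo)
        if h_lo >= 0 and h_prev < 0:
            u_star = optimize.brentq(h, u_lo, u_hi, xtol=1e-10)
            return float(u_star), float(gaw(u_star))
        h_prev = h_lo
    return 0.0, 0.0


def pi0_reference_curves(pi0: float, x_grid) -> dict[str, np.ndarray]:
    """Retained null proportion pi0(x) for the two reference filters.

    best:   max(0, (pi0 − x)/(1 − x))  — removes only nulls until exhausted;
    random: pi0 (constant)             — removes regardless of truth.
    These bound every realistic filter from below and above.
    """
    if not 0.0 < pi0 < 1.0:
        raise ValueError("pi0 must be in (0, 1)")
    x = np.atleast_1d(np.asarray(x_grid, dtype=float))
    if np.any((x < 0) | (x >= 1)):
        raise ValueError("fractions filtered out must lie in [0, 1)")
    best = np.maximum(0.0, (pi0 - x) / (1.0 - x))
    return {"best": best, "random": np.full_like(x, pi0)}
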