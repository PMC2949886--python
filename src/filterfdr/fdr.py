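"""Multiple-testing procedures in the unified empirical-cdf step-up form.

Step-up FDR procedures can all be written as: reject every p-value no greater
than

    u* = max_u { g(u, phi) <= Gm(u) },

where Gm is the empirical cdf of the m p-values and g encodes the procedure:
g(u, phi) = u/phi for Benjamini-Hochberg (BH), g(u, phi) = pi0*u/phi for the
adaptive BH (aBH) with an estimate of the null proportion pi0, and BH run at
level phi/c(m) with the harmonic sum c(m) = sum_{j=1..m} 1/j for
Benjamini-Yekutieli (BY).  Evaluating the inequality at the order statistics
P_(i), where Gm(P_(i)) = i/m, recovers the classical "reject while
P_(i) <= i*phi/m" descriptions; both routes are implemented and asserted
equal in the test suite.

Storey's q-value procedure and the Bonferroni correction are included for the
comparisons the simulation engine runs.  The q-value estimator of pi0 needs
p-values spanning [0, 1], which is why it cannot be combined with the
fold-change filter (that filter empties the neighbourhood of p = 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "FdrResult",
    "EmpiricalCdf",
    "empirical_cdf",
    "stepup_generic",
    "bh",
    "by",
    "abh",
    "qvalue",
    "bonferroni",
    "estimate_pi0_lsl",
    "estimate_pi0_storey",
    "apply_fdr",
    "FDR_METHODS",
]

FDR_METHODS = ("bh", "by", "abh", "qvalue", "bonferroni")


@dataclass
class FdrResult:
    """Outcome of a multiple-testing procedure at nominal level phi."""

    method: str
    phi: float
    u_star: float
    rejected: np.ndarray
    pi0_hat: float | None = None
    qvalues: np.ndarray | None = None

    @property
    def n_rejected(self) -> int:
        return int(np.count_nonzero(self.rejected))


def _check_pvalues(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def _check_phi(phi: float) -> None:
    if not 0.0 < phi < 1.0:
        raise ValueError(f"nominal level phi must be in (0, 1), got {phi}")


class EmpiricalCdf:
    """Right-continuous empirical cdf Gm(u) = #{P_i <= u} / m on [0, 1]."""

    def __init__(self, pvalues):
        self._sorted = np.sort(_check_pvalues(pvalues))
        self._m = self._sorted.size

    def __call__(self, u):
        return np.searchsorted(self._sorted, u, side="right") / self._m

    @property
    def m(self) -> int:
        return self._m


def empirical_cdf(pvalues) -> EmpiricalCdf:
    return EmpiricalCdf(pvalues)


def stepup_generic(
    pvalues,
    g: Callable[[np.ndarray, float], np.ndarray],
    phi: float,
    method: str = "generic",
    pi0_hat: float | None = None,
) -> FdrResult:
    """Generic step-up procedure: reject all P_i <= u*, with
    u* = max{ P_(i) : g(P_(i), phi) <= Gm(P_(i)) = i/m }.

    ``g`` must be nondecreasing in its first argument.  With no qualifying
    order statistic, u* = 0 and nothing is rejected.
    """
    _check_phi(phi)
    p = _check_pvalues(pvalues)
    m = p.size
    p_sorted = np.sort(p)
    ok = np.asarray(g(p_sorted, phi)) <= np.arange(1, m + 1) / m
    if not ok.any():
        return FdrResult(method, phi, 0.0, np.zeros(m, dtype=bool), pi0_hat)
    u_star = float(p_sorted[np.flatnonzero(ok)[-1]])
    return FdrResult(method, phi, u_star, p <= u_star, pi0_hat)


def bh(pvalues, phi: float) -> FdrResult:
    """Benjamini-Hochberg step-up procedure: g(u, phi) = u/phi."""
    return stepup_generic(pvalues, lambda u, f: u / f, phi, method="bh")


def by(pvalues, phi: float) -> FdrResult:
    """Benjamini-Yekutieli procedure for arbitrary dependence.

    Implemented as BH at level phi / c(m), c(m) = sum_{j=1..m} 1/j, which is
    equivalent to the per-rank thresholds i*phi/(m*c(m)).
    """
    _check_phi(phi)
    p = _check_pvalues(pvalues)
    c_m = np.sum(1.0 / np.arange(1, p.size + 1))
    res = stepup_generic(p, lambda u, f: u * c_m / f, phi, method="by")
    return res


def estimate_pi0_lsl(pvalues) -> float:
    """Lowest-slope estimator of the null proportion pi0 (Benjamini et al. 2000).

    Computes slopes S_i = (1 − P_(i)) / (m + 1 − i) on the ascending order
    statistics and scans from i = 1 until the slopes first decrease
    (S_i < S_{i-1}); with slope S_j at the stop,
    m0_hat = min(m, 1/S_j + 1) and pi0_hat = m0_hat/m, clipped to (0, 1].
    If the slopes never decrease the last slope is used.
    """
    p = _check_pvalues(pvalues)
    m = p.size
    if m < 2:
        return 1.0
    p_sorted = np.sort(p)
    i = np.arange(1, m + 1)
    slopes = (1.0 - p_sorted) / (m + 1 - i)
    dec = np.flatnonzero(np.diff(slopes) < 0)
    s_j = slopes[dec[0] + 1] if dec.size else slopes[-1]
    if s_j <= 0:
        return 1.0
    m0 = min(m, 1.0 / s_j + 1.0)
    return float(min(1.0, max(m0 / m, 1.0 / m)))


def abh(pvalues, phi: float, pi0_estimator: Callable[[np.ndarray], float] = estimate_pi0_lsl) -> FdrResult:
    """Adaptive BH: g(u, phi) = pi0_hat * u / phi, i.e. BH at level phi/pi0_hat.

    The pi0 estimator defaults to the lowest-slope method and is pluggable
    (e.g. :func:`estimate_pi0_storey`).
    """
    _check_phi(phi)
    p = _check_pvalues(pvalues)
    pi0 = pi0_estimator(p)
    res = stepup_generic(p, lambda u, f: pi0 * u / f, phi, method="abh", pi0_hat=pi0)
    return res


def estimate_pi0_storey(pvalues, lam: float = 0.5) -> float:
    """Storey's pi0 estimate #{P_i > lambda} / (m (1 − lambda)), clipped to (0, 1]."""
    p = _check_pvalues(pvalues)
    if not 0.0 <= lam < 1.0:
        raise ValueError("lambda must be in [0, 1)")
    pi0 = np.count_nonzero(p > lam) / (p.size * (1.0 - lam))
    return float(min(1.0, max(pi0, 1.0 / p.size)))


def qvalue(pvalues, phi: float, lam: float = 0.5) -> FdrResult:
    """Storey's q-value procedure: reject features with q_i <= phi.

    q_i = min_{j: P_(j) >= P_(i)} pi0_hat * m * P_(j) / j with
    pi0_hat = #{P > lambda} / (m (1 − lambda)).  The estimator requires
    p-values reaching beyond lambda; if max(P) < lambda it is degenerate
    (pi0_hat = 0) and the procedure refuses — the reason the q-value method
    cannot be combined with the fold-change filter, which removes the
    features with p-values near 1.
    """
    _check_phi(phi)
    p = _check_pvalues(pvalues)
    if p.max() < lam:
        raise ValueError(
            f"q-value method needs p-values exceeding lambda={lam}: the p-value "
            "range after filtering no longer spans [0, 1] (this happens with "
            "filters associated with the test statistic, e.g. fold change)"
        )
    m = p.size
    pi0 = estimate_pi0_storey(p, lam)
    order = np.argsort(p, kind="stable")
    raw = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q = np.empty(m)
    q[order] = q_sorted
    rejected = q <= phi
    u_star = float(p[rejected].max()) if rejected.any() else 0.0
    return FdrResult("qvalue", phi, u_star, rejected, pi0_hat=pi0, qvalues=q)


def bonferroni(pvalues, phi: float) -> FdrResult:
    """Bonferroni FWER correction: reject P_i <= phi/m (comparison baseline)."""
    _check_phi(phi)
    p = _check_pvalues(pvalues)
    u_star = phi / p.size
    return FdrResult("bonferroni", phi, u_star, p <= u_star)


_PROCEDURES = {"bh": bh, "by": by, "abh": abh, "qvalue": qvalue, "bonferroni": bonferroni}


def apply_fdr(pvalues, method: str, phi: float, **kwargs) -> FdrResult:
    """Dispatch a named procedure from :data:`FDR_METHODS`."""
    try:
        proc = _PROCEDURES[method]
    except KeyError:
        raise ValueError(f"unknown FDR method {method!r}; choose from {FDR_METHODS}") from None
    return proc(pvalues, phi, **kwargs)
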