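"""Per-feature filter statistics and fraction-based filtering.

A filter scores every feature with a statistic W and *retains* the features
with the largest scores (W >= w): filtering removes the low-scoring fraction.
Three statistics used in practice are provided —

* ``signal``       WS = (X̄ + Ȳ)/2, the average signal over both groups;
* ``fold_change``  WFC = |X̄ − Ȳ|, the absolute (log) fold change;
* ``variance``     WV = S², the overall sample variance across all n samples
  (groups pooled, single grand mean, n−1 denominator);

plus two reference filters that only make sense in simulations, where the
null/alternative truth of each feature is known: the ``best`` filter removes
null features first (a lower bound on the retained null proportion) and the
``random`` filter removes features uniformly at random (an upper bound).

Experiments are parameterised by the *fraction removed* rather than by the
threshold w, so that different filters remove exactly the same number of
features; w is derived as the smallest retained statistic value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import ExpressionDataset

__all__ = [
    "FilterResult",
    "signal_statistic",
    "foldchange_statistic",
    "variance_statistic",
    "filter_statistic",
    "apply_filter",
    "oracle_best_filter",
    "random_filter",
    "FILTER_NAMES",
]

FILTER_NAMES = ("signal", "fold_change", "variance", "best", "random")


@dataclass
class FilterResult:
    """Outcome of filtering m features.

    Attributes
    ----------
    statistic_name : str
    values : ndarray or None
        Per-feature filter statistic W(Z_i) (None for the random filter,
        which scores nothing).
    threshold : float
        Derived cut w: the smallest statistic value among retained features
        (NaN when values is None).
    retained : ndarray of bool
        R_i = True when feature i survives the filter.
    gamma : float
        Retained fraction, count(retained)/m.
    """

    statistic_name: str
    values: np.ndarray | None
    threshold: float
    retained: np.ndarray

    @property
    def gamma(self) -> float:
        return float(np.count_nonzero(self.retained) / self.retained.size)

    @property
    def n_retained(self) -> int:
        return int(np.count_nonzero(self.retained))


def signal_statistic(dataset: ExpressionDataset) -> np.ndarray:
    """Average signal per feature: (X̄ + Ȳ)/2 (mean of the two group means)."""
    x, y = dataset.group_values()
    return (x.mean(axis=1) + y.mean(axis=1)) / 2.0


def foldchange_statistic(dataset: ExpressionDataset) -> np.ndarray:
    """Absolute (log) fold change per feature: |X̄ − Ȳ|."""
    x, y = dataset.group_values()
    return np.abs(x.mean(axis=1) - y.mean(axis=1))


def variance_statistic(dataset: ExpressionDataset) -> np.ndarray:
    """Overall sample variance per feature across all n samples (ddof=1)."""
    if dataset.n < 2:
        raise ValueError("variance statistic needs at least 2 samples")
    return dataset.values.var(axis=1, ddof=1)


_STATISTICS = {
    "signal": signal_statistic,
    "fold_change": foldchange_statistic,
    "variance": variance_statistic,
}


def filter_statistic(dataset: ExpressionDataset, name: str) -> np.ndarray:
    """Dispatch a named data-based filter statistic (signal/fold_change/variance)."""
    try:
        return _STATISTICS[name](dataset)
    except KeyError:
        raise ValueError(
            f"unknown filter statistic {name!r}; choose from {sorted(_STATISTICS)}"
        ) from None


def _check_fraction(fraction_out: float) -> None:
    if not 0.0 <= fraction_out < 1.0:
        raise ValueError(f"fraction_out must be in [0, 1), got {fraction_out}")


def _n_removed(m: int, fraction_out: float) -> int:
    # round-half-even would under-remove at .5 grid points; use plain rounding
    return int(np.floor(fraction_out * m + 0.5))


def apply_filter(
    values: np.ndarray, fraction_out: float, statistic_name: str = "custom"
) -> FilterResult:
    """Remove the ``round(fraction_out * m)`` features with smallest statistic.

    Ties at the cut are broken by original feature order: among equal values
    the earlier feature is retained first, so the retained count is exact.
    The threshold w is the smallest retained value.
    """
    _check_fraction(fraction_out)
    values = np.asarray(values, dtype=float)
    m = values.size
    k = _n_removed(m, fraction_out)
    # ascending by value; among ties, larger index first => removed first
    order = np.lexsort((-np.arange(m), values))
    retained = np.ones(m, dtype=bool)
    retained[order[:k]] = False
    # k can equal m only via rounding at tiny m (e.g. m=1, fraction 0.5)
    threshold = float(values[retained].min()) if retained.any() else float("inf")
    return FilterResult(statistic_name, values, threshold, retained)


def oracle_best_filter(truth_null: np.ndarray, fraction_out: float) -> FilterResult:
    """Oracle reference filter: removes null features first.

    ``truth_null`` flags the features for which the null hypothesis holds
    (V_i = 1); available only in simulation.  Null features are removed in
    index order until either the removal budget or the null set is exhausted;
    any remaining budget removes non-null features in index order.
    """
    _check_fraction(fraction_out)
    truth_null = np.asarray(truth_null, dtype=bool)
    m = truth_null.size
    k = _n_removed(m, fraction_out)
    retained = np.ones(m, dtype=bool)
    null_idx = np.flatnonzero(truth_null)
    alt_idx = np.flatnonzero(~truth_null)
    removal_order = np.concatenate([null_idx, alt_idx])
    retained[removal_order[:k]] = False
    # score: non-null above null, later removal later => encode removal rank
    score = np.empty(m)
    score[removal_order] = np.arange(m)
    return FilterResult("best", score, float(score[retained].min()) if k < m else np.nan,
                        retained)


def random_filter(m: int, fraction_out: float, seed) -> FilterResult:
    """Retain a uniformly random subset of round((1−fraction_out)·m) features."""
    _check_fraction(fraction_out)
    rng = np.random.default_rng(seed)
    k = _n_removed(m, fraction_out)
    retained = np.ones(m, dtype=bool)
    retained[rng.choice(m, size=k, replace=False)] = False
    return FilterResult("random", None, float("nan"), retained)
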