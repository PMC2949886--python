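"""Synthetic two-group data and the filter x fraction x FDR-method experiment.

The generator mimics a microarray experiment measuring m features on two
groups of independent samples.  Values are Gaussian with common s.d. sigma;
round(pi0*m) features are null (equal group means), the rest differ by
Delta = delta*sigma*sqrt(1/nX+1/nY) in group A, with the sign of the shift
drawn +/- with equal probability per feature.  delta is then exactly the
noncentrality of the pooled t statistic for alternative features.

The experiment engine runs, per simulated dataset: test -> filter the
p-value list (same fraction removed for every filter, for comparability) ->
FDR-correct at nominal level phi, and accumulates

* achieved FDR: fraction of true nulls among rejected features (0 when
  nothing is rejected);
* observed power: rejected alternatives / ALL alternatives in the original
  dataset — filtered-out features count as non-rejected, so the maximum
  achievable power after filtering can be below 1;
* retained null proportion pi0(x).

Means and Monte-Carlo standard errors per cell are returned as a DataFrame;
runs are bit-reproducible from the master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset
from .fdr import FDR_METHODS, FdrResult, apply_fdr
from .filters import (FILTER_NAMES, apply_filter, filter_statistic,
                      oracle_best_filter, random_filter)
from .testing import run_test

__all__ = [
    "SimulationConfig",
    "generate_dataset",
    "achieved_fdr",
    "observed_power",
    "pi0_retained",
    "run_grid",
    "post_fdr_filter",
]

logger = logging.getLogger(__name__)

DEFAULT_FRACTIONS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass
class SimulationConfig:
    """Factorial simulation configuration (defaults follow the standard
    two-group setup: m=1000 features, pi0=0.8, nX=nY=5 so v=8, delta=1,
    sigma=1, nominal FDR phi=0.05)."""

    m: int = 1000
    pi0: float = 0.8
    nX: int = 5
    nY: int = 5
    delta: float = 1.0
    sigma: float = 1.0
    n_datasets: int = 200
    phi: float = 0.05
    fractions: tuple = DEFAULT_FRACTIONS
    filters: tuple = ("signal", "fold_change", "variance")
    fdr_methods: tuple = ("bh",)
    test: str = "t"
    seed: int = 0

    def __post_init__(self):
        if self.m <= 0 or self.nX <= 0 or self.nY <= 0 or self.n_datasets <= 0:
            raise ValueError("m, nX, nY and n_datasets must be positive")
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValueError("pi0 must be in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 < self.phi < 1.0:
            raise ValueError("phi must be in (0, 1)")
        for f in self.fractions:
            if not 0.0 <= f < 1.0:
                raise ValueError(f"fraction filtered out must be in [0, 1), got {f}")
        for flt in self.filters:
            if flt not in FILTER_NAMES:
                raise ValueError(f"unknown filter {flt!r}")
        for meth in self.fdr_methods:
            if meth not in FDR_METHODS:
                raise ValueError(f"unknown FDR method {meth!r}")
        if self.test not in ("t", "wilcoxon"):
            raise ValueError("test must be 't' or 'wilcoxon'")
        if "qvalue" in self.fdr_methods and "fold_change" in self.filters:
            raise ValueError(
                "the q-value method cannot be combined with the fold-change "
                "filter: that filter truncates the p-value range away from 1, "
                "making the pi0 estimator degenerate"
            )

    def replace(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def generate_dataset(config: SimulationConfig, replicate_seed) -> tuple[ExpressionDataset, np.ndarray]:
    """One simulated dataset plus its truth vector (True = null feature)."""
    rng = np.random.default_rng(replicate_seed)
    m, n = config.m, config.nX + config.nY
    n_null = int(np.floor(config.pi0 * m + 0.5))
    truth_null = np.zeros(m, dtype=bool)
    truth_null[:n_null] = True
    values = rng.normal(0.0, config.sigma, size=(m, n))
    n_alt = m - n_null
    if n_alt and config.delta != 0.0:
        delta_mean = config.delta * config.sigma * np.sqrt(1 / config.nX + 1 / config.nY)
        signs = rng.choice([-1.0, 1.0], size=n_alt)
        values[n_null:, : config.nX] += (signs * delta_mean)[:, None]
    group = np.array(["A"] * config.nX + ["B"] * config.nY)
    ds = ExpressionDataset(
        values=values,
        feature_ids=[f"f{i:05d}" for i in range(m)],
        sample_ids=[f"s{j:02d}" for j in range(n)],
        group=group,
    )
    return ds, truth_null


def achieved_fdr(rejected, truth_null) -> float:
    """Fraction of true nulls among rejected features; 0 with no rejections."""
    rejected = np.asarray(rejected, dtype=bool)
    truth_null = np.asarray(truth_null, dtype=bool)
    if rejected.shape != truth_null.shape:
        raise ValueError("rejected and truth vectors must have equal length")
    n_rej = np.count_nonzero(rejected)
    if n_rej == 0:
        return 0.0
    return float(np.count_nonzero(rejected & truth_null) / n_rej)


def observed_power(rejected, truth_null) -> float:
    """Rejected alternatives over ALL alternatives of the original dataset."""
    rejected = np.asarray(rejected, dtype=bool)
    truth_null = np.asarray(truth_null, dtype=bool)
    if rejected.shape != truth_null.shape:
        raise ValueError("rejected and truth vectors must have equal length")
    n_alt = np.count_nonzero(~truth_null)
    if n_alt == 0:
        return 0.0
    return float(np.count_nonzero(rejected & ~truth_null) / n_alt)


def pi0_retained(retained, truth_null) -> float:
    """Null proportion among retained features."""
    retained = np.asarray(retained, dtype=bool)
    truth_null = np.asarray(truth_null, dtype=bool)
    if retained.shape != truth_null.shape:
        raise ValueError("retained and truth vectors must have equal length")
    n_ret = np.count_nonzero(retained)
    if n_ret == 0:
        raise ValueError("no features retained: pi0 undefined")
    return float(np.count_nonzero(retained & truth_null) / n_ret)


def _retained_mask(filter_name: str, dataset, truth_null, fraction_out, rng) -> np.ndarray:
    if filter_name == "best":
        return oracle_best_filter(truth_null, fraction_out).retained
    if filter_name == "random":
        return random_filter(dataset.m, fraction_out, rng).retained
    return apply_filter(filter_statistic(dataset, filter_name), fraction_out,
                        statistic_name=filter_name).retained


def run_grid(config: SimulationConfig) -> pd.DataFrame:
    """Run the full filter x fraction x FDR-method factorial experiment.

    Returns one row per cell with mean and Monte-Carlo s.e. of achieved FDR,
    observed power and retained null proportion across ``n_datasets``
    replicates.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_datasets)
    cells: dict[tuple, dict[str, list]] = {
        (flt, frac, meth): {"fdr": [], "power": [], "pi0": []}
        for flt in config.filters
        for frac in config.fractions
        for meth in config.fdr_methods
    }
    for r, child in enumerate(children):
        gen_seed, filt_seed = child.spawn(2)
        dataset, truth_null = generate_dataset(config, gen_seed)
        pvals = run_test(dataset, config.test).pvalue
        filt_rng = np.random.default_rng(filt_seed)
        for flt in config.filters:
            for frac in config.fractions:
                retained = _retained_mask(flt, dataset, truth_null, frac, filt_rng)
                p_ret = pvals[retained]
                p0 = pi0_retained(retained, truth_null)
                for meth in config.fdr_methods:
                    res = apply_fdr(p_ret, meth, config.phi)
                    rejected = np.zeros(config.m, dtype=bool)
                    rejected[np.flatnonzero(retained)[res.rejected]] = True
                    cell = cells[(flt, frac, meth)]
                    cell["fdr"].append(achieved_fdr(rejected, truth_null))
                    cell["power"].append(observed_power(rejected, truth_null))
                    cell["pi0"].append(p0)
        if (r + 1) % 50 == 0 or r + 1 == config.n_datasets:
            logger.info("simulation replicate %d/%d done", r + 1, config.n_datasets)

    rows = []
    for (flt, frac, meth), acc in cells.items():
        row = {"filter": flt, "fraction_out": frac, "fdr_method": meth,
               "n_datasets": config.n_datasets}
        for key, col in (("fdr", "achieved_fdr"), ("power", "power"),
                         ("pi0", "pi0_retained")):
            arr = np.asarray(acc[key])
            row[f"{col}_mean"] = arr.mean()
            row[f"{col}_se"] = arr.std(ddof=1) / np.sqrt(arr.size) if arr.size > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def post_fdr_filter(
    fdr_result: FdrResult, filter_values, fraction_out: float, truth_null
) -> tuple[float, float]:
    """Metrics after prioritising an FDR-significant list by a filter.

    From the features rejected by ``fdr_result``, remove the ``fraction_out``
    with the smallest filter statistic (e.g. fold change) — the common
    practice of shortening a discovery list for validation.  Returns the
    false-positive fraction WITHIN the shortened list and the corresponding
    observed power.  Filtering a posteriori does not bias the multiple
    testing correction itself, but the shortened list need no longer carry
    the nominal proportion phi of false positives.
    """
    filter_values = np.asarray(filter_values, dtype=float)
    truth_null = np.asarray(truth_null, dtype=bool)
    rejected = np.asarray(fdr_result.rejected, dtype=bool)
    if not (filter_values.shape == truth_null.shape == rejected.shape):
        raise ValueError("inputs must share the per-feature length")
    idx = np.flatnonzero(rejected)
    if idx.size == 0:
        return 0.0, 0.0
    keep_within = apply_filter(filter_values[idx], fraction_out).retained
    short = np.zeros_like(rejected)
    short[idx[keep_within]] = True
    return achieved_fdr(short, truth_null), observed_power(short, truth_null)
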