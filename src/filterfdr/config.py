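"""Run-configuration loading and validation (YAML, hence also JSON).

A configuration file has up to four sections — ``simulation``, ``filter``,
``fdr`` and ``bias_test`` — each optional; absent keys take the documented
defaults and unknown keys are rejected outright (misspelled options must not
silently fall back to defaults).  ``dump_config``/``load_config`` round-trip.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

import yaml

from .fdr import FDR_METHODS
from .filters import FILTER_NAMES
from .simulate import SimulationConfig

__all__ = ["RunConfig", "FilterConfig", "FdrConfig", "BiasTestConfig",
           "load_config", "dump_config"]


@dataclass
class FilterConfig:
    statistic: str = "variance"
    fraction_out: float = 0.0

    def __post_init__(self):
        if self.statistic not in FILTER_NAMES:
            raise ValueError(f"unknown filter statistic {self.statistic!r}")
        if not 0.0 <= self.fraction_out < 1.0:
            raise ValueError(f"fraction_out must be in [0, 1), got {self.fraction_out}")


@dataclass
class FdrConfig:
    method: str = "bh"
    phi: float = 0.05
    qvalue_lambda: float = 0.5

    def __post_init__(self):
        if self.method not in FDR_METHODS:
            raise ValueError(f"unknown FDR method {self.method!r}")
        if not 0.0 < self.phi < 1.0:
            raise ValueError(f"phi must be in (0, 1), got {self.phi}")
        if not 0.0 <= self.qvalue_lambda < 1.0:
            raise ValueError("qvalue_lambda must be in [0, 1)")


@dataclass
class BiasTestConfig:
    filter: str = "fold_change"
    fraction_out: float = 0.3
    test: str = "t"
    n_permutations: int = 100
    per_round: str = "ks"
    seed: int = 0

    def __post_init__(self):
        if self.filter not in FILTER_NAMES:
            raise ValueError(f"unknown filter {self.filter!r}")
        if not 0.0 <= self.fraction_out < 1.0:
            raise ValueError(f"fraction_out must be in [0, 1), got {self.fraction_out}")
        if self.n_permutations < 20:
            raise ValueError("n_permutations must be >= 20")
        if self.per_round not in ("ks", "bh"):
            raise ValueError("per_round must be 'ks' or 'bh'")


@dataclass
class RunConfig:
    simulation: SimulationConfig
    filter: FilterConfig
    fdr: FdrConfig
    bias_test: BiasTestConfig


_SECTIONS = {
    "simulation": SimulationConfig,
    "filter": FilterConfig,
    "fdr": FdrConfig,
    "bias_test": BiasTestConfig,
}


def _build(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) in [{section}]: {sorted(unknown)}")
    # YAML lists -> tuples so configs compare equal after a round trip
    kwargs = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
    return cls(**kwargs)


def load_config(path: str | os.PathLike | None = None, data: dict | None = None) -> RunConfig:
    """Load and validate a configuration tree; defaults fill absent keys."""
    if data is None:
        if path is None:
            data = {}
        else:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("configuration root must be a mapping")
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown configuration section(s): {sorted(unknown)}")
    return RunConfig(**{
        name: _build(cls, data.get(name, {}) or {}, name)
        for name, cls in _SECTIONS.items()
    })


def dump_config(config: RunConfig, path: str | os.PathLike) -> None:
    """Write a configuration back to YAML (inverse of :func:`load_config`)."""
    tree = {
        name: {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in dataclasses.asdict(getattr(config, name)).items()}
        for name in _SECTIONS
    }
    with open(path, "w") as fh:
        yaml.safe_dump(tree, fh, sort_keys=False)
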