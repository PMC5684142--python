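"""Experiment configuration, seeding, fixtures and tabular output.

Configuration files are TOML. Every experiment derives all randomness from
one master seed through per-pool substreams keyed by (seed, stream label,
pool index), so serial and parallel execution produce identical results and
a run is reproducible byte-for-byte from its config echo.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import SpeciesPool
from .pools import PoolStructureConfig, traits_from_axis

__all__ = [
    "ExperimentConfig",
    "load_config",
    "substream",
    "make_fixture_pool",
    "write_results",
    "write_provenance",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20171113

EXPERIMENTS = ("tradeoffs", "gradient", "pool_sweep", "bef")

_LABEL_CODES = {"": 0, "pool": 1, "bef": 2, "tradeoffs": 3, "gradient": 4}


@dataclass
class ExperimentConfig:
    """Validated settings of one experiment run."""

    experiment: str = "gradient"
    n_pools: int = 20
    seed: int = DEFAULT_SEED
    tol: float = 1e-8
    t_max: float = 5000.0
    eps: float = 1e-6
    pool: PoolStructureConfig = field(default_factory=PoolStructureConfig)
    sizes: tuple[int, ...] = (1, 5, 10, 20, 50, 100, 150)
    reps: int = 10
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}; "
                             f"expected one of {EXPERIMENTS}")
        if self.n_pools < 1:
            raise ValueError("n_pools must be >= 1")
        if not (isinstance(self.seed, int) and self.seed >= 0):
            raise ValueError("seed must be a non-negative integer")
        if self.tol <= 0 or self.t_max <= 0 or self.eps <= 0:
            raise ValueError("tol, t_max and eps must be positive")


def load_config(path: str | Path) -> ExperimentConfig:
    """Read a TOML experiment config; missing keys fall back to defaults.

    The ``[pool]`` table maps onto :class:`PoolStructureConfig` (defaults:
    the reference 125-species triple-trade-off configuration). Unknown keys
    raise, listing the offenders.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    pool_raw = raw.pop("pool", {})
    known = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(raw) - known
    pool_known = {f.name for f in dataclasses.fields(PoolStructureConfig)}
    pool_unknown = set(pool_raw) - pool_known
    if unknown or pool_unknown:
        bad = sorted(unknown) + [f"pool.{k}" for k in sorted(pool_unknown)]
        raise ValueError(f"unknown config keys: {bad}")
    if "sizes" in raw:
        raw["sizes"] = tuple(int(k) for k in raw["sizes"])
    return ExperimentConfig(pool=PoolStructureConfig(**pool_raw), **raw)


def substream(seed: int, index: int, label: str = "pool") -> np.random.Generator:
    """Independent generator for pool ``index`` under the master ``seed``."""
    code = _LABEL_CODES.get(label)
    if code is None:
        raise ValueError(f"unknown stream label {label!r}")
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(code, index)))


def make_fixture_pool() -> SpeciesPool:
    """Deterministic 8-species triple-trade-off pool for tests and demos.

    Axis positions are evenly spaced over [0, 1]; trait ranges are the
    reference configuration (f over [1.0, 2.2], l over [1.2, 2.9], b=0.5),
    so R* spans [0.5, 1.1].
    """
    cfg = PoolStructureConfig(N=8)
    axis = np.linspace(0.0, 1.0, 8)
    return traits_from_axis(axis, cfg)


def write_results(records, path: str | Path) -> Path:
    """Write a list of record dicts or a DataFrame as CSV.

    Stable column order (first-record order for dicts), full float
    precision, UTF-8, one header row. Returns the path written.
    """
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        df = pd.DataFrame(records)
        if records:
            df = df[list(records[0].keys())]
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")
    return path


def write_provenance(config: ExperimentConfig, path: str | Path) -> Path:
    """Echo the config, seed and package version next to the results."""
    from . import __version__

    payload = dataclasses.asdict(config)
    payload["package_version"] = __version__
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n",
                    encoding="utf-8")
    return path
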