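"""Species-pool generation under functional trade-offs.

Each species occupies a position ``x`` in [0, 1] on a one-dimensional
trade-off axis mirroring Grime's Competition-Stress strategy axis. Traits
constrained by the active trade-off are deterministic monotone maps of
``x``; unconstrained traits are drawn independently. The five structures:

``none``
    no constraint — f, m, l drawn independently and uniformly.
``m_f``
    mortality-resource acquisition: fast-growing (high f), stress-sensitive
    (high m, high R*) species at x=1 vs slow-growing stress-tolerant
    species at x=0.
``m_l``
    mortality-biomass tolerance: stress-sensitive but biomass-tolerant
    (low l) at x=1 vs stress-tolerant, biomass-intolerant at x=0.
``f_l``
    resource acquisition-biomass tolerance: fast-growing and
    biomass-tolerant at x=1.
``m_f_l``
    the triple trade-off — a single functional axis on which all three
    traits covary (corr(f, m) = +1, corr(f, l) = -1).

Mortality is tied to uptake through the R*-slope parameter ``b`` via
``m = b f**2``, so that R* = m/f = b f rises linearly along the axis: fast
growers demand richer soils. When mortality is not on the active axis it is
drawn uniformly from the same range shrunk about its midpoint by the factor
``B``.

Trait ranges are parametrized by a mean and a range width rw, i.e.
``[mean - rw/2, mean + rw/2]``. The axis positions themselves follow one of
four distributions: uniform, or triangular with mode at the minimum
("decreasing"), centre ("bell") or maximum ("increasing") of the range.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model import SpeciesPool

__all__ = [
    "PoolStructureConfig",
    "sample_axis",
    "traits_from_axis",
    "build_pool",
    "sample_pool_config",
    "SHAPES",
    "TRADEOFFS",
    "SWEEP_RANGES",
]

SHAPES = ("uniform", "decreasing", "bell", "increasing")
TRADEOFFS = ("none", "m_f", "m_l", "f_l", "m_f_l")

#: which traits ride the common axis under each trade-off structure
_AXIS_TRAITS = {
    "none": frozenset(),
    "m_f": frozenset({"f", "m"}),
    "m_l": frozenset({"m", "l"}),
    "f_l": frozenset({"f", "l"}),
    "m_f_l": frozenset({"f", "m", "l"}),
}

#: sweep ranges for the pool-structure experiment (uniform draws)
SWEEP_RANGES = {
    "N": (25, 200),
    "f_mean": (1.2, 2.0),
    "f_rw": (0.4, 2.0),
    "l_mean": (1.4, 2.7),
    "l_rw": (0.4, 3.0),
}

_TRIANGULAR_MODE = {"decreasing": 0.0, "bell": 0.5, "increasing": 1.0}


@dataclass(frozen=True)
class PoolStructureConfig:
    """Structure of a species pool: size, axis distribution, trait ranges.

    Defaults are the reference configuration of the trade-off comparison
    (N=125 species, uniform axis, f over 1.0-2.2, l over 1.2-2.9, c=0.6,
    b=0.5, B=0.5, triple trade-off).
    """

    N: int = 125
    shape: str = "uniform"
    f_mean: float = 1.6
    f_rw: float = 1.2
    l_mean: float = 2.05
    l_rw: float = 1.7
    c: float = 0.6
    tradeoff: str = "m_f_l"
    b: float = 0.5
    B: float = 0.5

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("pool size N must be >= 1")
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; expected one of {SHAPES}")
        if self.tradeoff not in TRADEOFFS:
            raise ValueError(
                f"unknown tradeoff {self.tradeoff!r}; expected one of {TRADEOFFS}")
        if self.f_mean - self.f_rw / 2 <= 0:
            raise ValueError("f range lower bound must be positive")
        if self.l_mean - self.l_rw / 2 <= 0:
            raise ValueError("l range lower bound must be positive")
        if self.c <= 0 or self.b <= 0 or self.B <= 0:
            raise ValueError("c, b and B must be positive")

    @property
    def f_range(self) -> tuple[float, float]:
        return (self.f_mean - self.f_rw / 2, self.f_mean + self.f_rw / 2)

    @property
    def l_range(self) -> tuple[float, float]:
        return (self.l_mean - self.l_rw / 2, self.l_mean + self.l_rw / 2)

    @property
    def m_range(self) -> tuple[float, float]:
        """Mortality range implied by m = b f**2 over the f range."""
        f_lo, f_hi = self.f_range
        return (self.b * f_lo ** 2, self.b * f_hi ** 2)


def sample_axis(N: int, shape: str, rng: np.random.Generator) -> np.ndarray:
    """Draw ``N`` axis positions in [0, 1] with the given distribution shape."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if shape == "uniform":
        return rng.uniform(0.0, 1.0, N)
    try:
        mode = _TRIANGULAR_MODE[shape]
    except KeyError:
        raise ValueError(
            f"unknown shape {shape!r}; expected one of {SHAPES}") from None
    return rng.triangular(0.0, mode, 1.0, N)


def traits_from_axis(axis: np.ndarray, config: PoolStructureConfig,
                     rng: np.random.Generator | None = None) -> SpeciesPool:
    """Map axis positions to a trait pool under ``config.tradeoff``.

    Traits on the active axis are linear in the position x: f rises from
    f_lo to f_hi, l falls from l_hi to l_lo, and m follows ``b f**2`` when
    both m and f are on the axis (so R* = b f rises with x), or rises
    linearly over the implied mortality range when m alone is constrained.
    Off-axis traits are drawn uniformly over their ranges (mortality from
    the B-shrunk range); a ``rng`` is then required.
    """
    axis = np.asarray(axis, dtype=float)
    if axis.size and (axis.min() < 0 or axis.max() > 1):
        raise ValueError("axis positions must lie in [0, 1]")
    N = axis.size
    on_axis = _AXIS_TRAITS[config.tradeoff]
    if len(on_axis) < 3 and rng is None:
        raise ValueError(
            f"tradeoff {config.tradeoff!r} leaves traits unconstrained; "
            "a random generator is required")

    f_lo, f_hi = config.f_range
    l_lo, l_hi = config.l_range
    m_lo, m_hi = config.m_range

    f = f_lo + axis * (f_hi - f_lo) if "f" in on_axis else rng.uniform(f_lo, f_hi, N)
    l = l_hi - axis * (l_hi - l_lo) if "l" in on_axis else rng.uniform(l_lo, l_hi, N)

    if "m" in on_axis and "f" in on_axis:
        m = config.b * f ** 2
    elif "m" in on_axis:
        m = m_lo + axis * (m_hi - m_lo)
    else:
        mid, half = (m_lo + m_hi) / 2, (m_hi - m_lo) / 2
        m = rng.uniform(mid - config.B * half, mid + config.B * half, N)

    pool_axis = axis if config.tradeoff != "none" else np.empty(0)
    return SpeciesPool(f=f, m=m, l=l, c=config.c,
                       tradeoff=config.tradeoff, axis=pool_axis)


def build_pool(config: PoolStructureConfig,
               rng: np.random.Generator) -> SpeciesPool:
    """Sample a species pool: axis positions, then traits."""
    axis = sample_axis(config.N, config.shape, rng)
    return traits_from_axis(axis, config, rng)


def sample_pool_config(rng: np.random.Generator,
                       tradeoff: str = "m_f_l") -> PoolStructureConfig:
    """Draw a pool structure for the sweep experiment.

    Pool size, axis-distribution shape, and the means and range widths of f
    and l are drawn uniformly over :data:`SWEEP_RANGES`; c, b and B stay at
    their reference values. The (l_mean, l_rw) pair is redrawn jointly when
    the implied lower bound of l would be non-positive, so every returned
    config has strictly positive trait ranges.
    """
    n_lo, n_hi = SWEEP_RANGES["N"]
    while True:
        l_mean = rng.uniform(*SWEEP_RANGES["l_mean"])
        l_rw = rng.uniform(*SWEEP_RANGES["l_rw"])
        if l_mean - l_rw / 2 > 0:
            break
    return PoolStructureConfig(
        N=int(rng.integers(n_lo, n_hi + 1)),
        shape=SHAPES[rng.integers(0, len(SHAPES))],
        f_mean=rng.uniform(*SWEEP_RANGES["f_mean"]),
        f_rw=rng.uniform(*SWEEP_RANGES["f_rw"]),
        l_mean=l_mean,
        l_rw=l_rw,
        tradeoff=tradeoff,
    )
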