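"""Community diversity statistics.

Diversity is measured with the log inverse Simpson index
``ln(1 / sum p_i^2)`` (natural log), whose exponential is the order-2 Hill
number — the "effective number" of equally-abundant species. Beta-diversity
across a set of communities is the multiplicative (Jost) partition
``gamma / alpha`` computed on Hill numbers, i.e. the effective number of
distinct communities: 1 when all communities are identical, M for M fully
disjoint, equally-even communities.
"""

from __future__ import annotations

import numpy as np

from .model import EXTINCTION_EPS

__all__ = ["total_biomass", "log_inv_simpson", "hill_q2", "beta_diversity",
           "relative_abundance", "richness"]


def total_biomass(P: np.ndarray) -> float:
    """Community productivity proxy: the summed biomass of all species."""
    P = np.asarray(P, dtype=float)
    if P.size and P.min() < 0:
        raise ValueError("biomasses must be non-negative")
    return float(P.sum())


def richness(P: np.ndarray, eps: float = EXTINCTION_EPS) -> int:
    """Number of species at or above the extinction threshold."""
    return int(np.count_nonzero(np.asarray(P, dtype=float) >= eps))


def relative_abundance(P: np.ndarray,
                       eps: float = EXTINCTION_EPS) -> np.ndarray:
    """Normalize biomasses (entries below ``eps`` zeroed) to proportions."""
    P = np.asarray(P, dtype=float)
    P = np.where(P < eps, 0.0, P)
    tot = P.sum()
    if tot <= 0:
        raise ValueError("empty community: no species at or above eps")
    return P / tot


def hill_q2(p: np.ndarray) -> float:
    """Order-2 Hill number 1 / sum p^2 of a relative-abundance profile."""
    p = np.asarray(p, dtype=float)
    if p.size == 0 or p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("p must be a non-negative vector summing to 1")
    return float(1.0 / np.sum(p ** 2))


def log_inv_simpson(P: np.ndarray, eps: float = EXTINCTION_EPS) -> float:
    """ln(1 / sum p^2) of the community, after pruning below ``eps``.

    Zero for a monoculture, ln(n) for n equally-abundant species.
    """
    return float(np.log(hill_q2(relative_abundance(P, eps))))


def beta_diversity(profiles: np.ndarray) -> float:
    """Multiplicative beta-diversity of a set of abundance profiles.

    ``profiles`` is an (M, N) array of relative-abundance vectors over one
    shared species list. Gamma is the Hill number of the unweighted mean
    profile; alpha the mean of the per-community Hill numbers; beta their
    ratio gamma / alpha, in [1, M].
    """
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    if profiles.shape[0] < 1:
        raise ValueError("at least one community profile required")
    sums = profiles.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-9) or profiles.min() < 0:
        raise ValueError("every profile must be non-negative and sum to 1")
    gamma = hill_q2(profiles.mean(axis=0))
    alpha = float(np.mean([hill_q2(p) for p in profiles]))
    return gamma / alpha
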