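"""BEF-style subsampling: sown richness vs productivity at fixed resources.

Biodiversity-ecosystem functioning experiments manipulate the number of
sown species at a constant environment and measure yield. Replicating that
design, random subsets of a species pool are assembled to equilibrium at
each of four fixed resource levels, and the Spearman rank correlation
between realized diversity (log inverse Simpson) and total biomass is
computed per pool x level. Over-yielding (intraspecific crowding c exceeds
the interspecific component) makes these correlations positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .diversity import log_inv_simpson, richness, total_biomass
from .model import (
    EXTINCTION_EPS,
    ResourceEnvironment,
    SpeciesPool,
    prune_extinct,
    simulate_to_equilibrium,
)

__all__ = [
    "BEF_LEVELS",
    "BEF_SIZES",
    "BEF_REPS",
    "BefResult",
    "subsample_species",
    "run_bef",
    "summarize_bef",
    "bef_experiment",
]

logger = logging.getLogger(__name__)

#: the four fixed (a, S) resource levels of the sown-richness manipulation
BEF_LEVELS = (
    ResourceEnvironment(a=0.05, S=0.1),
    ResourceEnvironment(a=0.85, S=1.1),
    ResourceEnvironment(a=1.65, S=2.1),
    ResourceEnvironment(a=2.45, S=3.1),
)
#: sown pool sizes (those exceeding the pool size are skipped)
BEF_SIZES = (1, 5, 10, 20, 50, 100, 150)
#: replicates per (level, size)
BEF_REPS = 10


@dataclass
class BefResult:
    """Per pool: replicate-level records and per-level correlations.

    ``records`` has one row per (level, size, replicate) with the realized
    diversity and biomass (empty replicates carry NaN diversity and are
    excluded from the correlations). ``correlations`` has one row per
    resource level with the Spearman rho of diversity vs biomass over its
    defined replicates (NaN where fewer than two defined points or constant
    diversity), plus the count of excluded replicates.
    """

    records: pd.DataFrame
    correlations: pd.DataFrame


def subsample_species(pool: SpeciesPool, k: int,
                      rng: np.random.Generator) -> SpeciesPool:
    """Uniform sample of ``k`` species without replacement."""
    if not 1 <= k <= pool.size:
        raise ValueError(f"subset size {k} outside [1, {pool.size}]")
    idx = rng.choice(pool.size, size=k, replace=False)
    return pool.subset(np.sort(idx))


def run_bef(pool: SpeciesPool,
            levels: tuple[ResourceEnvironment, ...] = BEF_LEVELS,
            sizes: tuple[int, ...] = BEF_SIZES,
            reps: int = BEF_REPS,
            rng: np.random.Generator | None = None,
            eps: float = EXTINCTION_EPS,
            **sim_kwargs) -> BefResult:
    """Assemble random subsets of ``pool`` at each resource level.

    Sizes above the pool size are skipped (with a log notice). Replicates
    in which no species survives are recorded with NaN diversity and
    excluded from the correlations; a single survivor has diversity 0.
    Spearman correlations use average-rank tie handling.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    usable = [k for k in sizes if k <= pool.size]
    for k in sizes:
        if k > pool.size:
            logger.info("skipping sown size %d > pool size %d", k, pool.size)
    rows = []
    for li, env in enumerate(levels):
        for k in usable:
            for rep in range(reps):
                sub = subsample_species(pool, k, rng)
                result = simulate_to_equilibrium(sub, env, **sim_kwargs)
                state = prune_extinct(result.state, eps)
                n = richness(state.P, eps)
                rows.append({
                    "level": li, "a": env.a, "S": env.S, "size": k,
                    "rep": rep, "realized_richness": n,
                    "diversity": log_inv_simpson(state.P, eps) if n else np.nan,
                    "biomass": total_biomass(state.P),
                    "converged": result.converged,
                })
    records = pd.DataFrame(rows)
    corr_rows = []
    for li, env in enumerate(levels):
        sub = records[(records["level"] == li)
                      & records["diversity"].notna()]
        n_skipped = int((records["level"] == li).sum() - len(sub))
        rho = np.nan
        if len(sub) >= 2 and sub["diversity"].nunique() > 1:
            rho = float(spearmanr(sub["diversity"], sub["biomass"]).statistic)
        else:
            logger.info("level %d: correlation undefined "
                        "(constant diversity or too few points)", li)
        corr_rows.append({"level": li, "a": env.a, "S": env.S,
                          "spearman": rho, "n_points": len(sub),
                          "n_skipped": n_skipped})
    return BefResult(records=records, correlations=pd.DataFrame(corr_rows))


def summarize_bef(results: list[BefResult]) -> tuple[float, float, float]:
    """(mean, min, max) Spearman over all defined pool x level correlations."""
    rhos = np.concatenate([
        r.correlations["spearman"].dropna().to_numpy() for r in results])
    if rhos.size == 0:
        raise ValueError("no defined correlations to summarize")
    return float(rhos.mean()), float(rhos.min()), float(rhos.max())


def bef_experiment(pools: list[SpeciesPool], seed: int,
                   levels: tuple[ResourceEnvironment, ...] = BEF_LEVELS,
                   sizes: tuple[int, ...] = BEF_SIZES,
                   reps: int = BEF_REPS) -> tuple[list[BefResult], pd.DataFrame]:
    """Run the subsampling design over many pools with per-pool substreams.

    Returns the per-pool results and a tidy table of all pool x level
    correlations.
    """
    from .config import substream

    results = []
    rows = []
    for i, pool in enumerate(pools):
        res = run_bef(pool, levels=levels, sizes=sizes, reps=reps,
                      rng=substream(seed, i, "bef"))
        results.append(res)
        corr = res.correlations.copy()
        corr.insert(0, "pool", i)
        rows.append(corr)
    return results, pd.concat(rows, ignore_index=True)
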