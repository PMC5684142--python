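"""Community assembly along a soil-resource gradient.

Each species pool is assembled to equilibrium under a factorial grid of
resource conditions (renewal rate ``a`` x capacity ``S``). The resulting
diversity-biomass scatter is smoothed with a penalized cubic spline
(GCV-selected smoothness) and summarized by four statistics: the mean and
coefficient of variation of diversity along the modelled curve, the
multiplicative beta-diversity of the equilibrium communities, and the
relative position of the curve's maximum on the biomass axis (interior
values indicate a hump-shaped productivity-diversity relationship).

Two experiment drivers build on this: :func:`tradeoff_comparison` contrasts
community turnover across the five trade-off structures at a fixed pool
configuration, and :func:`pool_structure_sweep` draws many pool structures
at random and regresses the curve statistics on the structure parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .diversity import beta_diversity, log_inv_simpson, relative_abundance, richness
from .model import (
    EXTINCTION_EPS,
    ResourceEnvironment,
    SpeciesPool,
    prune_extinct,
    simulate_to_equilibrium,
)
from .pools import PoolStructureConfig, build_pool, sample_pool_config

__all__ = [
    "GradientResult",
    "CurveSummary",
    "RegressionTable",
    "resource_gradient",
    "run_gradient",
    "fit_curve",
    "curve_statistics",
    "summarize_gradient",
    "pool_regression",
    "tradeoff_comparison",
    "pool_structure_sweep",
]

#: renewal rates and capacities of the 42-condition factorial gradient
GRADIENT_A = (0.05, 0.45, 0.85, 1.25, 1.65, 2.05, 2.45)
GRADIENT_S = (0.1, 0.7, 1.3, 1.9, 2.5, 3.1)

#: number of evaluation points for curve statistics
CURVE_GRID = 200


def resource_gradient() -> list[ResourceEnvironment]:
    """The factorial a x S grid of 42 soil resource conditions."""
    return [ResourceEnvironment(a=a, S=S) for a in GRADIENT_A for S in GRADIENT_S]


@dataclass
class GradientResult:
    """Assembly outcomes of one pool across a resource gradient.

    ``records`` holds one row per condition (a, S, biomass, diversity,
    richness, converged); diversity is NaN where no species survived.
    ``profiles`` is the (n_conditions, N) relative-abundance matrix over
    the full pool species list, NaN rows where the community is empty.
    ``survivors`` lists the surviving species indices per condition.
    """

    records: pd.DataFrame
    profiles: np.ndarray
    survivors: list[np.ndarray]


@dataclass
class CurveSummary:
    """The four statistics of one diversity-biomass curve."""

    mean_div: float
    cv_div: float
    beta: float
    peak_pos: float


@dataclass
class RegressionTable:
    """OLS summary relating curve statistics to pool structure.

    ``table`` has one row per (response, term, modality) with the
    coefficient estimate and the Type-II partial eta-squared of the term;
    ``r2`` maps each response to its multiple R-squared.
    """

    table: pd.DataFrame
    r2: dict[str, float]


def run_gradient(pool: SpeciesPool,
                 grid: list[ResourceEnvironment] | None = None,
                 eps: float = EXTINCTION_EPS,
                 **sim_kwargs) -> GradientResult:
    """Assemble ``pool`` to equilibrium under every condition of ``grid``."""
    if grid is None:
        grid = resource_gradient()
    rows = []
    profiles = np.full((len(grid), pool.size), np.nan)
    survivors: list[np.ndarray] = []
    for k, env in enumerate(grid):
        result = simulate_to_equilibrium(pool, env, **sim_kwargs)
        state = prune_extinct(result.state, eps)
        n = richness(state.P, eps)
        biomass = float(state.P.sum())
        div = log_inv_simpson(state.P, eps) if n >= 1 else np.nan
        if n >= 1:
            profiles[k] = relative_abundance(state.P, eps)
        survivors.append(np.flatnonzero(state.P))
        rows.append({"a": env.a, "S": env.S, "biomass": biomass,
                     "diversity": div, "richness": n,
                     "converged": result.converged})
    return GradientResult(records=pd.DataFrame(rows), profiles=profiles,
                          survivors=survivors)


def fit_curve(biomass: np.ndarray, diversity: np.ndarray):
    """Penalized cubic-spline smoother of diversity on biomass.

    Smoothness is selected automatically by generalized cross-validation.
    Exact biomass ties are averaged before fitting. Returns a callable
    evaluable over [min(biomass), max(biomass)].
    """
    biomass = np.asarray(biomass, dtype=float)
    diversity = np.asarray(diversity, dtype=float)
    ok = np.isfinite(biomass) & np.isfinite(diversity)
    biomass, diversity = biomass[ok], diversity[ok]
    if biomass.size < 5:
        raise ValueError(
            f"need at least 5 points to fit the curve, got {biomass.size}")
    x, inv = np.unique(biomass, return_inverse=True)
    if x.size < biomass.size:
        y = np.bincount(inv, weights=diversity) / np.bincount(inv)
    else:
        order = np.argsort(biomass)
        x, y = biomass[order], diversity[order]
    if x.size < 5:
        raise ValueError("fewer than 5 distinct biomass values")
    return make_smoothing_spline(x, y)


def curve_statistics(curve, biomass: np.ndarray,
                     profiles: np.ndarray) -> CurveSummary:
    """The four summary statistics of a fitted diversity-biomass curve.

    ``biomass`` sets the evaluation range; ``profiles`` (one row per
    non-empty community, shared species list) feed the beta-diversity.
    ``peak_pos`` is the relative position of the curve maximum on a
    200-point grid; ``cv_div`` uses the population standard deviation and
    is 0 for an identically-zero curve.
    """
    biomass = np.asarray(biomass, dtype=float)
    biomass = biomass[np.isfinite(biomass)]
    lo, hi = float(biomass.min()), float(biomass.max())
    if hi <= lo:
        raise ValueError("degenerate biomass range: max equals min")
    grid = np.linspace(lo, hi, CURVE_GRID)
    values = np.asarray(curve(grid), dtype=float)
    mean_div = float(values.mean())
    cv_div = float(values.std() / mean_div) if mean_div != 0 else 0.0
    peak_pos = float((grid[np.argmax(values)] - lo) / (hi - lo))
    beta = beta_diversity(profiles)
    return CurveSummary(mean_div=mean_div, cv_div=cv_div, beta=beta,
                        peak_pos=peak_pos)


def summarize_gradient(result: GradientResult) -> CurveSummary:
    """Fit the curve for one pool's gradient run and extract its statistics.

    Only converged, non-empty conditions enter the fit and the
    beta-diversity.
    """
    rec = result.records
    use = (rec["richness"] >= 1) & rec["converged"]
    curve = fit_curve(rec.loc[use, "biomass"], rec.loc[use, "diversity"])
    profiles = result.profiles[use.to_numpy()]
    return curve_statistics(curve, rec.loc[use, "biomass"].to_numpy(), profiles)


_PREDICTORS = ["shape", "N", "f_mean", "f_rw", "l_mean", "l_rw"]
_RESPONSES = ["peak_pos", "mean_div", "cv_div"]


def pool_regression(data: pd.DataFrame,
                    responses: list[str] | None = None) -> RegressionTable:
    """OLS of curve statistics on pool-structure parameters.

    ``data`` needs the response columns and the predictors shape
    (categorical; uniform is the reference level), N, f_mean, f_rw, l_mean
    and l_rw. Partial eta-squared is SS_effect / (SS_effect + SS_residual)
    from Type-II sums of squares.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    if responses is None:
        responses = [r for r in _RESPONSES if r in data.columns]
    if len(data) < 30:
        raise ValueError("need at least 30 pools for the regression")
    _check_design_rank(data)
    rhs = "C(shape, Treatment('uniform')) + N + f_mean + f_rw + l_mean + l_rw"
    rows = []
    r2 = {}
    for resp in responses:
        fit = smf.ols(f"{resp} ~ {rhs}", data=data).fit()
        anova = anova_lm(fit, typ=2)
        ss_resid = anova.loc["Residual", "sum_sq"]
        r2[resp] = float(fit.rsquared)
        for term in anova.index:
            if term == "Residual":
                continue
            eta2 = float(anova.loc[term, "sum_sq"]
                         / (anova.loc[term, "sum_sq"] + ss_resid))
            if term.startswith("C(shape"):
                for level in ("decreasing", "bell", "increasing"):
                    name = f"{term}[T.{level}]"
                    if name in fit.params.index:
                        rows.append({"response": resp, "term": "shape",
                                     "modality": level,
                                     "estimate": float(fit.params[name]),
                                     "partial_eta2": eta2})
            else:
                rows.append({"response": resp, "term": term, "modality": "",
                             "estimate": float(fit.params[term]),
                             "partial_eta2": eta2})
    return RegressionTable(table=pd.DataFrame(rows), r2=r2)


def _check_design_rank(data: pd.DataFrame) -> None:
    """Raise naming the collinear columns if the design is rank-deficient."""
    numeric = ["N", "f_mean", "f_rw", "l_mean", "l_rw"]
    dummies = pd.get_dummies(data["shape"], prefix="shape")
    # one dummy is redundant with the intercept when all levels are present
    if dummies.shape[1] == 4:
        dummies = dummies.drop(columns="shape_uniform")
    blocks = [("intercept", np.ones(len(data)))]
    blocks += [(c, dummies[c].to_numpy(float)) for c in dummies.columns]
    blocks += [(c, data[c].to_numpy(float)) for c in numeric]
    names = [n for n, _ in blocks]
    X = np.column_stack([v for _, v in blocks])
    # scale columns so the pivot test is unit-free
    norms = np.linalg.norm(X, axis=0)
    _, r = np.linalg.qr(X / np.where(norms > 0, norms, 1.0))
    bad = [names[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-8]
    if bad:
        raise ValueError(f"rank-deficient design; collinear predictors: {bad}")


def tradeoff_comparison(n_pools: int, rng: np.random.Generator,
                        config: PoolStructureConfig | None = None,
                        grid: list[ResourceEnvironment] | None = None,
                        ) -> pd.DataFrame:
    """Beta-diversity along the gradient for each trade-off structure.

    Builds ``n_pools`` pools per structure at the reference configuration
    (uniform axis distribution) and returns one row per pool with its
    across-gradient beta-diversity.
    """
    from .pools import TRADEOFFS

    if n_pools < 1:
        raise ValueError("n_pools must be >= 1")
    if config is None:
        config = PoolStructureConfig()
    if grid is None:
        grid = resource_gradient()
    rows = []
    for tag in TRADEOFFS:
        cfg = replace(config, tradeoff=tag)
        for j in range(n_pools):
            pool = build_pool(cfg, rng)
            result = run_gradient(pool, grid)
            use = (result.records["richness"] >= 1).to_numpy()
            beta = (beta_diversity(result.profiles[use])
                    if use.any() else np.nan)
            rows.append({"tradeoff": tag, "pool": j, "beta": beta})
    return pd.DataFrame(rows)


def pool_structure_sweep(n_pools: int, seed: int,
                         grid: list[ResourceEnvironment] | None = None,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random pool structures -> gradient assembly -> curve statistics.

    Draws ``n_pools`` triple-trade-off pool configurations, assembles each
    across the gradient, and returns (summaries, records): one summary row
    per pool (structure parameters + curve statistics; NaN where the curve
    could not be fitted) and the per-condition records of every pool.
    """
    from .config import substream

    if grid is None:
        grid = resource_gradient()
    summaries, all_records = [], []
    for i in range(n_pools):
        rng = substream(seed, i)
        cfg = sample_pool_config(rng)
        pool = build_pool(cfg, rng)
        result = run_gradient(pool, grid)
        row = {f.name: getattr(cfg, f.name) for f in fields(cfg)}
        row["pool"] = i
        try:
            summary = summarize_gradient(result)
            row.update(vars(summary))
        except ValueError:
            row.update({k: np.nan for k in
                        ("mean_div", "cv_div", "beta", "peak_pos")})
        summaries.append(row)
        rec = result.records.copy()
        rec.insert(0, "pool", i)
        all_records.append(rec)
    return pd.DataFrame(summaries), pd.concat(all_records, ignore_index=True)
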