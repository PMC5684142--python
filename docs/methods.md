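# Methods

## Model

The community model couples one soil resource $R$ to the biomasses $P_i$
of $N$ plant species:

$$\dot R = a(S-R) - \textstyle\sum_i f_i P_i R, \qquad
\dot P_i = P_i\,(f_i R - m_i - c P_i - l_i \textstyle\sum_j P_j).$$

Assumptions: a single limiting resource with chemostat renewal; Holling
type-I (linear) uptake; well-mixed, non-spatial, deterministic dynamics;
competition for light summarized phenomenologically by a per-species
sensitivity $l_i$ to *total* standing biomass. The total-biomass term
includes the focal species, so the effective intraspecific rate is
$c + l_i$; the crowding rate $c$ is shared by all species and is what
generates over-yielding in mixtures. $R^*_i = m_i/f_i$ is the lowest
resource level at which species $i$ has non-negative growth in an empty
community; $R^*_i < S$ is the monoculture persistence condition, and at
any coexistence equilibrium every survivor satisfies $R^*_i < \hat R \le S$.

## Species pools

Species occupy positions $x \in [0,1]$ on a trade-off axis. With range
bounds derived from a mean and range width (e.g.
$f \in [f_{\text{mean}} - f_{\text{rw}}/2,\, f_{\text{mean}} + f_{\text{rw}}/2]$):

- $f(x)$ rises linearly from $f_{lo}$ to $f_{hi}$ when $f$ is on the axis;
- $l(x)$ falls linearly from $l_{hi}$ to $l_{lo}$ when $l$ is on the axis;
- when $m$ and $f$ are both on the axis, $m = b f^2$, so $R^* = b f$
  rises linearly along the axis (fast growers demand richer soils). With
  the reference values ($f \in [1.0, 2.2]$, $b = 0.5$) the pool spans
  $R^* \in [0.5, 1.1]$. When $m$ alone is on the axis (the $m$–$l$
  trade-off) it rises linearly over the implied range
  $[b f_{lo}^2,\, b f_{hi}^2]$.
- traits not constrained by the active trade-off are drawn independently
  and uniformly over their ranges; unconstrained mortality is drawn from
  the same range shrunk about its midpoint by the factor $B$.

The quadratic $m$–$f$ link and the role of $B$ are this package's
parametrization of a mapping whose original source is not fully specified;
they are chosen so that $R^*$ increases along the axis, the single
parameter $b$ sets the $R^*$ slope, and all traits stay strictly positive.
Axis positions follow a uniform or triangular distribution (mode at the
minimum, centre or maximum of $[0,1]$ — "decreasing", "bell",
"increasing"), sampled by inverse CDF so runs are seed-reproducible.

Defaults (used by the trade-off comparison and as the centre of the
sweep): $N = 125$, $f_{\text{mean}} = 1.6$, $f_{\text{rw}} = 1.2$,
$l_{\text{mean}} = 2.05$, $l_{\text{rw}} = 1.7$, $c = 0.6$, $b = 0.5$,
$B = 0.5$, uniform axis. The structure sweep draws
$N \sim U\{25,\dots,200\}$, shape uniformly over the four options,
$f_{\text{mean}} \in [1.2, 2.0]$, $f_{\text{rw}} \in [0.4, 2.0]$,
$l_{\text{mean}} \in [1.4, 2.7]$, $l_{\text{rw}} \in [0.4, 3.0]$, with the
$(l_{\text{mean}}, l_{\text{rw}})$ pair redrawn jointly when the implied
lower bound of $l$ would be non-positive.

## Numerical assembly

Initial conditions: $R(0) = S$ and $P_i(0) = 0.01$ for every sown species
(small equal propagules into a resource-saturated site). The system is
integrated with an adaptive Dormand–Prince 5(4) scheme (JIT-compiled;
`rtol=1e-6`, `atol=1e-9` by default) with states clipped at zero, until
the maximum absolute derivative falls below `tol = 1e-8` or `t_max = 5000`
time units.

Near-threshold species decay exponentially at arbitrarily slow rates, so
the raw residual criterion can stay unmet past any practical horizon. Once
the residual is below $10^{-3}$, the state is therefore projected onto the
exact saturated equilibrium of the surviving species: for a fixed active
set the zero-growth conditions are linear in $(R, P)$ — with
$M = cI + l\mathbf{1}^\top$, $P(R) = M^{-1}(fR - m)$ is linear in $R$
(Sherman–Morrison) and the resource balance becomes a quadratic in $R$,
the multispecies generalization of the closed-form monoculture
equilibrium. Species whose equilibrium abundance is non-positive are
dropped iteratively; the candidate is accepted only if every species being
sent extinct has a negative invasion growth rate there (species at exactly
$P = 0$ are skipped — zero biomass is invariant under the flow) and the
full-system residual is below `tol`. Projected equilibria match
40000-time-unit pure integration to $|\Delta P| < 10^{-6}$ with identical
survivor sets, and cut the per-assembly cost by roughly fifty-fold. The
projection can be disabled (`polish=False`) for pure-integration runs;
explicit Runge–Kutta then stalls at an error-controller floor of order
`rtol`·|y| near the fixed point, so reaching `tol = 1e-8` by integration
alone requires `rtol` around `1e-10`.

After assembly, biomasses strictly below `eps = 1e-6` are set to zero
before any diversity computation (entries exactly at `eps` survive).

## Experiments and statistics

**Resource gradient.** A factorial grid of
$a \in \{0.05, 0.45, \dots, 2.45\}$ by $S \in \{0.1, 0.7, \dots, 3.1\}$
(42 conditions) spanning the four fixed levels used by the BEF design.
Diversity is the natural-log inverse Simpson index $\ln(1/\sum p_i^2)$; its
exponential is the order-2 Hill number. The diversity–biomass relationship
of each pool is smoothed with `scipy`'s penalized cubic smoothing spline
with GCV-selected smoothness (exact biomass ties averaged first; at least
5 points required), fitted to converged, non-empty conditions only. Curve
statistics are computed on a 200-point grid over the realized biomass
range: mean, coefficient of variation (population SD / mean; defined as 0
for an identically zero curve), and relative peak position. β-diversity is
computed on the raw equilibrium communities, not the curve, as the
Hill-number ratio γ/α with equal community weights — the multiplicative
(Jost) partition, chosen because it is independent of α-diversity; a
log-ratio would not be. It is exactly 1 for identical communities and M
for M disjoint equally-even ones.

**Trade-off comparison.** 500 pools per trade-off structure at the default
configuration in the full-scale protocol (the acceptance tests use 20 per
structure, which already separates the medians cleanly), each assembled
across the gradient and summarized by its β-diversity.

**Structure sweep and regression.** 3000 pool structures at full scale
(300 in the acceptance replication) under the triple trade-off. Curve
statistics are regressed on shape (categorical, uniform as the reference
level, matching a table that reports the three non-uniform modalities),
$N$, $f_{\text{mean}}$, $f_{\text{rw}}$, $l_{\text{mean}}$ and
$l_{\text{rw}}$ by OLS; effect sizes are Type-II partial
$\eta^2 = SS_{\text{effect}} / (SS_{\text{effect}} + SS_{\text{resid}})$
(no interactions, so Type II equals Type III). The design matrix is
rank-checked first and collinear predictors are reported by name.

**BEF subsampling.** For each pool and each of the four resource levels
$(a,S) \in \{(0.05,0.1), (0.85,1.1), (1.65,2.1), (2.45,3.1)\}$, subsets of
1, 5, 10, 20, 50, 100 and 150 species (sizes above the pool size skipped)
are drawn uniformly without replacement, 10 replicates each at full scale
(sizes up to 50 and 3 replicates in the scaled acceptance runs), assembled
to equilibrium, and the Spearman correlation (average-rank ties) between
diversity and biomass is computed per pool × level — one correlation per
"experiment". Replicates with no survivors are recorded as missing and
excluded (with a logged count); monoculture outcomes have diversity 0;
levels with constant diversity yield an undefined correlation and are
flagged rather than imputed.

## Randomness and reproducibility

All randomness derives from one master seed through `SeedSequence`
substreams keyed by (seed, stream label, pool index), so results are
independent of execution order and identical across serial and parallel
runs. Every CLI run writes a provenance JSON (config echo, seed, package
version) next to its CSV outputs.

## What the generator does and does not emulate

The synthetic pools reproduce the *structure* of the study conditions —
trade-off-constrained trait covariation, the four axis-distribution
shapes, and the swept ranges of pool size and trait means/widths. They do
not emulate features of real floras: phylogenetic structure, trait
measurement error, dispersal limitation, temporal environmental variation,
or demographic stochasticity. Passing tests therefore demonstrate
properties of the model and its implementation, not predictions validated
against field data.

## Known limitations

- The exact trade-off equations and sweep ranges of the original study are
  not fully recoverable; this package's parametrization is documented
  above. Regression *sign* patterns are largely, but not fully, robust to
  that choice: in this parametrization a wider $f$ range widens the $R^*$
  span and sustains copiotrophic coexistence at rich conditions, so the
  diversity peak shifts toward high biomass as $f_{\text{rw}}$ grows,
  whereas the original analysis reports the opposite (weak) effect. The
  corresponding acceptance check is left failing rather than
  reparametrized.
- The equilibrium projection assumes the integrated trajectory has entered
  the basin of a saturated equilibrium; the invasibility and positivity
  guards reject premature projections, falling back to plain integration.
- Single resource, no space, no stochasticity (model scope, not numerical
  limits).
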