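# poolsim

Simulation toolkit for a long-standing puzzle in grassland ecology: sowing
experiments (BEF designs) find that more plant species means more biomass,
while fertilization studies find that more productive sites hold *fewer*
species. `poolsim` implements a mechanistic plant–resource community model
in which both observations emerge from the same dynamics, and the shape of
the productivity–diversity relationship is controlled by the structure of
the regional species pool — how many species it holds and how their traits
are distributed along functional trade-off axes.

It is aimed at theoretical community ecologists who want a fast, tested,
reproducible implementation of the model and of the three in-silico
experiments built on it: trade-off comparison, species-pool-structure
sweep, and BEF-style subsampling.

## The model

A single soil resource $R$ renews chemostat-style toward a capacity $S$ at
rate $a$ and is consumed by $N$ plant species with biomasses $P_i$:

$$\frac{dR}{dt} = a(S - R) - \sum_i f_i P_i R$$

$$\frac{dP_i}{dt} = P_i \left( f_i R - m_i - c_i P_i - l_i \sum_j P_j \right)$$

Each species carries four traits: resource uptake $f_i$ (Holling type-I
growth), intrinsic mortality $m_i$, intraspecific crowding $c_i$ (constant
$c$ across species — conspecifics overlap more in niche than
heterospecifics, which is what produces over-yielding), and sensitivity
$l_i$ to total standing biomass (phenomenological competition for light).
The minimum resource requirement of species $i$ is Tilman's
$R^*_i = m_i / f_i$: a species can establish alone only where $R^*_i < S$.

Species pools are generated along a one-dimensional trade-off axis
mirroring Grime's Competition–Stress strategy axis. Under the full triple
trade-off, fast-growing species (high $f$) are also stress-sensitive
(high $m$, with $R^* = b f$ rising along the axis) and biomass-tolerant
(low $l$); slow-growing stress-tolerators sit at the other end. Single
trade-offs ($m$–$f$, $m$–$l$, $f$–$l$) and unconstrained pools are also
available, and the axis positions can follow uniform, decreasing,
bell-shaped or increasing (triangular) distributions.

Communities are assembled to equilibrium across a 42-condition resource
grid; the diversity (log inverse Simpson) vs total biomass relationship is
smoothed with a penalized cubic spline (GCV-selected smoothness) and
summarized by its mean, coefficient of variation, across-gradient
multiplicative β-diversity (Hill-number γ/α), and the relative position of
its peak — interior peak positions indicate the hump-shaped relationship.

## Worked example

```python
import numpy as np
from poolsim import ResourceEnvironment, simulate_to_equilibrium, prune_extinct
from poolsim.pools import PoolStructureConfig, build_pool
from poolsim.gradient import run_gradient, summarize_gradient

rng = np.random.default_rng(42)
pool = build_pool(PoolStructureConfig(), rng)   # 125 species, triple trade-off

env = ResourceEnvironment(a=0.85, S=1.1)
res = simulate_to_equilibrium(pool, env)
state = prune_extinct(res.state)
print(f"survivors: {int((state.P > 0).sum())} of {pool.size}")
print(f"equilibrium resource: {state.R:.4f}, total biomass: {state.P.sum():.4f}")

summary = summarize_gradient(run_gradient(pool))
print(f"mean diversity: {summary.mean_div:.3f}")
print(f"CV of diversity: {summary.cv_div:.3f}")
print(f"beta-diversity:  {summary.beta:.3f}")
print(f"peak position:   {summary.peak_pos:.3f}")
```

prints

```
survivors: 23 of 125
equilibrium resource: 0.9209, total biomass: 0.1461
mean diversity: 2.514
CV of diversity: 0.282
beta-diversity:  1.887
peak position:   0.417
```

Of 125 available species, 23 coexist at this mid-gradient resource level,
drawing the resource down to 0.92 (every survivor has $R^* < 0.92$).
Across the whole gradient this pool turns over substantially
(β ≈ 1.9 effective communities) and its diversity–biomass curve is
hump-shaped, peaking at 42% of the biomass range.

The same experiments are available from the shell:

```sh
$ poolsim tradeoffs --n-pools 3 --seed 1 --out results/
median beta [f_l]: 0.962
median beta [m_f]: 1.625
median beta [m_f_l]: 2.397
median beta [m_l]: 1.349
median beta [none]: 1.204

$ poolsim bef --n-pools 3 --seed 1 --out results/
mean Spearman: 0.955 (range 0.857-0.981)
```

The first compares community turnover under the five trade-off structures
(sorting requires the mortality–uptake trade-off and is strongest under the
triple trade-off); the second replicates a sowing experiment at four fixed
resource levels, where the diversity–biomass rank correlation is
consistently positive. Subcommands `gradient` and `pool-sweep` drive the
resource-gradient and pool-structure-sweep experiments; all accept
`--config` (TOML), `--seed`, `--n-pools` and `--out`, and write CSV tables
plus a JSON provenance echo.

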