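"""Dynamics, analytic equilibria and assembly of the plant-resource model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolsim import (
    CommunityState,
    ResourceEnvironment,
    SpeciesPool,
    derivatives,
    prune_extinct,
    rstar,
    simulate_to_equilibrium,
    single_species_equilibrium,
)
from poolsim.model import default_initial_state


class TestDerivatives:
    def test_empty_community_is_fixed_point(self, fixture_pool):
        state = CommunityState(R=1.1, P=np.zeros(fixture_pool.size))
        env = ResourceEnvironment(a=0.85, S=1.1)
        assert np.allclose(derivatives(state, fixture_pool, env), 0.0)

    def test_chemostat_renewal_below_capacity(self, fixture_pool):
        state = CommunityState(R=0.3, P=np.zeros(fixture_pool.size))
        env = ResourceEnvironment(a=0.85, S=1.1)
        d = derivatives(state, fixture_pool, env)
        assert d[0] == pytest.approx(0.85 * (1.1 - 0.3))
        assert np.all(d[1:] == 0.0)

    def test_hand_computed_rates(self, single_species_pool, env):
        state = CommunityState(R=1.0, P=np.array([0.5]))
        d = derivatives(state, single_species_pool, env)
        # dR = 0.85*(1.1-1) - 1.6*0.5*1; dP = 0.5*(1.6 - 1.28 - 0.3 - 1.025)
        assert d[0] == pytest.approx(-0.715)
        assert d[1] == pytest.approx(-0.5025)

    def test_dimension_mismatch_raises(self, single_species_pool, env):
        state = CommunityState(R=1.0, P=np.array([0.5, 0.5]))
        with pytest.raises(ValueError, match="pool"):
            derivatives(state, single_species_pool, env)


class TestRstar:
    def test_direct_ratio_and_identity(self):
        assert rstar(1.6, 1.28) == pytest.approx(0.8)
        assert rstar(2.0, 2.0) == pytest.approx(1.0)

    def test_homogeneity(self):
        assert rstar(3.2, 1.28) == pytest.approx(rstar(1.6, 1.28) / 2)

    def test_zero_uptake_is_invalid(self):
        with pytest.raises(ValueError, match="invalid trait"):
            rstar(0.0, 1.0)

    def test_vectorized(self, fixture_pool):
        rs = fixture_pool.rstar()
        assert np.allclose(rs, fixture_pool.m / fixture_pool.f)


class TestPruneExtinct:
    def test_below_threshold_zeroed(self):
        state = CommunityState(R=0.5, P=np.array([1e-9, 0.4]))
        out = prune_extinct(state, eps=1e-6)
        assert out.P.tolist() == [0.0, 0.4]
        assert out.R == 0.5

    def test_all_above_threshold_unchanged(self):
        state = CommunityState(R=0.5, P=np.array([0.1, 0.4]))
        assert prune_extinct(state, eps=1e-6).P.tolist() == [0.1, 0.4]

    def test_boundary_survives(self):
        state = CommunityState(R=0.5, P=np.array([1e-6]))
        assert prune_extinct(state, eps=1e-6).P.tolist() == [1e-6]


class TestSingleSpeciesEquilibrium:
    def test_nonviable_species_goes_extinct(self):
        env = ResourceEnvironment(a=0.85, S=0.5)  # R* = 0.8 > S
        assert single_species_equilibrium(1.6, 1.28, 0.6, 2.05, env) == (0.5, 0.0)

    def test_fast_renewal_pins_resource_at_capacity(self):
        env = ResourceEnvironment(a=1e7, S=1.1)
        R_hat, P_hat = single_species_equilibrium(1.6, 1.28, 0.6, 2.05, env)
        assert R_hat == pytest.approx(1.1, rel=1e-5)
        assert P_hat == pytest.approx((1.6 * 1.1 - 1.28) / (0.6 + 2.05), rel=1e-4)

    def test_root_satisfies_both_balance_equations(self, single_species_pool, env):
        R_hat, P_hat = single_species_equilibrium(1.6, 1.28, 0.6, 2.05, env)
        assert 1.28 / 1.6 < R_hat <= 1.1
        state = CommunityState(R=R_hat, P=np.array([P_hat]))
        d = derivatives(state, single_species_pool, env)
        assert np.max(np.abs(d)) < 1e-10


class TestSimulateToEquilibrium:
    def test_empty_pool_resource_reaches_capacity(self):
        pool = SpeciesPool(f=np.empty(0), m=np.empty(0), l=np.empty(0), c=0.6)
        env = ResourceEnvironment(a=0.85, S=1.1)
        init = CommunityState(R=0.2, P=np.empty(0))
        res = simulate_to_equilibrium(pool, env, init=init)
        assert res.converged
        assert res.state.R == pytest.approx(1.1, abs=1e-6)

    def test_unsown_species_stay_absent(self, fixture_pool):
        env = ResourceEnvironment(a=0.85, S=1.1)
        init = CommunityState(R=0.4, P=np.zeros(fixture_pool.size))
        res = simulate_to_equilibrium(fixture_pool, env, init=init)
        assert res.converged
        assert res.state.R == pytest.approx(1.1, abs=1e-6)
        assert np.all(res.state.P == 0.0)

    def test_species_above_capacity_goes_extinct(self, single_species_pool):
        env = ResourceEnvironment(a=0.85, S=0.5)  # R* = 0.8 > S
        res = simulate_to_equilibrium(single_species_pool, env)
        assert res.converged
        assert res.state.P[0] < 1e-6
        assert res.state.R == pytest.approx(0.5, abs=1e-6)

    @pytest.mark.parametrize("polish", [True, False])
    def test_matches_closed_form_monoculture(self, polish):
        rng = np.random.default_rng(20)
        env = ResourceEnvironment(a=0.85, S=1.1)
        for _ in range(20):
            f = rng.uniform(1.0, 2.2)
            m = rng.uniform(0.3, 0.9) * f  # R* in (0.3, 0.9) < S
            c, l = 0.6, rng.uniform(1.2, 2.9)
            pool = SpeciesPool(f=np.array([f]), m=np.array([m]),
                               l=np.array([l]), c=c)
            R_hat, P_hat = single_species_equilibrium(f, m, c, l, env)
            # tight solver tolerances: the pure-integration route must push
            # the residual below tol without the equilibrium projection
            res = simulate_to_equilibrium(pool, env, polish=polish,
                                          rtol=1e-10, atol=1e-12)
            assert res.converged
            assert res.state.R == pytest.approx(R_hat, rel=1e-5)
            assert res.state.P[0] == pytest.approx(P_hat, rel=1e-5)

    def test_polish_agrees_with_long_integration(self, fixture_pool):
        for a, S in [(0.85, 1.1), (2.45, 3.1), (0.05, 0.7)]:
            env = ResourceEnvironment(a=a, S=S)
            fast = simulate_to_equilibrium(fixture_pool, env)
            slow = simulate_to_equilibrium(fixture_pool, env, polish=False,
                                           t_max=40000)
            P_fast = prune_extinct(fast.state).P
            P_slow = prune_extinct(slow.state).P
            assert fast.converged
            assert np.array_equal(P_fast > 0, P_slow > 0)
            assert np.allclose(P_fast, P_slow, atol=1e-6)
            assert fast.state.R == pytest.approx(slow.state.R, abs=1e-6)

    def test_cross_check_against_scipy_rk45(self, fixture_pool):
        """Independent integrator route: scipy solve_ivp on the same RHS."""
        from scipy.integrate import solve_ivp

        env = ResourceEnvironment(a=0.85, S=1.1)
        init = default_initial_state(fixture_pool, env)

        def rhs(_, y):
            return derivatives(CommunityState(R=y[0], P=np.maximum(y[1:], 0)),
                               fixture_pool, env)

        sol = solve_ivp(rhs, (0.0, 3000.0),
                        np.concatenate(([init.R], init.P)),
                        method="RK45", rtol=1e-8, atol=1e-10)
        ours = simulate_to_equilibrium(fixture_pool, env)
        assert ours.converged
        assert ours.state.R == pytest.approx(sol.y[0, -1], abs=1e-5)
        assert np.allclose(ours.state.P, np.maximum(sol.y[1:, -1], 0.0),
                           atol=1e-4)

    def test_invalid_tolerance_rejected(self, single_species_pool, env):
        with pytest.raises(ValueError, match="tol"):
            simulate_to_equilibrium(single_species_pool, env, tol=0.0)


@st.composite
def small_pools(draw):
    n = draw(st.integers(min_value=1, max_value=6))
    f = draw(st.lists(st.floats(0.5, 2.5), min_size=n, max_size=n))
    rs = draw(st.lists(st.floats(0.1, 1.5), min_size=n, max_size=n))
    l = draw(st.lists(st.floats(0.5, 3.0), min_size=n, max_size=n))
    m = [fi * ri for fi, ri in zip(f, rs)]
    return SpeciesPool(f=np.array(f), m=np.array(m), l=np.array(l), c=0.6)


@st.composite
def environments(draw):
    return ResourceEnvironment(a=draw(st.floats(0.05, 2.5)),
                               S=draw(st.floats(0.1, 3.1)))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(pool=small_pools(), env=environments())
def test_equilibrium_invariants(pool, env):
    """Converged equilibria respect the model's analytic constraints:

    residual below tolerance when re-evaluated, resource at or below
    capacity, no negative abundances, and every persisting species able to
    grow at the equilibrium resource level (R* < R_hat).
    """
    res = simulate_to_equilibrium(pool, env)
    state = res.state
    assert state.R >= 0.0 and np.all(state.P >= 0.0)
    if res.converged:
        d = derivatives(state, pool, env)
        assert np.max(np.abs(d)) <= 1e-8 * 1.01
        assert state.R <= env.S * (1 + 1e-9)
        survivors = state.P > 1e-6
        if survivors.any():
            assert np.all(pool.rstar()[survivors] < state.R)
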