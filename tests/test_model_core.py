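"""Within-cycle dynamics: growth-rate functions, derivatives and the
single-cycle integrator."""

import numpy as np
import pytest

from crossprotect import (
    PatchState,
    cycle_derivatives,
    growth_rate_ampR,
    growth_rate_chlR,
    integrate_growth_cycle,
)
from crossprotect._kernels import integrate_cycle, pack_params
from crossprotect.model import logistic_with_lag


class TestGrowthRates:
    def test_ampR_zero_antibiotic_gives_max_rate(self, simple_params):
        t = simple_params.t_lag + 1.0
        assert growth_rate_ampR(0.0, t, simple_params) == pytest.approx(
            simple_params.gamma1R
        )

    def test_ampR_half_inhibition_point(self, simple_params):
        t = simple_params.t_lag + 1.0
        assert growth_rate_ampR(
            simple_params.I12, t, simple_params
        ) == pytest.approx(simple_params.gamma1R / 2)

    def test_lag_phase_shuts_growth_off(self, simple_params):
        t = simple_params.t_lag / 2
        assert growth_rate_ampR(123.0, t, simple_params) == 0.0
        assert growth_rate_chlR(123.0, t, simple_params) == 0.0

    def test_ampR_rate_never_negative(self, simple_params):
        # chloramphenicol is bacteriostatic: rate stays in [0, gamma1R]
        t = simple_params.t_lag + 1.0
        for a2 in [0.0, 0.1, 1.0, 100.0, 1e6]:
            r = growth_rate_ampR(a2, t, simple_params)
            assert 0.0 <= r <= simple_params.gamma1R

    def test_chlR_zero_antibiotic_gives_max_rate(self, simple_params):
        t = simple_params.t_lag + 1.0
        assert growth_rate_chlR(0.0, t, simple_params) == pytest.approx(
            simple_params.gamma2R
        )

    def test_chlR_bactericidal_asymptote(self, simple_params):
        # ampicillin kills: the rate approaches -gamma2D at saturation
        t = simple_params.t_lag + 1.0
        assert growth_rate_chlR(1e9, t, simple_params) == pytest.approx(
            -simple_params.gamma2D, rel=1e-6
        )

    def test_chlR_midpoint_value(self, simple_params):
        t = simple_params.t_lag + 1.0
        expected = (simple_params.gamma2R - simple_params.gamma2D) / 2
        assert growth_rate_chlR(
            simple_params.I21, t, simple_params
        ) == pytest.approx(expected)

    @pytest.mark.parametrize("func", [growth_rate_ampR, growth_rate_chlR])
    def test_domain_errors(self, func, simple_params):
        with pytest.raises(ValueError):
            func(-1.0, 5.0, simple_params)
        with pytest.raises(ValueError):
            func(1.0, -0.1, simple_params)
        with pytest.raises(ValueError):
            func(1.0, simple_params.T_cycle + 1.0, simple_params)


class TestCycleDerivatives:
    def test_logistic_saturation_stops_growth(self, simple_params):
        state = PatchState(6e4, 4e4, 1.0, 1.0)  # N1+N2 == K
        d = cycle_derivatives(state, 5.0, state.N1, simple_params)
        assert d[0] == pytest.approx(0.0, abs=1e-12)
        assert d[1] == pytest.approx(0.0, abs=1e-12)

    def test_no_antibiotic_no_degradation(self, simple_params):
        state = PatchState(100.0, 100.0, 0.0, 0.0)
        d = cycle_derivatives(state, 5.0, state.N1, simple_params)
        assert d[2] == 0.0 and d[3] == 0.0

    def test_chloramphenicol_degradation_arithmetic(self, simple_params):
        # dA2/dt = -c2 * A2 * N2 with c2=0.1, A2=5, N2=2 -> -1
        params = simple_params.replace(c2=0.1)
        state = PatchState(0.0, 2.0, 0.0, 5.0)
        d = cycle_derivatives(state, 5.0, 0.0, params)
        assert d[3] == pytest.approx(-1.0)

    def test_ampicillin_uses_initial_not_instantaneous_density(
        self, simple_params
    ):
        # the enzyme driver is the start-of-cycle AmpR density
        state = PatchState(1.0, 0.0, 10.0, 0.0)
        d_small = cycle_derivatives(state, 5.0, 1.0, simple_params)
        d_large = cycle_derivatives(state, 5.0, 1000.0, simple_params)
        assert d_large[2] == pytest.approx(1000.0 * d_small[2])


class TestIntegrateGrowthCycle:
    def test_empty_patch_is_fixed_point(self, simple_params):
        tr = integrate_growth_cycle(PatchState(0, 0, 7.0, 3.0), simple_params)
        end = tr.final_state
        # no cells: the A1 driver N1(0)=0 and c2*A2*N2=0 freeze everything
        assert end.N1 == 0 and end.N2 == 0
        assert end.A1 == pytest.approx(7.0, rel=1e-9)
        assert end.A2 == pytest.approx(3.0, rel=1e-9)

    def test_single_strain_matches_lagged_logistic(self, simple_params):
        # no antibiotics: N1 follows the closed-form logistic with lag
        n0 = 50.0
        tr = integrate_growth_cycle(PatchState(n0, 0, 0, 0), simple_params)
        expected = logistic_with_lag(
            n0,
            simple_params.T_cycle,
            simple_params.gamma1R,
            simple_params.K,
            simple_params.t_lag,
        )
        assert tr.final_state.N1 == pytest.approx(expected, rel=1e-6)

    def test_total_density_bounded_by_capacity(self, model):
        tr = integrate_growth_cycle(PatchState(400, 600, 10, 8), model)
        totals = tr.states[:, 0] + tr.states[:, 1]
        assert np.all(totals <= model.K * (1 + 1e-9))

    def test_antibiotics_nonincreasing(self, model):
        tr = integrate_growth_cycle(PatchState(400, 600, 10, 8), model)
        assert np.all(np.diff(tr.states[:, 2]) <= 1e-9)
        assert np.all(np.diff(tr.states[:, 3]) <= 1e-9)

    def test_state_nonnegative_throughout(self, model):
        tr = integrate_growth_cycle(PatchState(5, 1e4, 10, 16), model)
        assert np.all(tr.states >= 0)

    def test_lag_inertness_densities_constant_antibiotics_fall(self, model):
        # during the lag phase cells neither grow nor die, but degradation
        # (enzyme carry-over, intracellular deactivation) continues
        tr = integrate_growth_cycle(PatchState(500, 500, 10, 8), model)
        in_lag = tr.times <= model.t_lag
        assert np.ptp(tr.states[in_lag, 0]) <= 1e-6 * 500
        assert np.ptp(tr.states[in_lag, 1]) <= 1e-6 * 500
        assert tr.states[in_lag][-1, 2] < 10.0

    def test_trajectory_records_frozen_driver(self, model):
        tr = integrate_growth_cycle(PatchState(321.0, 10, 10, 8), model)
        assert tr.N1_initial == 321.0
        assert tr.states[0, 0] == pytest.approx(321.0)

    def test_grid_refinement_convergence(self, model):
        init = PatchState(400, 600, 10, 8)
        a = integrate_growth_cycle(init, model, rtol=1e-8, atol=1e-10)
        b = integrate_growth_cycle(init, model, rtol=5e-9, atol=5e-11)
        ref = np.maximum(np.abs(b.states[-1]), 1.0)
        assert np.all(np.abs(a.states[-1] - b.states[-1]) / ref <= 1e-6)


class TestKernelAgreement:
    """The compiled day-map kernel and the SciPy reference integration are
    independent implementations of the same cycle; they must agree."""

    @pytest.mark.parametrize(
        "init",
        [(500, 500, 10, 8), (5, 2e4, 10, 16), (300, 0.01, 10, 8)],
    )
    def test_end_states_agree(self, model, init):
        y0 = np.array(init, dtype=float)
        fast = integrate_cycle(y0, pack_params(model), 1e-10, 1e-12)
        slow = integrate_growth_cycle(
            PatchState(*init), model, rtol=1e-10, atol=1e-12
        ).final_state.as_array()
        assert np.all(np.abs(fast - slow) <= 1e-6 * np.abs(slow) + 1e-8)
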