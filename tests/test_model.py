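"""Core gLV dynamics: right-hand side, event handling, integrator agreement."""

import numpy as np
import pytest

from vmbsim.model import (
    NAB,
    PROB,
    AntibioticWindow,
    CommunityState,
    DoseEvent,
    GLVParameters,
    glv_rhs,
    simulate,
    simulate_batch,
)

from oracles import logistic_solution, rk4_glv


def null_probiotic_params(k_p=0.5, a_pp=-0.022):
    """Only P grows; residents inert (k=0, all interactions 0)."""
    k = np.zeros(4)
    k[PROB] = k_p
    a = np.zeros((4, 4))
    a[PROB, PROB] = a_pp
    return GLVParameters(k, a)


@pytest.fixture()
def stable_resident_params(rng):
    """A random 3-resident parameter set with a stable interior point."""
    # diagonally dominant draw: coexistence equilibrium guaranteed stable
    k = np.array([0.6, 0.4, 0.3, 0.5])
    a = rng.uniform(-0.005, 0.005, size=(4, 4))
    np.fill_diagonal(a, [-0.03, -0.025, -0.02, -0.022])
    return GLVParameters(k, a)


class TestRHS:
    def test_extinction_is_absorbing(self):
        p = null_probiotic_params()
        assert np.allclose(glv_rhs(0.0, np.zeros(4), p), 0.0)

    def test_logistic_fixed_point_of_null_strain(self):
        p = null_probiotic_params()
        x = np.zeros(4)
        x[PROB] = 0.5 / 0.022
        assert np.allclose(glv_rhs(0.0, x, p), 0.0, atol=1e-12)

    def test_kill_rate_replaces_nab_growth_only_inside_window(self):
        k = np.array([0.8, 0.5, 0.5, 0.5])
        a = -0.02 * np.eye(4)
        p = GLVParameters(k, a)
        w = [AntibioticWindow(1.0, 3.0, -2.64)]
        x = np.ones(4)
        inside = glv_rhs(2.0, x, p, w)
        outside = glv_rhs(0.5, x, p, w)
        assert inside[NAB] == pytest.approx(-2.64 - 0.02)
        assert outside[NAB] == pytest.approx(0.8 - 0.02)
        assert np.allclose(inside[1:], outside[1:])

    def test_overlapping_windows_rejected(self):
        p = null_probiotic_params()
        ws = [AntibioticWindow(0, 5, -2.0), AntibioticWindow(4, 8, -3.0)]
        with pytest.raises(ValueError, match="overlap"):
            glv_rhs(0.0, np.ones(4), p, ws)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            GLVParameters(np.array([0.5, 0, 0, 0]), np.zeros((4, 4)))
        with pytest.raises(ValueError):
            AntibioticWindow(3.0, 1.0, -2.64)
        with pytest.raises(ValueError):
            AntibioticWindow(0.0, 1.0, +1.0)
        with pytest.raises(ValueError):
            DoseEvent(0.0, -1.0)


class TestSimulate:
    def test_antibiotic_window_gives_first_order_decay(self):
        # nAB alone with zero growth/interactions: x(t) = x0 exp(k_kill t)
        k = np.zeros(4)
        a = np.zeros((4, 4))
        p = GLVParameters(k, a)
        x0 = CommunityState(np.array([10.0, 0, 0, 0]))
        traj = simulate(
            p, x0, windows=[AntibioticWindow(0.0, 2.0, -2.64)], horizon=2.0, eval_times=[1.0, 2.0]
        )
        assert traj.state_at(1.0).abundances[NAB] == pytest.approx(10 * np.exp(-2.64), rel=1e-5)
        assert traj.state_at(2.0).abundances[NAB] == pytest.approx(10 * np.exp(-5.28), rel=1e-5)

    def test_fixed_point_is_stationary(self):
        p = null_probiotic_params()
        x0 = CommunityState(np.array([0, 0, 0, 0.5 / 0.022]))
        traj = simulate(p, x0, horizon=100.0, eval_times=[50.0, 100.0])
        assert np.allclose(traj.final_state().abundances[PROB], 0.5 / 0.022, rtol=1e-6)

    def test_dose_accounting_with_inert_probiotic(self):
        # no P sources or sinks: total P equals the sum of all boluses
        p = GLVParameters(np.zeros(4), np.zeros((4, 4)))
        doses = [DoseEvent(float(t), 1.5) for t in range(7)]
        traj = simulate(p, CommunityState(np.zeros(4)), doses=doses, horizon=10.0, eval_times=[10.0])
        assert traj.final_state().abundances[PROB] == pytest.approx(7 * 1.5, rel=1e-9)

    def test_null_strain_decouples_from_residents(self, stable_resident_params):
        # zero P row/column except the diagonal: P follows its isolated logistic
        p = stable_resident_params
        a = p.alpha.copy()
        a[PROB, :] = 0.0
        a[:, PROB] = 0.0
        a[PROB, PROB] = -0.022
        k = p.k_grow.copy()
        k[PROB] = 0.5
        coupled = GLVParameters(k, a)
        x0 = CommunityState(np.array([20.0, 5.0, 3.0, 0.0]))
        traj = simulate(coupled, x0, doses=[DoseEvent(0.0, 4.0)], horizon=30.0, eval_times=[10.0, 30.0])
        for t in (10.0, 30.0):
            expected = logistic_solution(0.5, -0.022, 4.0, t)
            assert traj.state_at(t).abundances[PROB] == pytest.approx(expected, rel=1e-6)

    def test_negative_initial_rejected(self):
        with pytest.raises(ValueError):
            CommunityState(np.array([-1.0, 0, 0, 0]))

    def test_agrees_with_fixed_step_rk4_oracle(self, stable_resident_params):
        p = stable_resident_params
        doses = [DoseEvent(float(t), 2.0) for t in range(7)]
        x0 = np.array([15.0, 4.0, 2.0, 0.0])
        traj = simulate(p, CommunityState(x0.copy()), doses=doses, horizon=10.0, eval_times=[10.0])
        # oracle: integrate the dose-free segments with an independent RK4
        x = x0.copy()
        for t in range(7):
            x[PROB] += 2.0
            x = rk4_glv(p.k_grow, p.alpha, x, t, t + 1, h=1e-3)
        x = rk4_glv(p.k_grow, p.alpha, x, 7.0, 10.0, h=1e-3)
        np.testing.assert_allclose(traj.final_state().abundances, x, rtol=1e-4)

    def test_tolerance_refinement_changes_little(self, stable_resident_params):
        p = stable_resident_params
        x0 = CommunityState(np.array([15.0, 4.0, 2.0, 1.0]))
        kw = dict(doses=[DoseEvent(2.0, 3.0)], horizon=50.0, eval_times=[25.0, 50.0])
        a = simulate(p, x0, rtol=1e-6, atol=1e-9, **kw)
        b = simulate(p, x0, rtol=5e-7, atol=5e-10, **kw)
        np.testing.assert_allclose(a.abundances[-1], b.abundances[-1], rtol=1e-5)


class TestSimulateBatch:
    def test_matches_single_trajectory_path(self, stable_resident_params, rng):
        p = stable_resident_params
        doses = [DoseEvent(float(t), 2.0) for t in range(7)]
        windows = [AntibioticWindow(0.0, 5.0, -2.64)]
        evals = [5.0, 12.0, 40.0]
        x0s = rng.uniform(0.5, 20.0, size=(6, 4))
        states, failed = simulate_batch(
            np.tile(p.k_grow, (6, 1)),
            np.tile(p.alpha, (6, 1, 1)),
            x0s,
            doses,
            windows,
            evals,
        )
        assert not failed.any()
        for i in range(6):
            traj = simulate(p, CommunityState(x0s[i].copy()), doses, windows, 40.0, evals)
            for j, t in enumerate(evals):
                np.testing.assert_allclose(
                    states[i, j], traj.state_at(t).abundances, rtol=2e-4, atol=1e-7
                )

    def test_step_refinement_converged(self, stable_resident_params, rng):
        p = stable_resident_params
        x0s = rng.uniform(0.5, 20.0, size=(4, 4))
        kw = dict(doses=[DoseEvent(1.0, 5.0)], eval_times=[30.0])
        a, _ = simulate_batch(np.tile(p.k_grow, (4, 1)), np.tile(p.alpha, (4, 1, 1)), x0s, h=0.01, **kw)
        b, _ = simulate_batch(np.tile(p.k_grow, (4, 1)), np.tile(p.alpha, (4, 1, 1)), x0s, h=0.005, **kw)
        np.testing.assert_allclose(a, b, rtol=1e-6)

    def test_divergent_system_flagged_not_crashed(self):
        # strong mutualism with negligible self-limitation blows up
        k = np.array([[0.5, 0.5, 0.3, 0.0]])
        a = np.zeros((1, 4, 4))
        a[0, 0, 0] = a[0, 1, 1] = -1e-4
        a[0, 0, 1] = a[0, 1, 0] = 0.1
        x0 = np.array([[50.0, 50.0, 1.0, 0.0]])
        states, failed = simulate_batch(k, a, x0, eval_times=[200.0])
        assert failed[0]
        assert np.isnan(states[0]).all()

    def test_nonnegativity(self, stable_resident_params, rng):
        p = stable_resident_params
        x0s = rng.uniform(0.0, 30.0, size=(8, 4))
        states, failed = simulate_batch(
            np.tile(p.k_grow, (8, 1)),
            np.tile(p.alpha, (8, 1, 1)),
            x0s,
            windows=[AntibioticWindow(0.0, 7.0, -3.82)],
            eval_times=[3.0, 7.0, 30.0],
        )
        assert not failed.any()
        assert (states >= 0).all()
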