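"""Path actions, heat, fluctuation estimators and expected free energy."""

import numpy as np
import pytest

from blanketmech import systems, thermo
from blanketmech.errors import UnsupportedConfigurationError
from blanketmech.geometry import sync_map
from blanketmech.mechanics import relax_modes
from blanketmech.simulate import Ensemble, Trajectory, simulate, simulate_ensemble
from blanketmech.synthetic import random_blanket_system, toy_discrete_model
from blanketmech.thermo import (
    DiscreteModel,
    expected_free_energy,
    fluctuation_average,
    heat,
    heat_free_energy,
    heat_temperature,
    path_action,
    path_functionals,
    reverse,
)


def _constant_trajectory(system, x, n_steps=10, dt=0.01):
    states = np.tile(np.atleast_1d(x), (n_steps + 1, 1))
    return Trajectory(dt=dt, times=dt * np.arange(n_steps + 1), states=states,
                      seed=0, system=system)


class TestPathAction:
    def test_constant_path_term_by_term(self, bare2d_solenoidal):
        # independent term-by-term quadrature oracle at a fixed point
        s = bare2d_solenoidal
        x = np.array([0.8, -0.3])
        traj = _constant_trajectory(s, x, n_steps=7, dt=0.02)
        f = s.drift(x)
        per_step = (f @ f + 2.0 * 1.0 * np.trace(s.A)) * 0.02 / 4.0
        assert path_action(s, traj) == pytest.approx(7 * per_step, abs=1e-12)

    def test_drift_following_path_cancels_quadratic_terms(self, bare1d):
        # along x_dot = f the quadratic terms vanish, leaving the divergence
        traj = simulate(bare1d, np.array([1.0]), 1e-3, 100, seed=0, noise=False)
        action = path_action(bare1d, traj)
        # v = f at midpoints only to O(dt); compare against the div-only value
        div_only = 0.5 * np.trace(bare1d.A) * traj.times[-1]
        assert action == pytest.approx(div_only, abs=5e-3)

    def test_refinement_stability(self, bare2d_solenoidal):
        vals = {}
        for dt in (1e-2, 5e-3):
            traj = simulate(bare2d_solenoidal, np.array([1.0, 0.0]),
                            dt, int(1.0 / dt), seed=3, noise=False)
            vals[dt] = path_action(bare2d_solenoidal, traj)
        assert abs(vals[1e-2] - vals[5e-3]) < 0.05

    def test_anisotropic_gamma_rejected(self):
        part = systems.make_partition(0, 0, 0, 2, bare=True)
        s = systems.build_linear_system(np.eye(2) * 2.0, np.zeros((2, 2)),
                                        np.diag([1.0, 2.0]), part, strict=False)
        traj = _constant_trajectory(s, np.zeros(2))
        with pytest.raises(UnsupportedConfigurationError):
            path_action(s, traj)


class TestReversal:
    def test_two_point_swap(self, bare1d):
        traj = Trajectory(dt=0.1, times=np.array([0.0, 0.1]),
                          states=np.array([[0.0], [1.0]]), seed=0, system=bare1d)
        rev = reverse(traj)
        assert rev.states[0, 0] == 1.0 and rev.states[1, 0] == 0.0

    def test_involution_preserves_everything(self, bare2d_solenoidal):
        traj = simulate(bare2d_solenoidal, np.zeros(2), 0.01, 20, seed=1)
        back = reverse(reverse(traj))
        assert np.array_equal(back.states, traj.states)
        assert back.dt == traj.dt and len(back.times) == len(traj.times)


class TestHeat:
    def test_reversal_asymmetry_equals_heat(self, bare2d_solenoidal):
        traj = simulate(bare2d_solenoidal, np.array([0.5, 0.5]), 0.01, 500, seed=2)
        pf = path_functionals(bare2d_solenoidal, traj)
        assert pf.action_reverse - pf.action_forward == pytest.approx(
            pf.heat / 1.0, abs=1e-10
        )

    def test_gradient_system_heat_equals_surprise_drop(self, bare1d):
        # Q = 0, quadratic surprise: the midpoint sum telescopes exactly
        traj = simulate(bare1d, np.array([1.0]), 0.01, 1000, seed=4)
        q = heat(bare1d, traj)
        dI = bare1d.surprise(traj.states[-1]) - bare1d.surprise(traj.states[0])
        assert q == pytest.approx(-1.0 * dI, abs=1e-10)

    def test_deterministic_relaxation_dissipates_initial_energy(self, bare1d):
        # x: 1 -> ~0 under Pi = 2: dissipated heat -> Gamma * I-drop = 1
        traj = simulate(bare1d, np.array([1.0]), 1e-3, 8000, seed=0, noise=False)
        assert heat(bare1d, traj) == pytest.approx(1.0, abs=1e-2)

    def test_constant_path_no_heat(self, bare2d_solenoidal):
        assert heat(bare2d_solenoidal, _constant_trajectory(bare2d_solenoidal, [0.4, 0.1])) == 0.0

    def test_temperature_relabelling(self):
        assert heat_temperature(1.0, 1.0) == pytest.approx(1.0)
        assert heat_temperature(-2.0, 0.5) == pytest.approx(-4.0)
        with pytest.raises(UnsupportedConfigurationError):
            heat_temperature(1.0, -1.0)


class TestHeatFreeEnergy:
    def test_zero_along_trivial_path(self):
        s = random_blanket_system((2, 1, 1, 2), 8, strict=False, isotropic_gamma=True)
        sm = sync_map(s)
        b = np.array([0.5, -0.5])
        mu_b = sm.mu_of_b(b)
        hf = heat_free_energy(s, np.array([mu_b, mu_b]), b, sm)
        assert hf.heat_from_F == pytest.approx(0.0, abs=1e-12)

    def test_two_routes_agree_along_relaxation(self):
        s = random_blanket_system((2, 1, 1, 2), 8, strict=False, isotropic_gamma=True)
        sm = sync_map(s)
        b = np.array([1.0, 0.3])
        mu0 = sm.mu_of_b(b) + np.array([1.0, -0.5])
        mus, Fs = relax_modes(s, b, mu0, 0.05, 500, sm)
        hf = heat_free_energy(s, mus, b, sm)
        assert hf.heat_from_F == pytest.approx(hf.heat_from_surprise, abs=1e-10)
        # downhill relaxation dissipates positive heat
        assert hf.heat_from_F > 0
        assert hf.heat_from_F == pytest.approx(-s.gamma_scalar * (Fs[-1] - Fs[0]), abs=1e-10)


@pytest.fixture
def mild_solenoidal():
    """2-D solenoidal system with moderate circulation: entropy-production
    fluctuations are small enough for tight fluctuation-theorem statistics."""
    part = systems.make_partition(0, 0, 0, 2, bare=True)
    Pi = np.array([[2.0, 0.5], [0.5, 1.5]])
    Q = np.array([[0.0, 0.3], [-0.3, 0.0]])
    return systems.build_linear_system(Pi, Q, np.eye(2), part, strict=False)


class TestFluctuationAverage:
    def test_integral_fluctuation_theorem(self, mild_solenoidal):
        ens = simulate_ensemble(mild_solenoidal, 4000, 2e-3, 250, seed=6)
        est, se = fluctuation_average(mild_solenoidal, ens)
        assert abs(est - 1.0) < 3.0 * se
        assert se < 0.05

    def test_indicator_functional_smoke(self, bare2d_solenoidal):
        ens = simulate_ensemble(bare2d_solenoidal, 8, 1e-2, 50, seed=7)
        est, se = fluctuation_average(
            bare2d_solenoidal, ens, g=lambda s: float(s < 0)  # reversed-heat sign
        )
        assert np.isfinite(est) and se > 0

    def test_refinement_moves_estimate_toward_one(self, mild_solenoidal):
        errs = []
        for dt in (4e-2, 4e-3):
            ens = simulate_ensemble(mild_solenoidal, 2000, dt, int(0.5 / dt), seed=8)
            est, _ = fluctuation_average(mild_solenoidal, ens)
            errs.append(abs(est - 1.0))
        assert errs[1] < errs[0] + 0.01


class TestExpectedFreeEnergy:
    def test_matched_beliefs_have_zero_risk(self):
        m = toy_discrete_model(3, 3, seed=0)
        p_eta = m.p_joint.sum(axis=1)
        matched = DiscreteModel(m.p_joint, m.q_pi, np.tile(p_eta[:, None], (1, 3)))
        assert expected_free_energy(matched).risk == 0.0

    def test_deterministic_mapping_has_zero_ambiguity(self):
        perm = np.eye(3)[[2, 0, 1]] / 3.0
        m = toy_discrete_model(3, 3, seed=1)
        res = expected_free_energy(DiscreteModel(perm, m.q_pi, m.q_eta_given_pi))
        assert res.ambiguity == 0.0

    def test_bound_and_nonnegativity_on_random_models(self):
        for seed in range(10):
            res = expected_free_energy(toy_discrete_model(3, 4, seed))
            assert res.risk >= 0 and res.ambiguity >= 0
            assert res.G_exact >= res.bound - 1e-12

    def test_gap_closes_when_beliefs_match_steady_state(self):
        # q(pi) = p(pi), q(eta|pi) = p(eta|pi): G = H[q(pi)] and the
        # risk+ambiguity decomposition is exact
        m = toy_discrete_model(3, 3, seed=2)
        p = m.p_joint
        q_pi = p.sum(axis=0)
        q_e_p = p / q_pi[None, :]
        res = expected_free_energy(DiscreteModel(p, q_pi, q_e_p))
        assert res.G_exact == pytest.approx(res.bound, abs=1e-12)
        assert res.gap == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_enumeration(self):
        from blanketmech.checks import _efe_bruteforce

        for seed in (3, 4):
            m = toy_discrete_model(3, 3, seed)
            res = expected_free_energy(m)
            G0, r0, a0 = _efe_bruteforce(m)
            assert res.G_exact == pytest.approx(G0, abs=1e-12)
            assert res.risk == pytest.approx(r0, abs=1e-12)
            assert res.ambiguity == pytest.approx(a0, abs=1e-12)

    def test_normalization_enforced(self):
        with pytest.raises(ValueError):
            DiscreteModel(np.ones((2, 2)), np.array([0.5, 0.5]), np.ones((2, 2)) / 2)
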