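"""Partition bookkeeping, system validation and the steady-state identities."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blanketmech import systems
from blanketmech.errors import PartitionError, SystemValidationError
from blanketmech.synthetic import random_blanket_system


class TestPartition:
    def test_canonical_ordering_and_groups(self):
        p = systems.make_partition(1, 1, 1, 1)
        assert p.n == 4
        assert (p.b.start, p.b.stop) == (1, 3)
        assert (p.pi.start, p.pi.stop) == (1, 4)

    def test_sensory_only_blanket_is_valid(self):
        p = systems.make_partition(2, 1, 0, 2)
        assert p.is_blanket and p.n_b == 1

    def test_empty_blanket_rejected(self):
        with pytest.raises(PartitionError):
            systems.make_partition(1, 0, 0, 1)

    def test_bare_flag_allows_degenerate(self):
        p = systems.make_partition(0, 0, 0, 2, bare=True)
        assert not p.is_blanket and p.n == 2

    @given(
        n_eta=st.integers(1, 4), n_s=st.integers(0, 3),
        n_a=st.integers(0, 3), n_mu=st.integers(1, 4),
    )
    @settings(max_examples=50, deadline=None)
    def test_blocks_disjoint_and_cover(self, n_eta, n_s, n_a, n_mu):
        if n_s + n_a == 0:
            n_s = 1
        p = systems.make_partition(n_eta, n_s, n_a, n_mu)
        idx = np.concatenate([np.arange(s.start, s.stop) for s in (p.eta, p.s, p.a, p.mu)])
        assert np.array_equal(idx, np.arange(p.n))


class TestValidation:
    def test_scalar_bare_system(self):
        part = systems.make_partition(0, 0, 0, 1, bare=True)
        sys_ = systems.build_linear_system([[2.0]], [[0.0]], [[1.0]], part, strict=False)
        assert np.allclose(sys_.A, [[-2.0]])

    def test_blanket_condition_violation_named(self):
        part = systems.make_partition(1, 1, 1, 1)
        Pi = np.eye(4) * 2.0
        Pi[0, 3] = Pi[3, 0] = 0.3
        with pytest.raises(SystemValidationError, match="blanket condition violated"):
            systems.build_linear_system(Pi, np.zeros((4, 4)), np.eye(4), part)

    def test_q_coupling_across_blocks_rejected(self):
        # Q coupling the eta and sensory blocks is not block-diagonal
        part = systems.make_partition(1, 1, 0, 1)
        Pi = np.diag([2.0, 3.0, 2.0])
        Q = np.zeros((3, 3))
        Q[0, 1], Q[1, 0] = 1.0, -1.0
        with pytest.raises(SystemValidationError, match="block-diagonal"):
            systems.build_linear_system(Pi, Q, np.eye(3), part)

    def test_strict_zero_blocks_enforced(self):
        part = systems.make_partition(1, 0, 1, 1)
        Pi = np.array([[2.0, 1.0, 0.0], [1.0, 3.0, 1.0], [0.0, 1.0, 2.0]])
        with pytest.raises(SystemValidationError, match="strict"):
            systems.build_linear_system(Pi, np.zeros((3, 3)), np.eye(3), part, strict=True)
        # the same matrix is a valid blanket-level system
        systems.build_linear_system(Pi, np.zeros((3, 3)), np.eye(3), part, strict=False)

    @pytest.mark.parametrize(
        "mutate,match",
        [
            (lambda Pi, Q, G: (Pi + np.diag([0, 0, 0, -10.0]), Q, G), "positive"),
            (lambda Pi, Q, G: (Pi + 0.1 * np.triu(np.ones((4, 4)), 1), Q, G), "symmetry"),
            (lambda Pi, Q, G: (Pi, Q + 0.1 * np.eye(4), G), "skew"),
            (lambda Pi, Q, G: (Pi, Q, -G), "positive"),
        ],
    )
    def test_each_invariant_rejected(self, mutate, match):
        part = systems.make_partition(1, 1, 1, 1)
        Pi = np.diag([2.0, 3.0, 3.0, 2.0])
        args = mutate(Pi, np.zeros((4, 4)), np.eye(4))
        with pytest.raises(SystemValidationError, match=match):
            systems.build_linear_system(*args, part)


class TestDriftAndSurprise:
    def test_scalar_drift(self, bare1d):
        assert systems.drift(bare1d, np.array([0.5]))[0] == pytest.approx(-1.0)

    def test_drift_zero_at_origin(self, blanket6d):
        assert np.allclose(systems.drift(blanket6d, np.zeros(6)), 0.0)

    def test_solenoidal_drift_matches_dense_product(self, bare2d_solenoidal):
        # independent dense matrix-product oracle
        s = bare2d_solenoidal
        rng = np.random.default_rng(0)
        for x in rng.standard_normal((5, 2)):
            expected = (s.Q - s.Gamma) @ s.Pi @ x
            assert np.allclose(systems.drift(s, x), expected, atol=1e-14)

    def test_surprise_closed_form(self, bare1d):
        # N(0, 1/2): -ln p(1) = 1 + ln(pi)/2
        assert systems.surprise(bare1d, np.array([1.0])) == pytest.approx(
            1.0 + 0.5 * np.log(np.pi)
        )

    def test_surprise_minimized_at_origin(self, blanket6d):
        rng = np.random.default_rng(1)
        base = systems.surprise(blanket6d, np.zeros(6))
        for x in rng.standard_normal((10, 6)):
            assert systems.surprise(blanket6d, x) > base

    def test_surprise_difference_is_quadratic_form(self, blanket6d):
        rng = np.random.default_rng(2)
        x0, x1 = rng.standard_normal((2, 6))
        diff = systems.surprise(blanket6d, x1) - systems.surprise(blanket6d, x0)
        expected = 0.5 * (x1 @ blanket6d.Pi @ x1 - x0 @ blanket6d.Pi @ x0)
        assert diff == pytest.approx(expected, abs=1e-12)


class TestStationarity:
    def test_inverse_and_lyapunov_residual(self, bare1d):
        assert systems.stationary_covariance(bare1d)[0, 0] == pytest.approx(0.5)

    def test_against_lyapunov_solver(self):
        # independent oracle: solve the continuous Lyapunov equation directly
        from scipy.linalg import solve_continuous_lyapunov

        s = random_blanket_system((2, 1, 1, 2), 5, strict=True)
        sigma = systems.stationary_covariance(s)
        oracle = solve_continuous_lyapunov(s.A, -2.0 * s.Gamma)
        assert np.allclose(sigma, oracle, atol=1e-9)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_exact_stationarity_property(self, seed):
        s = random_blanket_system((2, 1, 1, 2), seed, strict=True)
        sigma = np.linalg.inv(s.Pi)
        resid = s.A @ sigma + sigma @ s.A.T + 2.0 * s.Gamma
        assert np.max(np.abs(resid)) < 1e-10

    def test_solenoidal_divergence_vanishes_symbolically(self):
        # div(Q grad p) = 0 for constant skew Q and a 2-D Gaussian p
        import sympy as sp

        x, y = sp.symbols("x y")
        q = sp.Symbol("q")
        a, b, c = sp.symbols("a b c")
        I_ = (a * x**2 + 2 * b * x * y + c * y**2) / 2
        p = sp.exp(-I_)
        grad = [sp.diff(p, x), sp.diff(p, y)]
        Q = [[0, q], [-q, 0]]
        flux = [Q[i][0] * grad[0] + Q[i][1] * grad[1] for i in range(2)]
        div = sp.simplify(sp.diff(flux[0], x) + sp.diff(flux[1], y))
        assert div == 0

    def test_blanket_zero_block_gives_conditional_independence(self, blanket6d):
        # dense Gaussian conditioning: cov of (eta, mu) given b is block-diagonal
        p = blanket6d.partition
        Sigma = blanket6d.stationary_covariance()
        idx_em = np.r_[np.arange(0, p.n_eta), np.arange(p.mu.start, p.mu.stop)]
        idx_b = np.arange(p.b.start, p.b.stop)
        S_em = Sigma[np.ix_(idx_em, idx_em)]
        S_eb = Sigma[np.ix_(idx_em, idx_b)]
        S_bb = Sigma[np.ix_(idx_b, idx_b)]
        cond = S_em - S_eb @ np.linalg.solve(S_bb, S_eb.T)
        cross = cond[: p.n_eta, p.n_eta:]
        assert np.max(np.abs(cross)) < 1e-12


class TestNonlinear:
    def test_gradient_contract_checked(self):
        part = systems.make_partition(0, 0, 0, 1, bare=True)
        with pytest.raises(SystemValidationError, match="gradient contract"):
            systems.build_nonlinear_system(
                lambda x: float(x[0] ** 2),
                lambda x: np.array([3.0 * x[0]]),  # wrong gradient
                np.zeros((1, 1)), np.eye(1), part,
            )

    def test_quartic_drift_and_divergence(self):
        part = systems.make_partition(0, 0, 0, 1, bare=True)
        s = systems.build_nonlinear_system(
            lambda x: float(x[0] ** 4 / 4 + x[0] ** 2 / 2),
            lambda x: np.array([x[0] ** 3 + x[0]]),
            np.zeros((1, 1)), np.eye(1), part,
        )
        x = np.array([0.7])
        assert s.drift(x)[0] == pytest.approx(-(0.7**3 + 0.7))
        assert s.div_drift(x) == pytest.approx(-(3 * 0.7**2 + 1), rel=1e-6)


class TestRoundTrip:
    def test_json_round_trip_lossless(self, blanket6d):
        d = json.loads(systems.system_to_json(blanket6d))
        back = systems.system_from_dict(d)
        assert np.array_equal(back.Pi, blanket6d.Pi)
        assert np.array_equal(back.Q, blanket6d.Q)
        assert np.array_equal(back.Gamma, blanket6d.Gamma)
        assert back.content_hash() == blanket6d.content_hash()

    def test_save_load(self, tmp_path, strict6d):
        path = tmp_path / "sys.json"
        systems.save_system(strict6d, path)
        back = systems.load_system(path)
        assert back.strict and np.array_equal(back.Pi, strict6d.Pi)
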