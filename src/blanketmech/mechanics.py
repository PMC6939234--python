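"""Bayesian mechanics: free energy, gradient flows and prediction errors.

Variational free energy of an internal state mu and blanket state b:

    F(mu, b) = I(b) + KL[q_mu(eta) || p(eta|b)]
             = E_q[I(eta, b)] + E_q[ln q_mu(eta)],

an upper bound on the blanket surprise I(b), tight exactly at mu = mu(b)
(the Laplace belief is exact in the linear-Gaussian class).  The expected
flow of the internal mode is a gradient flow on F,

    mu_dot(b) = -Gamma_ss grad_mu F(mu, b),
    Gamma_ss  = J^+ Gamma[eta,eta] (J^+)^T,     J = grad_mu sigma,

(the symmetrized assembly makes Gamma_ss PSD; it reduces to the scalar form
in one dimension), and active states descend the same free energy:

    a_dot = (Q_aa - Gamma_aa) grad_a I(sigma(mu), b)
          = (Q_aa - Gamma_aa) grad_a F(mu, b),

the two gradients being equal in the linear class because the curvature
terms of F are constant in the mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import StabilityError, SystemValidationError
from .geometry import SyncMap, sync_map
from .systems import LinearBlanketSystem

_EQ_ATOL = 1e-10


@dataclass
class FreeEnergyReport:
    """Free energy and its two decompositions (all in nats)."""

    F: float
    blanket_surprise: float
    kl: float
    energy: float
    neg_entropy: float
    method: str = "exact-gaussian"

    @property
    def bound_gap(self) -> float:
        """F - I(b) = KL >= 0."""
        return self.F - self.blanket_surprise


@dataclass
class FlowReport:
    mu_dot: np.ndarray
    Gamma_ss: np.ndarray
    grad_mu_F: np.ndarray
    grad_mu_surprise: np.ndarray
    a_dot: np.ndarray | None = None
    grad_a_F: np.ndarray | None = None


@dataclass
class PredictionErrors:
    """Prediction errors of the quadratic (predictive-coding) reading of the
    joint surprise: eps_eta is the discrepancy between the belief mean and
    the prior mode of eta; eps_b between the observed blanket state and the
    one predicted from the belief."""

    eps_b: np.ndarray
    eps_eta: np.ndarray


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------


def _marginal_eb(system: LinearBlanketSystem):
    """Covariance and precision of the (eta, b) marginal, plus slices."""
    p = system.partition
    Sigma = system.stationary_covariance()
    idx = np.r_[np.arange(p.eta.start, p.eta.stop), np.arange(p.b.start, p.b.stop)]
    S = Sigma[np.ix_(idx, idx)]
    P = np.linalg.inv(S)
    P = 0.5 * (P + P.T)
    ne = p.n_eta
    return S, P, slice(0, ne), slice(ne, ne + p.n_b)


def joint_surprise_eta_b(system: LinearBlanketSystem, eta: np.ndarray, b: np.ndarray) -> float:
    """I(eta, b): surprise of the (eta, b) marginal of the NESS density."""
    S, P, se, sb = _marginal_eb(system)
    z = np.concatenate([np.atleast_1d(eta), np.atleast_1d(b)]).astype(float)
    _, logdet_S = np.linalg.slogdet(S)
    k = z.size
    return float(0.5 * z @ P @ z + 0.5 * (k * np.log(2 * np.pi) + logdet_S))


def blanket_surprise(system: LinearBlanketSystem, b: np.ndarray) -> float:
    """I(b): surprise of the blanket marginal."""
    p = system.partition
    Sigma = system.stationary_covariance()
    Sbb = Sigma[p.b, p.b]
    b = np.atleast_1d(np.asarray(b, dtype=float))
    _, logdet = np.linalg.slogdet(Sbb)
    return float(
        0.5 * b @ np.linalg.solve(Sbb, b) + 0.5 * (p.n_b * np.log(2 * np.pi) + logdet)
    )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def free_energy(
    system: LinearBlanketSystem,
    mu: np.ndarray,
    b: np.ndarray,
    smap: SyncMap | None = None,
) -> FreeEnergyReport:
    """Compute F(mu, b) by both decompositions (closed-form Gaussian
    expectations) and assert their agreement."""
    if smap is None:
        smap = sync_map(system)
    p = system.partition
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    Pi_ee = system.Pi[p.eta, p.eta]
    mean_q = smap(mu)
    eta_b = smap.eta_of_b(b)

    Ib = blanket_surprise(system, b)
    d = mean_q - eta_b
    kl = float(0.5 * d @ Pi_ee @ d)  # equal covariances: only the mean term
    F = Ib + kl

    # Independent route: energy minus entropy with q = N(sigma(mu), Pi_ee^{-1}).
    cov_q = np.linalg.inv(Pi_ee)
    energy = joint_surprise_eta_b(system, mean_q, b) + 0.5 * float(
        np.trace(Pi_ee @ cov_q)
    )
    _, logdet_cov = np.linalg.slogdet(cov_q)
    neg_entropy = -0.5 * (p.n_eta * np.log(2 * np.pi * np.e) + logdet_cov)
    F_alt = energy + neg_entropy
    assert abs(F - F_alt) < 1e-8 * max(1.0, abs(F)), "free-energy decompositions disagree"
    return FreeEnergyReport(
        F=F, blanket_surprise=Ib, kl=kl, energy=energy, neg_entropy=neg_entropy
    )


def grad_mu_free_energy(
    system: LinearBlanketSystem, mu, b, smap: SyncMap | None = None
) -> np.ndarray:
    """grad_mu F(mu, b) = J^T Pi[eta,eta] (sigma(mu) - eta(b))."""
    if smap is None:
        smap = sync_map(system)
    p = system.partition
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    J = smap.jacobian
    return J.T @ system.Pi[p.eta, p.eta] @ (smap(mu) - smap.eta_of_b(b))


def grad_mu_surprise(
    system: LinearBlanketSystem, mu, b, smap: SyncMap | None = None
) -> np.ndarray:
    """grad_mu I(sigma(mu), b) via the chain rule through sigma,
    J^T grad_eta I(eta, b) at eta = sigma(mu)."""
    if smap is None:
        smap = sync_map(system)
    p = system.partition
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    _, P, se, sb = _marginal_eb(system)
    z = np.concatenate([smap(mu), b])
    grad_eta = (P @ z)[se]
    return smap.jacobian.T @ grad_eta


def internal_flow(
    system: LinearBlanketSystem,
    mu: np.ndarray,
    b: np.ndarray,
    smap: SyncMap | None = None,
) -> FlowReport:
    """Expected internal-mode velocity mu_dot = -Gamma_ss grad_mu F(mu, b).

    Both gradient routes (through the joint surprise and through F) are
    computed and asserted equal; the flow vanishes at mu = mu(b).
    """
    if smap is None:
        smap = sync_map(system)
    p = system.partition
    Jp = smap.jacobian_pinv
    Gamma_ee = system.Gamma[p.eta, p.eta]
    Gamma_ss = Jp @ Gamma_ee @ Jp.T
    gF = grad_mu_free_energy(system, mu, b, smap)
    gI = grad_mu_surprise(system, mu, b, smap)
    assert np.allclose(gF, gI, atol=_EQ_ATOL * max(1.0, float(np.max(np.abs(gF)))))
    mu_dot = -Gamma_ss @ gF
    rep = FlowReport(mu_dot=mu_dot, Gamma_ss=Gamma_ss, grad_mu_F=gF, grad_mu_surprise=gI)
    if p.n_a >= 1:
        rep.a_dot = active_flow(system, mu, b, smap)
        rep.grad_a_F = _grad_a_free_energy(system, mu, b, smap)
    return rep


def internal_flow_via_external(
    system: LinearBlanketSystem,
    mu: np.ndarray,
    b: np.ndarray,
    smap: SyncMap | None = None,
) -> np.ndarray:
    """The intermediate (solenoidal-bearing) route: push the external-state
    gradient flow (Q_ee - Gamma_ee) grad_eta I through the pseudoinverse
    Jacobian.  Coincides with :func:`internal_flow` when Q_ee = 0 and the
    sigma Jacobian is square and invertible."""
    if smap is None:
        smap = sync_map(system)
    p = system.partition
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    _, P, se, sb = _marginal_eb(system)
    z = np.concatenate([smap(mu), b])
    grad_eta = (P @ z)[se]
    Q_ee = system.Q[p.eta, p.eta]
    Gamma_ee = system.Gamma[p.eta, p.eta]
    eta_dot = (Q_ee - Gamma_ee) @ grad_eta
    return smap.jacobian_pinv @ eta_dot


def _grad_a_free_energy(system, mu, b, smap) -> np.ndarray:
    """a-component of grad_b F(mu, b)."""
    p = system.partition
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    Sigma = system.stationary_covariance()
    Sbb = Sigma[p.b, p.b]
    d = smap(mu) - smap.eta_of_b(b)
    grad_b = np.linalg.solve(Sbb, b) - smap.K_eta.T @ system.Pi[p.eta, p.eta] @ d
    return grad_b[p.n_s:]


def active_flow(
    system: LinearBlanketSystem,
    mu: np.ndarray,
    b: np.ndarray,
    smap: SyncMap | None = None,
) -> np.ndarray:
    """a_dot = (Q_aa - Gamma_aa) grad_a I(sigma(mu), b).

    The gradient is taken through the joint surprise of (eta, b) at
    eta = sigma(mu); it equals grad_a F(mu, b) exactly in the linear class
    (asserted).  Requires at least one active state.
    """
    p = system.partition
    if p.n_a < 1:
        raise SystemValidationError("no active states", "active_flow needs n_a >= 1")
    if smap is None:
        smap = sync_map(system)
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    _, P, se, sb = _marginal_eb(system)
    z = np.concatenate([smap(mu), b])
    grad_b = (P @ z)[sb]
    grad_a = grad_b[p.n_s:]
    gaF = _grad_a_free_energy(system, mu, b, smap)
    assert np.allclose(grad_a, gaF, atol=_EQ_ATOL * max(1.0, float(np.max(np.abs(grad_a)))))
    Q_aa = system.Q[p.a, p.a]
    Gamma_aa = system.Gamma[p.a, p.a]
    return (Q_aa - Gamma_aa) @ grad_a


def prediction_errors(
    system: LinearBlanketSystem,
    mu: np.ndarray,
    b: np.ndarray,
    smap: SyncMap | None = None,
) -> PredictionErrors:
    """eps_eta = sigma(mu) - 0 (prior mode of eta is zero);
    eps_b = b - E[b | eta = sigma(mu)].

    The precision-weighted squares of these errors regroup the joint
    surprise: I(sigma(mu), b) = const + 1/2 eps_eta' S_ee^{-1} eps_eta
    + 1/2 eps_b' P_bb eps_b, with S_ee the marginal covariance of eta and
    P_bb the conditional precision of b given eta.
    """
    if smap is None:
        smap = sync_map(system)
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    S, P, se, sb = _marginal_eb(system)
    eta = smap(mu)
    P_bb = P[sb, sb]
    P_be = P[sb, se]
    b_pred = -np.linalg.solve(P_bb, P_be @ eta)
    return PredictionErrors(eps_b=b - b_pred, eps_eta=eta)


def relax_modes(
    system: LinearBlanketSystem,
    b: np.ndarray,
    mu0: np.ndarray,
    step: float,
    n_steps: int,
    smap: SyncMap | None = None,
):
    """Deterministic Euler integration of the internal-mode gradient flow at
    fixed blanket state, returning (mu path, F path).

    The step is pre-checked against the stability bound
    step < 2 / lambda_max(Gamma_ss H), H = J^T Pi[eta,eta] J, which for the
    quadratic F is exact; along the accepted path F is monotone
    non-increasing and converges to its lower bound I(b).
    """
    if smap is None:
        smap = sync_map(system)
    p = system.partition
    b = np.atleast_1d(np.asarray(b, dtype=float))
    mu = np.atleast_1d(np.asarray(mu0, dtype=float)).copy()
    J = smap.jacobian
    H = J.T @ system.Pi[p.eta, p.eta] @ J
    Jp = smap.jacobian_pinv
    Gamma_ss = Jp @ system.Gamma[p.eta, p.eta] @ Jp.T
    lam = np.max(np.abs(np.linalg.eigvals(Gamma_ss @ H).real))
    if lam > 0 and step >= 2.0 / lam:
        raise StabilityError(
            f"step {step} exceeds stability limit {2.0 / lam:.3g} for this system"
        )
    mus = np.empty((n_steps + 1, p.n_mu))
    Fs = np.empty(n_steps + 1)
    # Precompute the pieces of F that do not change along the path.
    Ib = blanket_surprise(system, b)
    eta_b = smap.eta_of_b(b)
    Pi_ee = system.Pi[p.eta, p.eta]
    for k in range(n_steps + 1):
        mus[k] = mu
        d = smap(mu) - eta_b
        Fs[k] = Ib + 0.5 * d @ Pi_ee @ d
        if k < n_steps:
            mu = mu - step * (Gamma_ss @ (J.T @ (Pi_ee @ d)))
    return mus, Fs
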