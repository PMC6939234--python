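"""Conditional structure and information geometry of a Markov blanket.

Given a blanket system, every blanket state b picks out a most likely
external state eta(b) and internal state mu(b) (conditional modes, which for
Gaussians coincide with conditional means).  The synchronization map sigma
sends internal modes to external modes, sigma(mu(b)) = eta(b); under the
Laplace assumption each internal mode parametrizes a Gaussian belief
q_mu(eta) = N(sigma(mu), Pi[eta,eta]^{-1}) over external states, which in the
linear-Gaussian class equals the exact conditional p(eta|b) at mu = mu(b).

The Fisher information metric is computed as the numerical Hessian of the
KL divergence at zero displacement; information length is the path length it
induces on a parameter path.  The blanket therefore carries a dual geometry:
a metric g_lambda on densities over internal states and a metric g_mu that
treats internal states as coordinates for beliefs about external states.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .errors import RankError, SystemValidationError
from .systems import LinearBlanketSystem

_RANK_TOL = 1e-10


def _require_blanket(system: LinearBlanketSystem):
    if not system.partition.is_blanket:
        raise SystemValidationError(
            "blanket required", "operation needs a blanket-partitioned system"
        )


# ---------------------------------------------------------------------------
# Conditional modes and the synchronization map
# ---------------------------------------------------------------------------


class ConditionalModes(NamedTuple):
    eta_mode: np.ndarray
    mu_mode: np.ndarray
    eta_cond_cov: np.ndarray
    mu_cond_cov: np.ndarray


def conditional_modes(system: LinearBlanketSystem, b: np.ndarray) -> ConditionalModes:
    """Gaussian conditional modes and covariances of eta|b and mu|b.

    Because Pi[eta, mu] = 0, conditioning eta on (b, mu) reduces to
    conditioning on b alone: the conditional precision of eta|b is the
    (eta, eta) block of Pi, and the mode is affine in b.  Conditional
    covariances do not depend on b (Gaussian property).
    """
    _require_blanket(system)
    p = system.partition
    b = np.atleast_1d(np.asarray(b, dtype=float))
    if b.shape != (p.n_b,):
        raise ValueError(f"b has shape {b.shape}, blanket dimension is {p.n_b}")
    Pi = system.Pi
    eta_cov = np.linalg.inv(Pi[p.eta, p.eta])
    mu_cov = np.linalg.inv(Pi[p.mu, p.mu])
    eta_mode = -eta_cov @ Pi[p.eta, p.b] @ b
    mu_mode = -mu_cov @ Pi[p.mu, p.b] @ b
    return ConditionalModes(eta_mode, mu_mode, eta_cov, mu_cov)


@dataclass
class SyncMap:
    """Affine mode maps b -> mu(b), b -> eta(b) and the composed
    synchronization map sigma = K_eta K_mu^+ (Moore-Penrose pseudoinverse).

    Off the internal-mode manifold, sigma projects onto it in the
    least-squares sense implied by the pseudoinverse.
    """

    K_eta: np.ndarray
    K_mu: np.ndarray
    K_mu_pinv: np.ndarray
    sigma_matrix: np.ndarray
    rcond: float

    @property
    def jacobian(self) -> np.ndarray:
        """grad_mu sigma (constant in the linear class)."""
        return self.sigma_matrix

    @property
    def jacobian_pinv(self) -> np.ndarray:
        return np.linalg.pinv(self.sigma_matrix, rcond=self.rcond)

    def mu_of_b(self, b: np.ndarray) -> np.ndarray:
        return self.K_mu @ np.atleast_1d(np.asarray(b, dtype=float))

    def eta_of_b(self, b: np.ndarray) -> np.ndarray:
        return self.K_eta @ np.atleast_1d(np.asarray(b, dtype=float))

    def __call__(self, mu: np.ndarray) -> np.ndarray:
        return self.sigma_matrix @ np.atleast_1d(np.asarray(mu, dtype=float))


def sync_map(system: LinearBlanketSystem, rcond: float = _RANK_TOL) -> SyncMap:
    """Build the synchronization map of a blanket system.

    Raises
    ------
    RankError
        If b -> mu(b) is not injective (rank of K_mu below the blanket
        dimension).  Injectivity is the sufficient condition for
        eta(b) = sigma(mu(b)) to be well defined; note that generic *strict*
        systems (Pi[a,eta] = Pi[s,mu] = 0 with n_s, n_a >= 1) violate it
        structurally, because mu(b) then depends on active states only while
        eta(b) depends on sensory states only (see docs/methods.md).
    """
    _require_blanket(system)
    p = system.partition
    Pi = system.Pi
    K_eta = -np.linalg.solve(Pi[p.eta, p.eta], Pi[p.eta, p.b])
    K_mu = -np.linalg.solve(Pi[p.mu, p.mu], Pi[p.mu, p.b])
    svals = np.linalg.svd(K_mu, compute_uv=False)
    rank = int(np.sum(svals > max(rcond, 1e-13) * max(svals[0], 1.0)))
    if rank < p.n_b:
        raise RankError(
            "b -> mu(b) is not injective "
            f"(rank {rank} < blanket dimension {p.n_b}); a sufficient condition "
            "for the synchronization map is that this mapping is injective"
        )
    K_mu_pinv = np.linalg.pinv(K_mu, rcond=rcond)
    sigma = K_eta @ K_mu_pinv
    return SyncMap(K_eta=K_eta, K_mu=K_mu, K_mu_pinv=K_mu_pinv,
                   sigma_matrix=sigma, rcond=rcond)


# ---------------------------------------------------------------------------
# Laplace-encoded beliefs
# ---------------------------------------------------------------------------


@dataclass
class GaussianBelief:
    """A Laplace-encoded density over external states: N(mean, cov)."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ValueError("covariance shape does not match mean")
        eigs = np.linalg.eigvalsh(0.5 * (self.cov + self.cov.T))
        if eigs.min() <= 0:
            raise ValueError("belief covariance must be positive definite")


def gaussian_kl(q: GaussianBelief, p: GaussianBelief) -> float:
    """KL[q || p] between Gaussian beliefs (nats)."""
    k = q.mean.size
    Pinv = np.linalg.inv(p.cov)
    d = p.mean - q.mean
    _, ld_p = np.linalg.slogdet(p.cov)
    _, ld_q = np.linalg.slogdet(q.cov)
    return 0.5 * (np.trace(Pinv @ q.cov) + d @ Pinv @ d - k + ld_p - ld_q)


def laplace_belief(system: LinearBlanketSystem, mu: np.ndarray,
                   smap: SyncMap | None = None) -> GaussianBelief:
    """Belief q_mu(eta) = N(sigma(mu), Pi[eta,eta]^{-1}).

    The precision is the eta-block curvature of the surprise, constant in the
    linear class, so the covariance does not depend on mu.
    """
    if smap is None:
        smap = sync_map(system)
    p = system.partition
    cov = np.linalg.inv(system.Pi[p.eta, p.eta])
    return GaussianBelief(mean=smap(mu), cov=cov)


def exact_conditional(system: LinearBlanketSystem, b: np.ndarray) -> GaussianBelief:
    """The exact conditional p(eta | b) as a GaussianBelief."""
    modes = conditional_modes(system, b)
    return GaussianBelief(mean=modes.eta_mode, cov=modes.eta_cond_cov)


# ---------------------------------------------------------------------------
# Belief families and Fisher metrics
# ---------------------------------------------------------------------------


class BeliefFamily(ABC):
    """A parametrized family of normalized densities with a KL oracle.

    The Fisher metric is obtained *numerically* as the Hessian of the KL
    divergence at zero displacement; closed-form Fisher informations live in
    the test suite as independent oracles.
    """

    @property
    @abstractmethod
    def dim(self) -> int:
        """Number of free parameters."""

    @abstractmethod
    def kl(self, theta_ref: np.ndarray, theta: np.ndarray) -> float:
        """KL[q_{theta_ref} || q_theta]."""


class GaussianMeanFamily(BeliefFamily):
    """Gaussians with frozen covariance, parametrized by the mean."""

    def __init__(self, cov: np.ndarray | float):
        cov = np.atleast_2d(np.asarray(cov, dtype=float))
        self._belief = lambda m: GaussianBelief(np.atleast_1d(m), cov)
        self.cov = cov

    @property
    def dim(self) -> int:
        return self.cov.shape[0]

    def kl(self, theta_ref, theta) -> float:
        return gaussian_kl(self._belief(theta_ref), self._belief(theta))


class DiscreteLogitFamily(BeliefFamily):
    """Densities on k outcomes in logit coordinates.

    theta in R^{k-1}; probabilities are softmax of (0, theta_1, ..).  For
    k = 2 this is the Bernoulli family in its natural parametrization.
    """

    def __init__(self, k: int):
        if k < 2:
            raise ValueError("need at least 2 outcomes")
        self.k = k

    @property
    def dim(self) -> int:
        return self.k - 1

    def probs(self, theta: np.ndarray) -> np.ndarray:
        z = np.concatenate([[0.0], np.atleast_1d(np.asarray(theta, dtype=float))])
        z = z - z.max()
        e = np.exp(z)
        return e / e.sum()

    def kl(self, theta_ref, theta) -> float:
        p = self.probs(theta_ref)
        q = self.probs(theta)
        if np.any(q <= 0):
            raise ValueError("support mismatch: zero probability in reference")
        return float(np.sum(p * (np.log(p) - np.log(q))))


def fisher_metric(family: BeliefFamily, theta: np.ndarray,
                  step: float = 1e-4) -> np.ndarray:
    """Fisher metric g(theta): central-difference Hessian of
    KL[q_theta || q_{theta + u}] at u = 0, symmetrized.

    The step for coordinate i is ``step * (1 + |theta_i|)``.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    d = family.dim
    if theta.shape != (d,):
        raise ValueError(f"theta has shape {theta.shape}, family dimension is {d}")
    h = step * (1.0 + np.abs(theta))
    G = np.empty((d, d))

    def f(u):
        return family.kl(theta, theta + u)

    f0 = f(np.zeros(d))
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h[i]
        G[i, i] = (f(ei) + f(-ei) - 2.0 * f0) / h[i] ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h[j]
            G[i, j] = G[j, i] = (
                f(ei + ej) - f(ei - ej) - f(-ei + ej) + f(-ei - ej)
            ) / (4.0 * h[i] * h[j])
    return 0.5 * (G + G.T)


def information_length(
    family: BeliefFamily,
    theta_path: Sequence[np.ndarray],
    tol: float = 1e-8,
    max_doublings: int = 10,
) -> float:
    """Length of a parameter path under the Fisher metric.

    Each segment contributes sqrt(d theta . g(theta_mid) . d theta); segments
    are subdivided (with midpoint metric evaluation) until the total length
    changes by less than ``tol``.
    """
    pts = [np.atleast_1d(np.asarray(t, dtype=float)) for t in theta_path]
    if len(pts) < 2:
        raise ValueError("path needs at least 2 points")

    def length(subdiv: int) -> float:
        total = 0.0
        for p0, p1 in zip(pts[:-1], pts[1:]):
            for k in range(subdiv):
                a = p0 + (p1 - p0) * k / subdiv
                bb = p0 + (p1 - p0) * (k + 1) / subdiv
                mid = 0.5 * (a + bb)
                g = fisher_metric(family, mid)
                d = bb - a
                total += float(np.sqrt(max(d @ g @ d, 0.0)))
        return total

    prev = length(1)
    subdiv = 2
    for _ in range(max_doublings):
        cur = length(subdiv)
        if abs(cur - prev) < tol:
            return cur
        prev = cur
        subdiv *= 2
    return prev


def dual_metrics(system: LinearBlanketSystem, b: np.ndarray | None = None,
                 smap: SyncMap | None = None):
    """The two metric tensors induced by the blanket.

    g_lambda: Fisher metric of p(mu | b) in its mean parametrization -- the
    conditional precision Pi[mu, mu] (constant in b for the linear class;
    the ``b`` argument is kept for interface uniformity).

    g_mu: metric on internal-mode space pulled back from beliefs over eta
    through sigma: J_sigma^T Pi[eta, eta] J_sigma.
    """
    _require_blanket(system)
    if smap is None:
        smap = sync_map(system)
    p = system.partition
    g_lambda = system.Pi[p.mu, p.mu].copy()
    J = smap.jacobian
    g_mu = J.T @ system.Pi[p.eta, p.eta] @ J
    return g_lambda, g_mu
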