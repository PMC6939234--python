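"""Synthetic fixtures: the affine-conditional dataset, random valid blanket
systems and discrete toy models.

The affine-conditional dataset emulates a minimal blanket construction: a
one-dimensional blanket state drawn from a standard normal, and 2-D internal
and external states drawn from conditional bivariate normals whose means are
affine in b and whose covariances are modulated affinely through their
Cholesky factors (a literal affine covariance map loses positive
definiteness for large |b|, so the modulation acts on the factor and every
realized covariance is validated).  The (mu(b), eta(b)) conditional means
then lie on a 1-D statistical manifold embedded in the 2-D state spaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SystemValidationError
from .systems import LinearBlanketSystem, Partition, build_linear_system, make_partition
from .thermo import DiscreteModel


# ---------------------------------------------------------------------------
# Figure-style affine-conditional dataset
# ---------------------------------------------------------------------------


def _default_params() -> dict:
    return {
        # conditional mean of eta|b and mu|b: column @ [b] + offset
        "A_eta": np.array([0.8, -0.5]),
        "c_eta": np.zeros(2),
        "A_mu": np.array([-0.6, 0.4]),
        "c_mu": np.zeros(2),
        # Cholesky factor L(b) = L0 + b * L1 of the conditional covariance
        "L0_eta": 0.35 * np.eye(2),
        "L1_eta": 0.05 * np.array([[1.0, 0.0], [0.5, 1.0]]),
        "L0_mu": 0.30 * np.eye(2),
        "L1_mu": 0.04 * np.array([[1.0, 0.0], [-0.5, 1.0]]),
    }


@dataclass
class Figure2Dataset:
    """Samples (b, eta, mu) with their exact conditional moments."""

    b: np.ndarray
    eta: np.ndarray
    mu: np.ndarray
    eta_means: np.ndarray
    mu_means: np.ndarray
    eta_covs: np.ndarray
    mu_covs: np.ndarray
    params: dict = field(repr=False)
    seed: int = 0

    @property
    def n(self) -> int:
        return len(self.b)


def _conditional(params, prefix, b):
    mean = params[f"A_{prefix}"] * b + params[f"c_{prefix}"]
    L = params[f"L0_{prefix}"] + b * params[f"L1_{prefix}"]
    # A Cholesky factor with non-positive diagonal means the affine
    # modulation has degenerated (the covariance is singular or the factor
    # has flipped orientation): the realized covariance is no longer a
    # PD, monotone function of b.
    if np.min(np.diag(L)) <= 1e-6:
        raise SystemValidationError(
            "conditional covariance not PD",
            f"covariance modulation degenerates at b = {b:.4g}",
        )
    return mean, L, L @ L.T


def figure2_dataset(n: int, seed: int, params: dict | None = None) -> Figure2Dataset:
    """Generate the affine-conditional blanket dataset.

    b is standard normal; eta|b and mu|b are bivariate normal with affine
    means and Cholesky-modulated covariances, each validated per sample.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p = dict(_default_params())
    if params:
        p.update({k: np.asarray(v, dtype=float) for k, v in params.items()})
    rng = np.random.default_rng(seed)
    b = rng.standard_normal(n)
    eta = np.empty((n, 2))
    mu = np.empty((n, 2))
    eta_means = np.empty((n, 2))
    mu_means = np.empty((n, 2))
    eta_covs = np.empty((n, 2, 2))
    mu_covs = np.empty((n, 2, 2))
    for i, bi in enumerate(b):
        m_e, L_e, C_e = _conditional(p, "eta", bi)
        m_m, L_m, C_m = _conditional(p, "mu", bi)
        eta[i] = m_e + L_e @ rng.standard_normal(2)
        mu[i] = m_m + L_m @ rng.standard_normal(2)
        eta_means[i], eta_covs[i] = m_e, C_e
        mu_means[i], mu_covs[i] = m_m, C_m
    return Figure2Dataset(
        b=b, eta=eta, mu=mu,
        eta_means=eta_means, mu_means=mu_means,
        eta_covs=eta_covs, mu_covs=mu_covs,
        params=p, seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Random valid blanket systems
# ---------------------------------------------------------------------------


def _random_spd(rng, n: int, ridge: float = 0.5) -> np.ndarray:
    W = rng.standard_normal((n, n))
    return W @ W.T / n + ridge * np.eye(n)


def _random_skew(rng, n: int, scale: float = 0.5) -> np.ndarray:
    B = rng.standard_normal((n, n))
    return scale * 0.5 * (B - B.T)


def random_blanket_system(
    dims: tuple[int, int, int, int],
    seed: int,
    strict: bool = True,
    *,
    isotropic_gamma: bool = False,
    off_block_scale: float = 0.35,
    max_ridge_attempts: int = 60,
) -> LinearBlanketSystem:
    """Draw a random valid blanket system (project-then-repair).

    A random PD precision has its forbidden blocks zeroed (always Pi[eta,mu];
    for strict systems also Pi[a,eta] and Pi[s,mu]); ridge is added until the
    result is PD again.  Q is random skew within each (eta, b, mu) block;
    Gamma is random positive diagonal (or a random scalar times identity when
    ``isotropic_gamma``).  The result always passes build_linear_system.
    """
    part = make_partition(*dims)
    n = part.n
    rng = np.random.default_rng(seed)
    Pi = _random_spd(rng, n)
    off = np.ones((n, n)) * off_block_scale
    off[np.diag_indices(n)] = 1.0
    Pi = Pi * off
    Pi = 0.5 * (Pi + Pi.T)

    def zero(block_a, block_b):
        Pi[block_a, block_b] = 0.0
        Pi[block_b, block_a] = 0.0

    zero(part.eta, part.mu)
    if strict:
        zero(part.a, part.eta)
        zero(part.s, part.mu)

    attempts = 0
    while np.min(np.linalg.eigvalsh(Pi)) < 0.05:
        Pi = Pi + 0.1 * np.eye(n)
        attempts += 1
        if attempts > max_ridge_attempts:
            raise SystemValidationError(
                "repair failure", "could not restore positive definiteness by ridging"
            )

    Q = np.zeros((n, n))
    for blk in part.coarse_blocks():
        m = blk.stop - blk.start
        if m > 1:
            Q[blk, blk] = _random_skew(rng, m)

    if isotropic_gamma:
        Gamma = float(rng.uniform(0.5, 1.5)) * np.eye(n)
    else:
        Gamma = np.diag(rng.uniform(0.5, 1.5, size=n))

    return build_linear_system(Pi, Q, Gamma, part, strict=strict)


# ---------------------------------------------------------------------------
# Discrete toy models
# ---------------------------------------------------------------------------


def toy_discrete_model(n_eta: int, n_pi: int, seed: int) -> DiscreteModel:
    """Random normalized joint and predictive tables with all cells positive."""
    if n_eta < 2 or n_pi < 2:
        raise ValueError("toy model needs at least 2 outcomes per variable")
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 1.0, size=(n_eta, n_pi))
    p /= p.sum()
    q_pi = rng.uniform(0.1, 1.0, size=n_pi)
    q_pi /= q_pi.sum()
    q_e_p = rng.uniform(0.1, 1.0, size=(n_eta, n_pi))
    q_e_p /= q_e_p.sum(axis=0, keepdims=True)
    return DiscreteModel(p_joint=p, q_pi=q_pi, q_eta_given_pi=q_e_p)
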