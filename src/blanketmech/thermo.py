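"""Stochastic thermodynamics at the level of paths.

The (Stratonovich) path action of a trajectory x[0..T] under drift f and
isotropic fluctuation amplitude Gamma is discretized with midpoint
evaluation and forward-difference velocities:

    action = sum_k  dt/(4 Gamma) [ v.v - 2 v.f + f.f + 2 Gamma div f ]_mid,
    v = (x_{k+1} - x_k)/dt,  mid = (x_k + x_{k+1})/2.

Heat is the Stratonovich work of the drift along the path,
q = sum_k dx_k . f(mid_k), and with this discretization the time-reversal
identity

    action(reversed) - action(forward) = q / Gamma

holds *exactly* step by step (the even terms share midpoints and cancel).
For gradient-descent systems (Q = 0) with quadratic surprise, the midpoint
sum also telescopes exactly, so q = -Gamma * (I(x_T) - I(x_0)) to machine
precision; for non-quadratic surprise the identity holds to O(dt).

Reading the scalar Gamma as k_B T converts heat into energy units and turns
the free-energy drop along a deterministic mode relaxation into dissipated
heat (the quasi-static limit of the Jarzynski relation).

The integral fluctuation theorem is estimated over an ensemble of steady
state paths: with total entropy production
sigma = q/Gamma + Delta I (path-probability ratio including the initial
state surprise), E[exp(-sigma)] = 1.

Expected free energy for discrete toy models: with a steady-state joint
table p(eta, pi) and a predictive density q(pi) q(eta|pi),

    G = E_q[I(eta, pi) + ln q(eta|pi)]
    risk = E_q[ KL[q(eta|pi) || p(eta)] ],  ambiguity = E_q[ H[p(pi|eta)] ],

with the exact relation G = risk + E_q(eta)[CE(q(pi|eta), p(pi|eta))]; the
risk + ambiguity decomposition coincides with G when q(pi|eta) = p(pi|eta),
and the gap G - (risk + ambiguity) is reported rather than asserted to have
a fixed sign.  G is always an upper bound on the predictive entropy H[q(pi)].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UnsupportedConfigurationError
from .simulate import Ensemble, Trajectory
from .systems import LinearBlanketSystem

_NORM_TOL = 1e-12


# ---------------------------------------------------------------------------
# Path functionals
# ---------------------------------------------------------------------------


@dataclass
class PathFunctionals:
    action_forward: float
    action_reverse: float
    heat: float
    surprise_change: float
    scheme: str = "midpoint"


def _gamma_scalar(system) -> float:
    return system.gamma_scalar


def _midpoint_pieces(system, traj: Trajectory):
    x = traj.states
    dx = np.diff(x, axis=0)
    mid = 0.5 * (x[:-1] + x[1:])
    f = system.drift(mid)
    if isinstance(system, LinearBlanketSystem):
        divf = np.full(len(mid), system.div_drift())
    else:
        divf = np.array([system.div_drift(m) for m in mid])
    return dx, mid, f, divf


def path_action(system, traj: Trajectory, *, add_initial_surprise: bool = False) -> float:
    """Negative log path probability (up to the scheme's constant), midpoint
    discretization.  Requires isotropic Gamma; with ``add_initial_surprise``
    the steady-state surprise of the first point is included, giving the full
    path surprise used by the fluctuation estimators."""
    if traj.dt <= 0:
        raise ValueError("dt must be positive")
    gamma = _gamma_scalar(system)
    dx, mid, f, divf = _midpoint_pieces(system, traj)
    v = dx / traj.dt
    integrand = (
        np.einsum("ki,ki->k", v, v)
        - 2.0 * np.einsum("ki,ki->k", v, f)
        + np.einsum("ki,ki->k", f, f)
        + 2.0 * gamma * divf
    )
    action = float(np.sum(integrand) * traj.dt / (4.0 * gamma))
    if add_initial_surprise:
        action += float(system.surprise(traj.states[0]))
    return action


def reverse(traj: Trajectory) -> Trajectory:
    """Time-reversed trajectory (states reversed, times re-indexed forward).
    An involution preserving dt and length."""
    return Trajectory(
        dt=traj.dt,
        times=traj.times[0] + traj.dt * np.arange(len(traj.times)),
        states=traj.states[::-1].copy(),
        seed=traj.seed,
        system=traj.system,
        scheme=traj.scheme,
    )


def heat(system, traj: Trajectory) -> float:
    """Dissipated heat q = sum dx . f(midpoint) (Stratonovich), in units of
    Gamma * nats, so that action(reverse) - action(forward) = q / Gamma."""
    _gamma_scalar(system)  # enforce isotropy
    dx, mid, f, _ = _midpoint_pieces(system, traj)
    return float(np.einsum("ki,ki->", dx, f))


def heat_temperature(q_value: float, gamma_scalar: float) -> float:
    """Express heat with the k_B T identification Gamma = k_B T: returns the
    number of k_B T units dissipated.  A pure unit relabelling."""
    if np.ndim(gamma_scalar) != 0 or gamma_scalar <= 0:
        raise UnsupportedConfigurationError("k_B T conversion needs a positive scalar Gamma")
    return float(q_value) / float(gamma_scalar)


def path_functionals(system, traj: Trajectory) -> PathFunctionals:
    """Bundle of forward/reverse actions, heat and surprise change for a
    stored path; the reverse action is computed on the reversed trajectory
    through the same code path as the forward one."""
    a_f = path_action(system, traj)
    a_r = path_action(system, reverse(traj))
    q = heat(system, traj)
    dI = float(system.surprise(traj.states[-1]) - system.surprise(traj.states[0]))
    return PathFunctionals(
        action_forward=a_f, action_reverse=a_r, heat=q, surprise_change=dI
    )


@dataclass
class HeatFreeEnergy:
    """Heat along a deterministic mode relaxation, by two routes."""

    heat_from_F: float
    heat_from_surprise: float


def heat_free_energy(system: LinearBlanketSystem, mode_path: np.ndarray, b, smap=None) -> HeatFreeEnergy:
    """q = -Gamma * Delta F(mu, b) = -Gamma * Delta I(sigma(mu), b) along a
    mode path at fixed b; the two routes agree exactly in the linear class
    (the curvature terms of F are constant) and are both returned."""
    from .geometry import sync_map as _sync
    from .mechanics import free_energy, joint_surprise_eta_b

    gamma = _gamma_scalar(system)
    if smap is None:
        smap = _sync(system)
    path = np.atleast_2d(np.asarray(mode_path, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    F0 = free_energy(system, path[0], b, smap).F
    F1 = free_energy(system, path[-1], b, smap).F
    I0 = joint_surprise_eta_b(system, smap(path[0]), b)
    I1 = joint_surprise_eta_b(system, smap(path[-1]), b)
    out = HeatFreeEnergy(heat_from_F=-gamma * (F1 - F0), heat_from_surprise=-gamma * (I1 - I0))
    assert abs(out.heat_from_F - out.heat_from_surprise) < 1e-8 * max(
        1.0, abs(out.heat_from_F)
    )
    return out


# ---------------------------------------------------------------------------
# Fluctuation-theorem estimator
# ---------------------------------------------------------------------------


def entropy_production(system, ensemble: Ensemble) -> np.ndarray:
    """Per-member total entropy production sigma = q/Gamma + Delta I: the log
    ratio of forward to time-reversed path probabilities, initial-state
    surprise included."""
    gamma = _gamma_scalar(system)
    S = ensemble.stacked()
    dx = np.diff(S, axis=1)
    mid = 0.5 * (S[:, :-1] + S[:, 1:])
    if isinstance(system, LinearBlanketSystem):
        f = mid @ system.A.T
        q = np.einsum("nki,nki->n", dx, f)
        x0, xT = S[:, 0], S[:, -1]
        dI = np.asarray(system.surprise(xT)) - np.asarray(system.surprise(x0))
    else:
        q = np.empty(len(ensemble))
        dI = np.empty(len(ensemble))
        for i, m in enumerate(ensemble.members):
            q[i] = heat(system, m)
            dI[i] = system.surprise(m.states[-1]) - system.surprise(m.states[0])
    return q / gamma + dI


def jackknife_mean(values: np.ndarray):
    values = np.asarray(values, dtype=float)
    N = len(values)
    mean = values.mean()
    if N < 2:
        return float(mean), float("inf")
    total = values.sum()
    loo = (total - values) / (N - 1)
    se = np.sqrt((N - 1) / N * np.sum((loo - loo.mean()) ** 2))
    return float(mean), float(se)


def fluctuation_average(system, ensemble: Ensemble, g=None):
    """Monte-Carlo estimate of E[g(S^dagger) exp(I(x^dagger) - I(x))] over
    the time-reversed ensemble, with jackknife standard error.

    Sampling forward steady-state paths x with entropy production sigma, the
    reversed path carries functional value S^dagger = -sigma and exponent
    -sigma, so for g = 1 this is the integral fluctuation theorem
    E[exp(-sigma)] = 1.  Exponentials are computed with a max-shift guard.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    sigma = entropy_production(system, ensemble)
    a = -sigma
    shift = a.max()
    w = np.exp(a - shift)
    if g is not None:
        w = w * np.array([float(g(s)) for s in -sigma])
    mean_w, se_w = jackknife_mean(w)
    scale = np.exp(shift)
    return mean_w * scale, se_w * scale


# ---------------------------------------------------------------------------
# Expected free energy (discrete toy model)
# ---------------------------------------------------------------------------


@dataclass
class DiscreteModel:
    """Finite-outcome model for the expected-free-energy bound.

    ``p_joint[i, j] = p(eta_i, pi_j)`` is the steady-state joint table;
    ``q_pi[j] = q(pi_j)`` is the predictive density over particular outcomes
    at a single future step, and ``q_eta_given_pi[i, j] = q(eta_i | pi_j)``
    the associated conditional beliefs.
    """

    p_joint: np.ndarray
    q_pi: np.ndarray
    q_eta_given_pi: np.ndarray

    def __post_init__(self):
        self.p_joint = np.asarray(self.p_joint, dtype=float)
        self.q_pi = np.asarray(self.q_pi, dtype=float)
        self.q_eta_given_pi = np.asarray(self.q_eta_given_pi, dtype=float)
        if self.p_joint.ndim != 2:
            raise ValueError("p_joint must be a 2-D table")
        ne, npi = self.p_joint.shape
        if self.q_pi.shape != (npi,) or self.q_eta_given_pi.shape != (ne, npi):
            raise ValueError("table shapes are inconsistent")
        if np.any(self.p_joint < 0) or np.any(self.q_pi < 0) or np.any(self.q_eta_given_pi < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.p_joint.sum() - 1.0) > _NORM_TOL:
            raise ValueError("p_joint must sum to 1")
        if abs(self.q_pi.sum() - 1.0) > _NORM_TOL:
            raise ValueError("q_pi must sum to 1")
        colsums = self.q_eta_given_pi.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > _NORM_TOL):
            raise ValueError("each q(eta|pi) column must sum to 1")

    def to_dict(self) -> dict:
        return {
            "p_joint": self.p_joint.tolist(),
            "q_pi": self.q_pi.tolist(),
            "q_eta_given_pi": self.q_eta_given_pi.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscreteModel":
        return cls(
            np.array(d["p_joint"], dtype=float),
            np.array(d["q_pi"], dtype=float),
            np.array(d["q_eta_given_pi"], dtype=float),
        )


@dataclass
class EFEResult:
    G_exact: float
    risk: float
    ambiguity: float
    G_decomposed: float
    bound: float
    gap: float


def expected_free_energy(model: DiscreteModel) -> EFEResult:
    """All expected-free-energy quantities by exact enumeration.

    Zero-probability conditioning cells use 0*ln 0 = 0, and the ambiguity
    expectation skips eta outcomes unreachable under q.
    """
    from scipy.special import xlogy

    p = model.p_joint
    q_pi = model.q_pi
    q_e_p = model.q_eta_given_pi
    q_joint = q_e_p * q_pi[None, :]
    p_eta = p.sum(axis=1)

    # G = E_q[-ln p(eta, pi) + ln q(eta|pi)]
    G = float(np.sum(xlogy(q_joint, q_e_p) - xlogy(q_joint, p)))

    # risk = E_{q(pi)} KL[q(eta|pi) || p(eta)]
    kl_cols = np.sum(xlogy(q_e_p, q_e_p) - xlogy(q_e_p, p_eta[:, None]), axis=0)
    risk = float(np.sum(q_pi * kl_cols))

    # ambiguity = E_q H[p(pi|eta)]
    safe = np.where(p_eta > 0, p_eta, 1.0)[:, None]
    p_pi_given_eta = np.where(p_eta[:, None] > 0, p / safe, 0.0)
    H_cond = -np.sum(xlogy(p_pi_given_eta, p_pi_given_eta), axis=1)
    q_eta = q_joint.sum(axis=1)
    ambiguity = float(np.sum(q_eta * H_cond))

    bound = float(-np.sum(xlogy(q_pi, q_pi)))

    G_dec = risk + ambiguity
    return EFEResult(
        G_exact=G,
        risk=risk,
        ambiguity=ambiguity,
        G_decomposed=G_dec,
        bound=bound,
        gap=G - G_dec,
    )
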