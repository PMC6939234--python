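"""Euler-Maruyama integration of the Langevin dynamics and ensemble statistics.

The integrator is the standard explicit scheme

    x_{k+1} = x_k + f(x_k) dt + sqrt(2 Gamma dt) xi_k,   xi_k ~ N(0, I),

with all noise drawn from a seeded generator, so trajectories are exactly
reproducible.  Thermodynamic path functionals (module :mod:`blanketmech.thermo`)
use midpoint (Stratonovich) evaluation on the *stored* paths, so no separate
Stratonovich integrator is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DivergenceError, SingularSampleError
from .systems import LinearBlanketSystem

#: Trajectories whose max-norm exceeds this are reported as divergent.
DIVERGENCE_THRESHOLD = 1e6


@dataclass
class Trajectory:
    """A discretized sample path: uniform grid, T+1 row states."""

    dt: float
    times: np.ndarray
    states: np.ndarray
    seed: int
    system: object = field(repr=False, default=None)
    scheme: str = "euler-maruyama"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.atleast_2d(np.asarray(self.states, dtype=float))
        if self.states.shape[0] != self.times.shape[0]:
            raise ValueError("states row count must equal times length")
        if len(self.times) > 1:
            steps = np.diff(self.times)
            if np.any(steps <= 0) or not np.allclose(steps, self.dt, rtol=1e-9):
                raise ValueError("times must increase uniformly with spacing dt")

    @property
    def n_steps(self) -> int:
        return self.states.shape[0] - 1

    @property
    def n(self) -> int:
        return self.states.shape[1]


@dataclass
class Ensemble:
    """Homogeneous collection of trajectories of one system."""

    members: list[Trajectory]

    def __post_init__(self):
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        shape = self.members[0].states.shape
        dt = self.members[0].dt
        for m in self.members:
            if m.states.shape != shape or not np.isclose(m.dt, dt):
                raise ValueError("ensemble members must share shape and dt")
        seeds = [m.seed for m in self.members]
        if len(set(seeds)) != len(seeds):
            raise ValueError("ensemble member seeds must be distinct")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def dt(self) -> float:
        return self.members[0].dt

    @property
    def system(self):
        return self.members[0].system

    def stacked(self) -> np.ndarray:
        """(n_traj, T+1, n) array of all member states."""
        return np.stack([m.states for m in self.members])


def _member_seed(seed: int, index: int) -> int:
    """Deterministic per-member seed derived from (seed, index)."""
    return int(np.random.SeedSequence((int(seed), int(index))).generate_state(1)[0])


def simulate(
    system,
    x0: np.ndarray,
    dt: float,
    n_steps: int,
    seed: int,
    *,
    noise: bool = True,
) -> Trajectory:
    """Integrate one Euler-Maruyama path from ``x0``.

    ``noise=False`` disables the fluctuations (Gamma-drift retained), which
    reduces the scheme to explicit Euler on the deterministic flow -- used to
    check against closed-form linear ODE solutions.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    x0 = np.asarray(x0, dtype=float)
    n = system.n
    if x0.shape != (n,):
        raise ValueError(f"x0 has shape {x0.shape}, system dimension is {n}")
    rng = np.random.default_rng(seed)
    sqrt_step = np.sqrt(2.0 * np.diag(system.Gamma) * dt)
    if noise and n_steps > 0:
        xi = rng.standard_normal((n_steps, n))
    else:
        xi = np.zeros((max(n_steps, 0), n))
    states = np.empty((n_steps + 1, n))
    states[0] = x0
    x = x0.copy()
    for k in range(n_steps):
        x = x + system.drift(x) * dt + sqrt_step * xi[k]
        m = np.max(np.abs(x))
        if not np.isfinite(m) or m > DIVERGENCE_THRESHOLD:
            raise DivergenceError(k + 1, m)
        states[k + 1] = x
    times = dt * np.arange(n_steps + 1)
    return Trajectory(dt=dt, times=times, states=states, seed=int(seed), system=system)


def _simulate_batch(system, X0: np.ndarray, dt: float, n_steps: int, rng) -> np.ndarray:
    """Vectorized Euler-Maruyama over a batch of initial rows.  Noise is drawn
    per step from a single generator; used where per-member seed streams are
    not required."""
    N, n = X0.shape
    out = np.empty((N, n_steps + 1, n))
    out[:, 0] = X0
    X = X0.copy()
    scale = np.sqrt(2.0 * np.diag(system.Gamma) * dt)
    for k in range(n_steps):
        X = X + system.drift(X) * dt + scale * rng.standard_normal((N, n))
        m = np.max(np.abs(X))
        if not np.isfinite(m) or m > DIVERGENCE_THRESHOLD:
            raise DivergenceError(k + 1, float(m))
        out[:, k + 1] = X
    return out


def ness_samples(
    system: LinearBlanketSystem,
    n_samples: int,
    seed: int,
    *,
    dt: float = 0.002,
    n_steps: int = 250,
) -> np.ndarray:
    """Independent samples of the simulated steady state.

    Each sample is the endpoint of an independent Euler-Maruyama run started
    from an exact draw of the stationary density N(0, Pi^{-1}); runs are
    integrated in one vectorized batch.  Endpoint samples are i.i.d. across
    the batch (up to the O(dt) discretization bias of the scheme).
    """
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(system.stationary_covariance())
    X0 = rng.standard_normal((n_samples, system.n)) @ L.T
    paths = _simulate_batch(system, X0, dt, n_steps, rng)
    return paths[:, -1]


def simulate_ensemble(
    system,
    n_traj: int,
    dt: float,
    n_steps: int,
    burn_in: int = 0,
    seed: int = 0,
    *,
    x0_sampler=None,
) -> Ensemble:
    """Independent seeded trajectories with NESS initial conditions.

    For linear systems, initial states are exact draws from N(0, Pi^{-1});
    for nonlinear systems a proposal sampler ``x0_sampler(rng) -> x0`` must be
    supplied.  Member i uses the seed derived from (seed, i), so members are
    reproducible individually.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    if isinstance(system, LinearBlanketSystem):
        L = np.linalg.cholesky(system.stationary_covariance())
    elif x0_sampler is None:
        raise ValueError("nonlinear systems need an explicit x0_sampler")

    members = []
    for i in range(n_traj):
        mseed = _member_seed(seed, i)
        rng = np.random.default_rng(mseed)
        if x0_sampler is not None:
            x0 = np.asarray(x0_sampler(rng), dtype=float)
        else:
            x0 = L @ rng.standard_normal(system.n)
        n = system.n
        sqrt_step = np.sqrt(2.0 * np.diag(system.Gamma) * dt)
        xi = rng.standard_normal((n_steps, n))
        states = np.empty((n_steps + 1, n))
        states[0] = x0
        x = x0
        if isinstance(system, LinearBlanketSystem):
            AT = system.A.T
            for k in range(n_steps):
                x = x + (x @ AT) * dt + sqrt_step * xi[k]
                states[k + 1] = x
            m = np.max(np.abs(states))
            if not np.isfinite(m) or m > DIVERGENCE_THRESHOLD:
                step = int(np.argmax(np.max(np.abs(states), axis=1) > DIVERGENCE_THRESHOLD))
                raise DivergenceError(step, float(m))
        else:
            for k in range(n_steps):
                x = x + system.drift(x) * dt + sqrt_step * xi[k]
                mm = np.max(np.abs(x))
                if not np.isfinite(mm) or mm > DIVERGENCE_THRESHOLD:
                    raise DivergenceError(k + 1, float(mm))
                states[k + 1] = x
        members.append(
            Trajectory(dt=dt, times=dt * np.arange(n_steps + 1), states=states,
                       seed=mseed, system=system)
        )
    ens = Ensemble(members)
    ens.burn_in = burn_in
    return ens


# ---------------------------------------------------------------------------
# Ensemble statistics
# ---------------------------------------------------------------------------


def integrated_autocorr_time(x: np.ndarray, max_lag: int | None = None) -> float:
    """Integrated autocorrelation time tau = 1 + 2 sum rho_k, truncating the
    empirical autocorrelation at its first non-positive value
    (initial-positive-sequence rule).  Returns at least 1."""
    x = np.asarray(x, dtype=float)
    T = len(x)
    if T < 3:
        return 1.0
    x = x - x.mean()
    var = np.dot(x, x) / T
    if var == 0:
        return 1.0
    if max_lag is None:
        max_lag = min(T - 1, 1000)
    tau = 1.0
    for k in range(1, max_lag + 1):
        rho = np.dot(x[:-k], x[k:]) / (T * var)
        if rho <= 0:
            break
        tau += 2.0 * rho
    return float(tau)


def empirical_moments(ensemble: Ensemble, burn_in: int | None = None):
    """Pooled post-burn-in mean and covariance with autocorrelation-corrected
    standard errors of the mean.

    Returns ``(mean, cov, se_mean)``; the effective sample size per dimension
    is the pooled sample count divided by the cross-member average integrated
    autocorrelation time.
    """
    if burn_in is None:
        burn_in = getattr(ensemble, "burn_in", 0)
    S = ensemble.stacked()[:, burn_in:, :]
    if S.shape[1] < 1:
        raise ValueError("empty post-burn-in window")
    N, T, n = S.shape
    pooled = S.reshape(N * T, n)
    mean = pooled.mean(axis=0)
    if N * T > 1:
        cov = np.cov(pooled, rowvar=False).reshape(n, n)
    else:
        cov = np.zeros((n, n))
    se = np.empty(n)
    for j in range(n):
        tau = np.mean([integrated_autocorr_time(S[i, :, j]) for i in range(min(N, 20))])
        ess = N * T / tau
        se[j] = np.sqrt(cov[j, j] / max(ess, 1.0))
    return mean, cov, se


def blanket_independence_check(
    data: Ensemble | np.ndarray,
    system: LinearBlanketSystem | None = None,
    burn_in: int | None = None,
    z_crit: float = 3.0,
) -> dict:
    """Test the Markov blanket condition in samples: the (eta, mu) block of
    the estimated precision matrix should vanish.

    ``data`` may be an :class:`Ensemble` (member-wise precision estimates give
    independent replicates, hence honest standard errors despite serial
    correlation within members) or an (N, n) array of i.i.d. samples (Wishart
    standard errors).  Returns a report dict with the blanket-block entries,
    their standard errors, the max |z| score and a pass flag.
    """
    if isinstance(data, Ensemble):
        if system is None:
            system = data.system
        if burn_in is None:
            burn_in = getattr(data, "burn_in", 0)
        S = data.stacked()[:, burn_in:, :]
        N, T, n = S.shape
        if T <= n:
            raise SingularSampleError(
                f"{T} post-burn-in samples per member cannot estimate a {n}x{n} precision"
            )
        p = system.partition
        blocks = []
        for i in range(N):
            c = np.cov(S[i], rowvar=False).reshape(n, n)
            if np.linalg.cond(c) > 1e12:
                raise SingularSampleError("singular member sample covariance")
            prec = np.linalg.inv(c)
            blocks.append(prec[p.eta, p.mu])
        blocks = np.array(blocks)  # (N, n_eta, n_mu)
        est = blocks.mean(axis=0)
        se = blocks.std(axis=0, ddof=1) / np.sqrt(N)
        n_samples = N * T
    else:
        X = np.asarray(data, dtype=float)
        N, n = X.shape
        if N <= n:
            raise SingularSampleError(f"{N} samples cannot estimate a {n}x{n} precision")
        if system is None:
            raise ValueError("system required for raw-sample input")
        c = np.cov(X, rowvar=False).reshape(n, n)
        if np.linalg.cond(c) > 1e12:
            raise SingularSampleError("singular sample covariance")
        prec = np.linalg.inv(c)
        p = system.partition
        est = prec[p.eta, p.mu]
        d = np.diag(prec)
        # Wishart large-N standard error of precision entries.
        se = np.sqrt(
            (np.outer(d[p.eta], d[p.mu]) + prec[p.eta, p.mu] ** 2) / N
        )
        n_samples = N
    z = np.abs(est) / np.where(se > 0, se, np.inf)
    return {
        "block": est,
        "se": se,
        "max_abs": float(np.max(np.abs(est))),
        "max_z": float(np.max(z)),
        "n_samples": int(n_samples),
        "passed": bool(np.max(z) < z_crit),
        "z_crit": float(z_crit),
    }


# ---------------------------------------------------------------------------
# Trajectory I/O (tab-separated text)
# ---------------------------------------------------------------------------


def write_trajectory_tsv(traj: Trajectory, path) -> None:
    sys_hash = traj.system.content_hash() if hasattr(traj.system, "content_hash") else "none"
    header = (
        f"# system={sys_hash} dt={traj.dt!r} seed={traj.seed} scheme={traj.scheme}\n"
        "# time\t" + "\t".join(f"state_{i}" for i in range(traj.n)) + "\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for t, row in zip(traj.times, traj.states):
            fh.write("\t".join(repr(float(v)) for v in (t, *row)) + "\n")


def read_trajectory_tsv(path, system=None) -> Trajectory:
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
                continue
            rows.append([float(v) for v in line.split("\t")])
    arr = np.array(rows)
    dt = float(meta.get("dt", arr[1, 0] - arr[0, 0] if len(arr) > 1 else 1.0))
    return Trajectory(
        dt=dt,
        times=arr[:, 0],
        states=arr[:, 1:],
        seed=int(meta.get("seed", 0)),
        system=system,
        scheme=meta.get("scheme", "euler-maruyama"),
    )
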