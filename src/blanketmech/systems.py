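"""Markov-blanketed Gaussian steady-state systems.

A system is specified by the stationary precision matrix ``Pi`` of a zero-mean
Gaussian non-equilibrium steady state (NESS), a constant skew-symmetric
solenoidal operator ``Q``, a diagonal fluctuation amplitude ``Gamma`` and a
:class:`Partition` of the state vector into external (eta), sensory (s),
active (a) and internal (mu) blocks.  The drift of the associated Langevin
equation is the Helmholtz-decomposed NESS flow

    f(x) = (Q - Gamma) * grad I(x),      I(x) = -ln p(x),

which for a Gaussian steady state is the linear map ``A x`` with
``A = (Q - Gamma) Pi``.  Stationarity of ``N(0, Pi^{-1})`` under this drift is
an algebraic identity:  A Pi^{-1} + Pi^{-1} A^T + 2 Gamma = 0.

The Markov blanket condition is the zero block ``Pi[eta, mu] = 0``: internal
and external states are conditionally independent given the blanket
b = (s, a).  ``Q`` is block-diagonal over the coarse partition
(eta, b, mu), so the *rates of change* of internal and external states are
also uncoupled.

Two validation levels are provided.  "Blanket" systems satisfy only
``Pi[eta, mu] = 0``.  "Strict" systems additionally satisfy
``Pi[a, eta] = 0`` and ``Pi[s, mu] = 0``, so that active states are not
(instantaneously) influenced by external states and sensory states not by
internal states.  Note that strictness severely constrains the conditional
modes (see :func:`blanketmech.geometry.sync_map` and docs/methods.md).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import PartitionError, SystemValidationError, UnsupportedConfigurationError

#: Condition-number threshold above which constructors emit a warning.
COND_WARN_THRESHOLD = 1e8

_ZERO_ATOL = 1e-12


# ---------------------------------------------------------------------------
# Partition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Partition:
    """Index bookkeeping for the (eta, s, a, mu) blocks of the state vector.

    Canonical ordering is external, sensory, active, internal.  Derived
    groupings: blanket ``b = (s, a)`` and particular states ``pi = (b, mu)``.
    """

    n_eta: int
    n_s: int
    n_a: int
    n_mu: int

    @property
    def n(self) -> int:
        return self.n_eta + self.n_s + self.n_a + self.n_mu

    @property
    def n_b(self) -> int:
        return self.n_s + self.n_a

    # --- index ranges (slices into the concatenated state vector) ---

    @property
    def eta(self) -> slice:
        return slice(0, self.n_eta)

    @property
    def s(self) -> slice:
        return slice(self.n_eta, self.n_eta + self.n_s)

    @property
    def a(self) -> slice:
        return slice(self.n_eta + self.n_s, self.n_eta + self.n_s + self.n_a)

    @property
    def mu(self) -> slice:
        return slice(self.n_eta + self.n_b, self.n)

    @property
    def b(self) -> slice:
        return slice(self.n_eta, self.n_eta + self.n_b)

    @property
    def pi(self) -> slice:
        return slice(self.n_eta, self.n)

    @property
    def is_blanket(self) -> bool:
        """Whether the partition supports a Markov blanket (all three groups
        non-empty)."""
        return self.n_eta >= 1 and self.n_mu >= 1 and self.n_b >= 1

    def coarse_blocks(self) -> list[slice]:
        """The (eta, b, mu) blocks over which Q must be block-diagonal."""
        return [self.eta, self.b, self.mu]


def make_partition(n_eta: int, n_s: int, n_a: int, n_mu: int, *, bare: bool = False) -> Partition:
    """Create a validated :class:`Partition`.

    Parameters
    ----------
    bare :
        If True, allow degenerate partitions without a blanket structure
        (used for plain stochastic systems in thermodynamic unit tests).
        Blanket-specific operations refuse such partitions.
    """
    sizes = (n_eta, n_s, n_a, n_mu)
    for v in sizes:
        if not isinstance(v, (int, np.integer)) or v < 0:
            raise PartitionError(f"block sizes must be non-negative integers, got {sizes}")
    p = Partition(int(n_eta), int(n_s), int(n_a), int(n_mu))
    if p.n < 1:
        raise PartitionError("total state dimension must be at least 1")
    if not bare and not p.is_blanket:
        raise PartitionError(
            "a blanket partition needs n_eta >= 1, n_mu >= 1 and n_s + n_a >= 1 "
            f"(got {sizes}); pass bare=True for a non-blanket system"
        )
    return p


# ---------------------------------------------------------------------------
# Linear (Gaussian NESS) systems
# ---------------------------------------------------------------------------


@dataclass
class LinearBlanketSystem:
    """Linear-drift system with Gaussian NESS ``N(0, Pi^{-1})``.

    Direct construction performs no validation (tests use this to build
    deliberately invalid systems); use :func:`build_linear_system` for the
    validated path.
    """

    Pi: np.ndarray
    Q: np.ndarray
    Gamma: np.ndarray
    partition: Partition
    strict: bool = True
    A: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.Pi = np.asarray(self.Pi, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        g = np.asarray(self.Gamma, dtype=float)
        if g.ndim == 1:
            g = np.diag(g)
        self.Gamma = g
        self.A = (self.Q - self.Gamma) @ self.Pi

    # --- basic quantities -------------------------------------------------

    @property
    def n(self) -> int:
        return self.Pi.shape[0]

    @property
    def gamma_diag(self) -> np.ndarray:
        return np.diag(self.Gamma)

    @property
    def gamma_scalar(self) -> float:
        """Isotropic fluctuation amplitude; raises for anisotropic Gamma.

        Path-level thermodynamic functionals read this value as k_B T.
        """
        d = self.gamma_diag
        if not np.allclose(d, d[0], rtol=1e-12, atol=0):
            raise UnsupportedConfigurationError(
                "this operation requires isotropic (scalar) Gamma"
            )
        return float(d[0])

    def drift(self, x: np.ndarray) -> np.ndarray:
        """f(x) = (Q - Gamma) Pi x.  Accepts a single state or an array of
        row states."""
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.n:
            raise ValueError(f"state dimension {x.shape[-1]} != system dimension {self.n}")
        return x @ self.A.T

    def div_drift(self, x: np.ndarray | None = None) -> float:
        """Divergence of the drift field (constant: trace of A)."""
        return float(np.trace(self.A))

    def surprise(self, x: np.ndarray) -> float | np.ndarray:
        """I(x) = -ln p(x) = 1/2 x^T Pi x + 1/2 ln((2 pi)^n / det Pi).

        The full Gaussian normalization is included so free energies and
        KL divergences are absolute; identities that must be
        normalization-independent are stated as differences.
        """
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.n:
            raise ValueError(f"state dimension {x.shape[-1]} != system dimension {self.n}")
        quad = 0.5 * np.einsum("...i,ij,...j->...", x, self.Pi, x)
        _, logdet = np.linalg.slogdet(self.Pi)
        out = quad + 0.5 * (self.n * np.log(2.0 * np.pi) - logdet)
        return float(out) if out.ndim == 0 else out

    def grad_surprise(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return x @ self.Pi.T  # Pi symmetric; row convention matches drift()

    def stationary_covariance(self) -> np.ndarray:
        """Pi^{-1}, asserting the Lyapunov residual A S + S A^T + 2 Gamma = 0."""
        cond = np.linalg.cond(self.Pi)
        if cond > COND_WARN_THRESHOLD:
            warnings.warn(
                f"precision matrix is ill-conditioned (cond = {cond:.3g})",
                RuntimeWarning,
                stacklevel=2,
            )
        sigma = np.linalg.inv(self.Pi)
        sigma = 0.5 * (sigma + sigma.T)
        resid = self.A @ sigma + sigma @ self.A.T + 2.0 * self.Gamma
        assert np.max(np.abs(resid)) < 1e-10 * max(1.0, np.max(np.abs(self.Pi))), (
            "stationarity residual unexpectedly large"
        )
        return sigma

    # --- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        p = self.partition
        return {
            "partition": {"n_eta": p.n_eta, "n_s": p.n_s, "n_a": p.n_a, "n_mu": p.n_mu},
            "Pi": self.Pi.tolist(),
            "Q": self.Q.tolist(),
            "Gamma": self.gamma_diag.tolist(),
            "strict": bool(self.strict),
        }

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class NonlinearSystem:
    """System with user-supplied surprise and gradient contracts.

    Supports the gradient-descent (Q = 0) and constant-Q cases used by the
    simulator and the path-level thermodynamics; there is no closed-form
    steady state here, only the drift f(x) = (Q - Gamma) grad I(x).
    """

    surprise_fn: Callable[[np.ndarray], float]
    grad_fn: Callable[[np.ndarray], np.ndarray]
    Q: np.ndarray
    Gamma: np.ndarray
    partition: Partition
    laplacian_fn: Callable[[np.ndarray], float] | None = None
    _fd_step: float = 1e-5

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=float)
        g = np.asarray(self.Gamma, dtype=float)
        if g.ndim == 1:
            g = np.diag(g)
        self.Gamma = g

    @property
    def n(self) -> int:
        return self.partition.n

    @property
    def gamma_diag(self) -> np.ndarray:
        return np.diag(self.Gamma)

    @property
    def gamma_scalar(self) -> float:
        d = self.gamma_diag
        if not np.allclose(d, d[0], rtol=1e-12, atol=0):
            raise UnsupportedConfigurationError(
                "this operation requires isotropic (scalar) Gamma"
            )
        return float(d[0])

    def surprise(self, x: np.ndarray) -> float | np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            return float(self.surprise_fn(x))
        return np.array([float(self.surprise_fn(row)) for row in x])

    def grad_surprise(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            return np.asarray(self.grad_fn(x), dtype=float)
        return np.array([np.asarray(self.grad_fn(row), dtype=float) for row in x])

    def drift(self, x: np.ndarray) -> np.ndarray:
        return self.grad_surprise(x) @ (self.Q - self.Gamma).T

    def div_drift(self, x: np.ndarray) -> float:
        """div f = tr((Q - Gamma) Hess I); Q's contribution vanishes for
        skew Q, leaving -tr(Gamma Hess I).  Uses the analytic Laplacian when
        supplied, else central differences of the gradient contract."""
        x = np.asarray(x, dtype=float)
        if self.laplacian_fn is not None and np.allclose(
            self.gamma_diag, self.gamma_diag[0]
        ):
            return -float(self.gamma_diag[0]) * float(self.laplacian_fn(x))
        h = self._fd_step
        M = self.Q - self.Gamma
        div = 0.0
        for i in range(self.n):
            e = np.zeros(self.n)
            e[i] = h
            col = (self.grad_fn(x + e) - self.grad_fn(x - e)) / (2.0 * h)
            div += float(M[i] @ col)
        return div


# ---------------------------------------------------------------------------
# Validated constructors
# ---------------------------------------------------------------------------


def _fail(invariant: str, message: str):
    raise SystemValidationError(invariant, message)


def build_linear_system(
    Pi: np.ndarray | Sequence,
    Q: np.ndarray | Sequence,
    Gamma: np.ndarray | Sequence,
    partition: Partition,
    strict: bool = True,
) -> LinearBlanketSystem:
    """Validate and construct a :class:`LinearBlanketSystem`.

    Raises
    ------
    SystemValidationError
        Naming the failed invariant: shape mismatch, asymmetry of Pi,
        non-positive-definiteness, non-skew or non-block-diagonal Q,
        invalid Gamma, violated blanket/strict zero blocks, or a
        non-Hurwitz drift matrix.
    """
    sys_ = LinearBlanketSystem(Pi, Q, Gamma, partition, strict)
    n = partition.n
    if sys_.Pi.shape != (n, n):
        _fail("shape", f"Pi has shape {sys_.Pi.shape}, partition total is {n}")
    if sys_.Q.shape != (n, n):
        _fail("shape", f"Q has shape {sys_.Q.shape}, partition total is {n}")
    if sys_.Gamma.shape != (n, n):
        _fail("shape", f"Gamma has shape {sys_.Gamma.shape}, partition total is {n}")

    if not np.allclose(sys_.Pi, sys_.Pi.T, atol=_ZERO_ATOL):
        _fail("Pi symmetry", "Pi must be symmetric")
    eigs = np.linalg.eigvalsh(sys_.Pi)
    if eigs.min() <= 0:
        _fail("Pi positive-definite", f"Pi has non-positive eigenvalue {eigs.min():.3g}")

    if not np.allclose(sys_.Q, -sys_.Q.T, atol=_ZERO_ATOL):
        _fail("Q skew-symmetry", "Q must be skew-symmetric")
    mask = np.ones((n, n), dtype=bool)
    for blk in partition.coarse_blocks():
        mask[blk, blk] = False
    if np.any(np.abs(sys_.Q[mask]) > _ZERO_ATOL):
        _fail(
            "Q block-diagonal",
            "Q must be block-diagonal over the (eta, b, mu) partition blocks",
        )

    if np.any(np.abs(sys_.Gamma - np.diag(np.diag(sys_.Gamma))) > _ZERO_ATOL):
        _fail("Gamma diagonal", "Gamma must be diagonal")
    if np.any(np.diag(sys_.Gamma) <= 0):
        _fail("Gamma positive", "Gamma must have strictly positive diagonal entries")

    p = partition
    if p.is_blanket:
        if np.any(np.abs(sys_.Pi[p.eta, p.mu]) > _ZERO_ATOL):
            _fail(
                "blanket condition violated",
                "Pi[eta, mu] must be zero (Markov blanket condition)",
            )
        if strict:
            if np.any(np.abs(sys_.Pi[p.a, p.eta]) > _ZERO_ATOL):
                _fail(
                    "strict condition violated",
                    "strict systems require Pi[a, eta] = 0 "
                    "(active states not influenced by external states)",
                )
            if np.any(np.abs(sys_.Pi[p.s, p.mu]) > _ZERO_ATOL):
                _fail(
                    "strict condition violated",
                    "strict systems require Pi[s, mu] = 0 "
                    "(sensory states not influenced by internal states)",
                )
    elif strict:
        _fail("strict on bare partition", "a bare (non-blanket) system cannot be strict")

    re_max = np.linalg.eigvals(sys_.A).real.max()
    if re_max >= 0:
        _fail("A Hurwitz", f"drift matrix has eigenvalue with real part {re_max:.3g} >= 0")

    cond = np.linalg.cond(sys_.Pi)
    if cond > COND_WARN_THRESHOLD:
        warnings.warn(
            f"precision matrix is ill-conditioned (cond = {cond:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    return sys_


def build_nonlinear_system(
    surprise_fn: Callable[[np.ndarray], float],
    grad_fn: Callable[[np.ndarray], np.ndarray],
    Q: np.ndarray | Sequence,
    Gamma: np.ndarray | Sequence,
    partition: Partition,
    laplacian_fn: Callable[[np.ndarray], float] | None = None,
    *,
    check_points: int = 5,
    check_seed: int = 0,
    check_tol: float = 1e-5,
    check_scale: float = 1.0,
) -> NonlinearSystem:
    """Construct a :class:`NonlinearSystem`, verifying that the gradient
    contract agrees with central finite differences of the surprise contract
    at seeded random test points."""
    sys_ = NonlinearSystem(surprise_fn, grad_fn, np.asarray(Q), np.asarray(Gamma), partition, laplacian_fn)
    rng = np.random.default_rng(check_seed)
    h = 1e-6
    for _ in range(check_points):
        x = check_scale * rng.standard_normal(partition.n)
        g = np.asarray(grad_fn(x), dtype=float)
        fd = np.empty_like(g)
        for i in range(partition.n):
            e = np.zeros(partition.n)
            e[i] = h
            fd[i] = (surprise_fn(x + e) - surprise_fn(x - e)) / (2.0 * h)
        scale = max(1.0, np.max(np.abs(g)))
        if np.max(np.abs(g - fd)) > check_tol * scale:
            _fail(
                "gradient contract",
                "grad_fn disagrees with central finite differences of surprise_fn "
                f"(max abs diff {np.max(np.abs(g - fd)):.3g})",
            )
    return sys_


# ---------------------------------------------------------------------------
# Free-function operation surface
# ---------------------------------------------------------------------------


def drift(system, x: np.ndarray) -> np.ndarray:
    """Drift field f(x) = (Q - Gamma) grad I(x)."""
    return system.drift(x)


def surprise(system, x: np.ndarray):
    """Steady-state surprise I(x) = -ln p(x)."""
    return system.surprise(x)


def grad_surprise(system, x: np.ndarray) -> np.ndarray:
    return system.grad_surprise(x)


def stationary_covariance(system: LinearBlanketSystem) -> np.ndarray:
    return system.stationary_covariance()


# ---------------------------------------------------------------------------
# JSON round trip
# ---------------------------------------------------------------------------


def system_to_json(system: LinearBlanketSystem) -> str:
    """Loss-free (full double precision) JSON encoding of a linear system."""
    d = system.to_dict()
    d["Pi"] = [[float(v) for v in row] for row in d["Pi"]]
    return json.dumps(d, indent=2)


def system_from_dict(d: dict) -> LinearBlanketSystem:
    p = d["partition"]
    part = make_partition(
        p["n_eta"], p["n_s"], p["n_a"], p["n_mu"],
        bare=not Partition(p["n_eta"], p["n_s"], p["n_a"], p["n_mu"]).is_blanket,
    )
    return build_linear_system(
        np.array(d["Pi"], dtype=float),
        np.array(d["Q"], dtype=float),
        np.array(d["Gamma"], dtype=float),
        part,
        strict=bool(d.get("strict", True)),
    )


def save_system(system: LinearBlanketSystem, path) -> None:
    with open(path, "w") as fh:
        fh.write(system_to_json(system))


def load_system(path) -> LinearBlanketSystem:
    with open(path) as fh:
        return system_from_dict(json.load(fh))
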