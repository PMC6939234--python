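"""Exception hierarchy for blanketmech."""


class BlanketMechError(Exception):
    """Base class for all package errors."""


class PartitionError(BlanketMechError):
    """Invalid state-space partition (e.g. empty blanket for a blanket system)."""


class SystemValidationError(BlanketMechError):
    """A system constructor invariant failed.

    Attributes
    ----------
    invariant : str
        Short name of the violated invariant.
    """

    def __init__(self, invariant: str, message: str | None = None):
        self.invariant = invariant
        super().__init__(f"{invariant}: {message}" if message else invariant)


class DivergenceError(BlanketMechError):
    """Numerical blow-up during integration; carries the offending step index."""

    def __init__(self, step: int, norm: float):
        self.step = step
        self.norm = norm
        super().__init__(
            f"trajectory diverged at step {step} (max |x| = {norm:.3g} exceeds threshold)"
        )


class RankError(BlanketMechError):
    """The blanket-to-internal-mode map is not injective, so the
    synchronization map is ill-defined.  A sufficient condition for the map
    eta(b) = sigma(mu(b)) to be well defined is that b -> mu(b) is injective."""


class StabilityError(BlanketMechError):
    """Requested integration step exceeds the stability limit."""


class UnsupportedConfigurationError(BlanketMechError):
    """Operation requires a configuration the package does not support
    (e.g. anisotropic fluctuation amplitude in a path functional)."""


class SingularSampleError(BlanketMechError):
    """Sample covariance is singular (too few samples for the dimension)."""
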