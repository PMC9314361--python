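"""Exception types shared across the package."""


class PadePSDError(Exception):
    """Base class for all package errors."""


class NetworkSpecError(PadePSDError):
    """Malformed network specification (bad stoichiometry, unknown species, ...)."""


class NegativeStateError(PadePSDError):
    """A propensity or generator was evaluated at a negative copy-number state."""


class UnsupportedOperationError(PadePSDError):
    """Operation not defined for this network (e.g. generator powers with
    jump kernels and non-affine observables)."""


class ErgodicityError(PadePSDError):
    """The linearised drift matrix is not Hurwitz-stable, so no stationary
    covariance exists for the linear-network machinery."""


class NonAffinePropensityError(PadePSDError):
    """linearize() was called on a network with a non-affine propensity."""
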