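"""Exception and warning types shared across the package."""


class HsmcrError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(HsmcrError, ValueError):
    """A kinetic parameter is non-finite or violates its sign constraint."""


class IntegrationError(HsmcrError, RuntimeError):
    """The ODE solver failed; the message names the offending parameter set."""


class DegenerateBandError(HsmcrError, ValueError):
    """The reference band integrates to a non-positive area."""


class IllConditionedError(HsmcrError, ValueError):
    """A least-squares design matrix is (numerically) rank deficient."""


class FormatError(HsmcrError, ValueError):
    """An input file does not follow the expected layout."""


class ClippingWarning(UserWarning):
    """Simulated intensities fell below zero and were clipped."""


class RankCollapseWarning(UserWarning):
    """A resolved component profile collapsed to zero during iteration."""


class IdentifiabilityWarning(UserWarning):
    """Too few time points to constrain all kinetic parameters."""


class KineticFitWarning(UserWarning):
    """The embedded kinetic refit did not converge; best iterate kept."""
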