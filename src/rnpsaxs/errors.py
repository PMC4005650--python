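"""Exception hierarchy shared across the package."""


class RnpSaxsError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RnpSaxsError, ValueError):
    """A file or record does not conform to the expected layout."""


class DomainError(RnpSaxsError, ValueError):
    """An argument lies outside the physically meaningful range."""


class FitError(RnpSaxsError, RuntimeError):
    """A least-squares or annealing fit could not be completed."""


class RangeError(RnpSaxsError, ValueError):
    """The q-range (or r-range) of the data is insufficient for the analysis."""


class ResolutionError(RnpSaxsError, ValueError):
    """Bead/lattice resolution too coarse for the requested geometry."""


class SpecificationError(RnpSaxsError, ValueError):
    """A phantom or run specification is internally inconsistent."""


class InversionError(RnpSaxsError, RuntimeError):
    """The indirect-Fourier-transform system could not be solved."""


class GridError(RnpSaxsError, ValueError):
    """Bead models do not share a compatible lattice."""


class DegenerateError(RnpSaxsError, ValueError):
    """All scattering contrasts vanish; the profile carries no signal."""
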