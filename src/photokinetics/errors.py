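"""Exception hierarchy shared by all photokinetics modules."""


class PhotokineticsError(Exception):
    """Base class for all errors raised by this package."""


class InvalidParameterError(PhotokineticsError, ValueError):
    """A kinetic parameter is non-finite or violates its sign constraint."""


class DegenerateParametersError(InvalidParameterError):
    """Equal formation/destruction rates make the consecutive-reaction
    closed form 0/0; the L'Hopital limit must be requested explicitly."""


class InvalidSchemeError(PhotokineticsError, ValueError):
    """A reaction scheme has a negative rate, unknown state or bad initial
    population."""


class NormalizationUndefinedError(PhotokineticsError, ValueError):
    """The normalisation divisor I*(k1-k2)/k1 is not positive."""


class UninformativeTraceError(PhotokineticsError, ValueError):
    """Trace dynamic range is below the noise floor; no fit is possible."""


class NoModelError(PhotokineticsError, RuntimeError):
    """Every candidate model failed to converge during selection."""


class NoPeakError(PhotokineticsError, ValueError):
    """Spectrum has no interior maximum (monotone band edge)."""


class UnidentifiableError(PhotokineticsError, ValueError):
    """Titration has no inflection inside the sampled pH range."""


class ClassificationUnavailableError(PhotokineticsError, ValueError):
    """Too few cycles (or missing fits) to call a variant behaviour."""


class TraceFormatError(PhotokineticsError, ValueError):
    """Malformed trace/spectrum/titration file."""


class TraceTooShortError(TraceFormatError):
    """Fewer than the minimum number of rows for a time trace."""


class PartialCoverageWarning(UserWarning):
    """Titration does not span a full pH unit on each side of the
    inflection; the pKa estimate may be poorly constrained."""
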