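"""Exception types shared across the package."""


class KirBlockError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(KirBlockError):
    """Inconsistent model/condition configuration (e.g. unknown blocker id)."""


class DesignError(KirBlockError):
    """An experiment design is missing groups or cells an analysis needs."""


class FitFailureError(KirBlockError):
    """A nonlinear fit failed to converge after multistart."""


class UnidentifiableError(KirBlockError):
    """Data carry no information about the requested parameter (e.g. all
    relative currents ~1 in a Hill fit)."""


class UndefinedRatioError(KirBlockError):
    """Relative current is undefined because the control current is ~0."""


class TraceFormatError(KirBlockError):
    """A trace directory or file violates the on-disk format contract."""
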