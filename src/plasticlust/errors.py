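"""Exception types shared across the package."""


class PlasticlustError(Exception):
    """Base class for package errors."""


class ParameterError(PlasticlustError, ValueError):
    """A caller-supplied parameter is outside its valid range."""


class DegenerateDataError(PlasticlustError, ValueError):
    """The input carries no usable signal (e.g. zero total dispersion)."""


class DataFormatError(PlasticlustError, ValueError):
    """An input table violates the expected layout or dtype contract."""
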