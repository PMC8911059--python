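"""Exception hierarchy shared by all pipeline stages."""


class SpectroinflameError(Exception):
    """Base class for all package errors."""


class AxisError(SpectroinflameError):
    """Wavenumber axis is non-monotone, non-uniform, or incompatible."""


class ShapeError(SpectroinflameError):
    """Array lengths / grid shapes do not line up."""


class FormatError(SpectroinflameError):
    """A file does not match the declared on-disk dialect."""


class RangeError(SpectroinflameError):
    """A wavenumber window misses the axis entirely."""


class ConfigError(SpectroinflameError):
    """Invalid configuration value."""


class DegenerateSpectrumError(SpectroinflameError):
    """Operation undefined on a constant / zero-variance spectrum."""


class DegenerateError(SpectroinflameError):
    """Statistic undefined for the given input (zero variance, zero rank...)."""


class EmptyTissueError(SpectroinflameError):
    """Background removal flagged every pixel."""


class SampleSizeError(SpectroinflameError):
    """Too few samples for the requested statistic or split."""


class ClassAbsentError(SpectroinflameError):
    """A required class label is missing from the data."""


class FoldError(SpectroinflameError):
    """A cross-validation fold lost an entire class."""


class IntegrityError(SpectroinflameError):
    """A stored artifact no longer matches its manifest hash."""
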