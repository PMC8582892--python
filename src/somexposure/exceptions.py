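"""Exception hierarchy for the somexposure pipeline."""


class SomexposureError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(SomexposureError, ValueError):
    """A configuration value is out of its valid range or inconsistent."""


class NoDataError(SomexposureError, ValueError):
    """An operation received no usable observations (e.g. zero stations with
    values for an interpolation target); the caller decides the fallback."""


class UnimputableColumnError(SomexposureError, ValueError):
    """A column has too few observed values to take part in chained imputation."""


class ConstantColumnError(SomexposureError, ValueError):
    """A continuous column has zero variance and cannot be z-scored."""


class UnknownLevelError(SomexposureError, ValueError):
    """A nominal value outside the declared level set was seen at transform time."""


class DegenerateLabelsError(SomexposureError, ValueError):
    """Supervised training requires both outcome classes to be present."""


class NoYLayerError(SomexposureError, ValueError):
    """Class prediction was requested from a model without an outcome layer."""
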