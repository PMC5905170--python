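"""Exception hierarchy for the pipeline."""


class PlasmaQuantError(Exception):
    """Base class for all pipeline errors."""


class FormatError(PlasmaQuantError):
    """A table does not conform to the documented TSV dialect."""


class DesignError(PlasmaQuantError):
    """The study design is invalid or cannot support the requested split."""


class ConfigError(PlasmaQuantError):
    """A configuration object is internally contradictory."""


class CalibrationError(PlasmaQuantError):
    """Retention-time calibration cannot be fitted for a sample."""


class NormalizationError(PlasmaQuantError):
    """ppm normalization failed (e.g. an all-zero sample column)."""


class StatsError(PlasmaQuantError):
    """A statistical routine received unusable input."""
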