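"""Exception hierarchy shared across the pipeline."""


class MitofociError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(MitofociError, ValueError):
    """Invalid simulation or analysis parameter."""


class FormatError(MitofociError, ValueError):
    """Malformed input file (image, ROI table, annotation, plate)."""


class EstimationError(MitofociError, RuntimeError):
    """Background or other estimate cannot be computed."""


class ClassificationError(MitofociError, RuntimeError):
    """Per-fiber classification cannot be performed (e.g. dead channel)."""


class CurveError(MitofociError, RuntimeError):
    """Standard curve cannot be fitted (e.g. non-negative slope)."""


class QCError(MitofociError, RuntimeError):
    """Quality-control gate blocks a downstream computation."""


class StatisticsError(MitofociError, ValueError):
    """Statistical test preconditions not met."""
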