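"""Exception hierarchy for hdflow.

All exceptions derive from :class:`HDFlowError` so callers can catch the
package's failures with a single except clause; the subclasses mirror the
stages of the pipeline (parsing, geometry, splitting, training, evaluation).
"""


class HDFlowError(Exception):
    """Base class for all hdflow errors."""


class EventParseError(HDFlowError, ValueError):
    """A row of an event file could not be parsed."""


class BoundsError(HDFlowError, ValueError):
    """An event coordinate falls outside the sensor."""


class WindowError(HDFlowError, ValueError):
    """An invalid (inverted or empty) time window was supplied."""


class ArgumentError(HDFlowError, ValueError):
    """A plain invalid-argument failure (non-positive block size, ...)."""


class DimensionError(HDFlowError, ValueError):
    """Two binary vectors or grids have incompatible dimensions."""


class ConfigError(HDFlowError, ValueError):
    """An encoder or simulation configuration is internally inconsistent."""


class TrainingError(HDFlowError, ValueError):
    """Training was requested for a class with no samples."""


class SplitError(HDFlowError, ValueError):
    """A dataset split specification cannot be satisfied."""


class EvaluationError(HDFlowError, ValueError):
    """The test set contains a class unknown to the model."""
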