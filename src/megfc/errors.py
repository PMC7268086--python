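"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`MegfcError` so callers can abort a
subject with the stage name attached (see :mod:`megfc.pipeline`).
"""


class MegfcError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MegfcError, ValueError):
    """Invalid parameter or configuration value."""


class ValidityError(MegfcError, ValueError):
    """A domain-object invariant was breached (e.g. coupling >= 0.95)."""


class GeometryError(MegfcError, ValueError):
    """A source location falls outside the conductor model."""


class InputError(MegfcError, ValueError):
    """Input data violates a precondition (too short, too few epochs...)."""


class DataSufficiencyError(InputError):
    """Not enough clean data to satisfy a selection requirement."""


class DegenerateVoxelError(MegfcError):
    """Lead field at a voxel has no usable (rank >= 2) sensitivity."""


class DegenerateDataError(MegfcError, ValueError):
    """A statistic is undefined for the data (zero variance, constant input)."""


class FormatError(MegfcError, ValueError):
    """A file is not a valid recording/epoch container."""


class SchemaError(MegfcError, ValueError):
    """A tabular input is missing required columns or rows."""
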