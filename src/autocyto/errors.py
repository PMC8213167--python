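"""Exception hierarchy.

Every error raised by the package derives from :class:`AutoCytoError` so callers
can catch the package's failures with a single except clause.
"""


class AutoCytoError(Exception):
    """Base class for all package errors."""


class StructuralError(AutoCytoError):
    """Population tree structure violated (unknown parent, cycle, ...)."""


class ContainmentError(AutoCytoError):
    """A population's event index is not contained in its parent's index."""


class NotFoundError(AutoCytoError):
    """Requested document does not exist in the persistence store."""


class MigrationError(AutoCytoError):
    """Stored document schema version does not match this package version."""


class FormatError(AutoCytoError):
    """File does not conform to the expected on-disk format (e.g. FCS header)."""


class IntegrityError(AutoCytoError):
    """File parses but its internal bookkeeping is inconsistent ($TOT, truncation)."""


class SchemaError(AutoCytoError):
    """Channel/label mismatch between two objects that must share a schema."""


class ParameterError(AutoCytoError):
    """Invalid parameter value passed to an operation."""


class NumericalError(AutoCytoError):
    """Numerical failure (singular spillover matrix, non-finite condition number)."""


class DegenerateColumnError(AutoCytoError):
    """A column required to have positive variance is constant."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"column {column!r} has zero variance")


class InsufficientDataError(AutoCytoError):
    """Too few events for the requested fit."""


class DegenerateHullError(AutoCytoError):
    """Fewer than 3 non-collinear points: no 2-D convex hull exists."""


class FitError(AutoCytoError):
    """Model fit failed to converge."""


class ConfigurationError(AutoCytoError):
    """Invalid run/gate/search configuration."""


class ContractError(AutoCytoError):
    """A plugin violated its declared signature or output contract."""


class RegistrationError(AutoCytoError):
    """Landmark registration could not pair any landmarks."""


class LabellingError(AutoCytoError):
    """Training populations overlap: each event must carry exactly one label."""


class ModellingError(AutoCytoError):
    """Endpoint unsuitable for the requested model (e.g. single class)."""
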