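"""Typed exceptions used across the package.

Every failure mode that callers may want to handle programmatically gets its
own class; all inherit from :class:`PancbnError` so ``except PancbnError``
catches everything the package raises deliberately.
"""


class PancbnError(Exception):
    """Base class for all pancbn errors."""


class ExtractionError(PancbnError):
    """Inconsistent literature extraction (e.g. more significant than included)."""


class UndefinedVariableError(PancbnError):
    """A weight was requested for a variable never included in any study."""


class EmptySynthesisError(PancbnError):
    """Evidence synthesis attempted on an empty study pool."""


class ConfigurationError(PancbnError):
    """Invalid or contradictory model configuration."""


class StructureError(ConfigurationError):
    """Invalid network structure (cycle, dangling arc, duplicate node)."""


class DegenerateNodeError(ConfigurationError):
    """A ranked node with fewer than two states."""


class ParameterError(PancbnError):
    """Invalid distribution parameter (e.g. non-positive variance)."""


class ZeroProbabilityEvidenceError(PancbnError):
    """Observed evidence has probability zero under the model."""


class RecordValidationError(PancbnError):
    """A patient record contains an illegal state label or field value."""


class UndefinedAUCError(PancbnError):
    """AUC requested on input containing only one outcome class."""


class SchemaError(PancbnError):
    """A CSV/YAML input does not match the expected schema."""
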