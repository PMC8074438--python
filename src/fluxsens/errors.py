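"""Exception hierarchy.

All fluxsens-specific failures derive from :class:`FluxsensError` so callers
can catch the package's errors without masking programming mistakes.
"""


class FluxsensError(Exception):
    """Base class for all fluxsens errors."""


class ModelFormatError(FluxsensError):
    """A model file could not be parsed under the requested dialect."""


class ModelValidationError(FluxsensError):
    """A model violates a structural invariant (bounds order, missing objective, ...)."""


class BoundOrderError(ModelValidationError):
    """A requested lower bound exceeds the reaction's upper bound."""


class EngineError(FluxsensError):
    """The LP solver failed for a reason unrelated to feasibility."""


class CapabilityError(FluxsensError):
    """A request exceeds what the implementation supports (dimension, memory, backend)."""


class CapacityError(CapabilityError):
    """Available memory cannot hold even a single design row."""


class DegenerateOutputError(FluxsensError):
    """The model output is constant across the design; sensitivity is undefined."""


class AlignmentError(FluxsensError):
    """An output vector does not align with its design."""


class EvaluationError(FluxsensError):
    """A design row failed to evaluate under an 'abort' failure policy."""


class ConfigurationError(FluxsensError):
    """A pipeline configuration names something that cannot be resolved."""
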