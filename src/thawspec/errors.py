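"""Exception hierarchy for thawspec."""


class ThawspecError(Exception):
    """Base class for all thawspec errors."""


class SchemaError(ThawspecError):
    """A required CSV column is missing or malformed."""


class ValidationError(ThawspecError):
    """Input data violate a domain invariant (e.g. non-positive resistance)."""


class GridError(ThawspecError):
    """Frequency grids are inconsistent under the strict grid policy."""


class CalibrationError(ThawspecError):
    """A requested Py target is not achievable with the given base parameters."""


class StabilityError(ThawspecError):
    """Explicit thermal stepping would be unstable; use a smaller dt."""


class TrainingError(ThawspecError):
    """Classifier training diverged (non-finite loss)."""


class DependencyError(ThawspecError):
    """A pipeline stage was requested without the inputs it depends on."""
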