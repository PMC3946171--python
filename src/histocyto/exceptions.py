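"""Exception hierarchy for histocyto.

All package-specific errors derive from :class:`HistocytoError` so callers can
catch the whole family with one clause; the subclasses distinguish parameter
problems (bad user input) from runtime failures (degenerate data, failed
generation).
"""


class HistocytoError(Exception):
    """Base class for all histocyto errors."""


class ParameterError(HistocytoError, ValueError):
    """A configuration or argument value violates its documented constraints."""


class ValidationError(HistocytoError, ValueError):
    """Input data fails a structural check (shape mismatch, non-finite values...)."""


class TrainingError(HistocytoError, RuntimeError):
    """Classifier training cannot proceed (e.g. a single-class labeled set)."""


class GenerationError(HistocytoError, RuntimeError):
    """Synthetic data could not be generated under the requested constraints."""


class QueryError(HistocytoError, RuntimeError):
    """Active-learning query selection failed (e.g. empty candidate pool)."""


class ConflictError(HistocytoError, ValueError):
    """An already-labeled cell was re-labeled with a contradictory label."""


class LookupError_(HistocytoError, KeyError):
    """A queried cell id is unknown to the oracle or ground truth."""


class CapabilityError(HistocytoError, RuntimeError):
    """A requested optional capability is unavailable in this installation."""


class FormatError(HistocytoError, ValueError):
    """A file on disk does not match the expected on-disk format."""


class AssemblyError(HistocytoError, ValueError):
    """Feature row sets cannot be joined into a single table."""
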