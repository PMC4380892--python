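"""Exception hierarchy.

Every error raised by the package derives from :class:`MorphoscoreError`, so
callers (and the CLI) can distinguish package failures from programming
errors.  The subclasses map onto the three failure families the CLI reports:
input/format problems, statistical failures, and model-schema problems.
"""


class MorphoscoreError(Exception):
    """Base class for all package errors."""


# --- input / format problems -------------------------------------------------

class FormatError(MorphoscoreError):
    """A required column or structural element is missing from the input."""


class ParseError(MorphoscoreError):
    """A cell could not be parsed; the message names the row."""


class IntegrityError(MorphoscoreError):
    """The input violates a data invariant (duplicate ids, t3 < t2, ...)."""


class InvalidSpecError(MorphoscoreError):
    """A simulation specification is self-inconsistent."""


class GenerationError(MorphoscoreError):
    """The synthetic generator could not satisfy its constraints."""


# --- statistical failures ----------------------------------------------------

class InsufficientDataError(MorphoscoreError):
    """Too few non-missing values for the requested computation."""


class InsufficientVariationError(MorphoscoreError):
    """The values carry too little variation (e.g. a constant sample)."""


class DegenerateSampleError(MorphoscoreError):
    """A sample with zero variance where a spread is required."""


class DegenerateCompartmentError(MorphoscoreError):
    """A compartment ended up empty; a structural merge is advised."""


class AmbiguousRankingError(MorphoscoreError):
    """Compartment rates are tied three ways; no deterministic ranking."""


class NonIdentifiableError(MorphoscoreError):
    """The logistic likelihood has no finite maximiser (separation,
    collinearity, a single outcome class, or a constant predictor)."""


class ConvergenceError(MorphoscoreError):
    """The iterative fit did not converge within the iteration budget."""


class NoModelError(MorphoscoreError):
    """Model selection eliminated every candidate predictor."""


class IncompleteRecordError(MorphoscoreError):
    """A record lacks an individual score the frozen model requires."""


class DegenerateQuarterError(MorphoscoreError):
    """A score quartile holds no records (massive ties)."""


class DegenerateTableError(MorphoscoreError):
    """A contingency table with an all-zero row or column."""


class UndefinedCurveError(MorphoscoreError):
    """ROC analysis needs both outcome classes."""


# --- model schema problems ---------------------------------------------------

class SchemaVersionError(MorphoscoreError):
    """The model document declares an unsupported schema version."""


class ModelValidationError(MorphoscoreError):
    """The model document is structurally invalid; the message lists the
    failing fields."""
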