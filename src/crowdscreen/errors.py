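"""Exception hierarchy for crowdscreen.

All package-specific failures derive from :class:`CrowdScreenError` so
callers can catch one base class at CLI boundaries.
"""


class CrowdScreenError(Exception):
    """Base class for all crowdscreen errors."""


class FormatError(CrowdScreenError):
    """Input file cannot be parsed in the declared format."""


class ValidationError(CrowdScreenError):
    """Input is well-formed but violates a domain constraint."""


class IntegrityError(CrowdScreenError):
    """An event log or project file violates its invariants."""


class InsufficientTrainingError(CrowdScreenError):
    """Training requested with fewer than one example per class."""


class ConsistencyError(CrowdScreenError):
    """Scores and pool membership disagree."""


class OwnershipError(CrowdScreenError):
    """A label was submitted for a record allocated to another user."""


class DuplicateLabelError(CrowdScreenError):
    """A terminal label was submitted twice for the same record."""


class VectorizationError(CrowdScreenError):
    """Text could not be turned into features (e.g. empty vocabulary)."""


class UndefinedMetricError(CrowdScreenError):
    """The requested metric is undefined for this screening trace."""


class DegenerateCurveError(CrowdScreenError):
    """Metric undefined because the corpus has zero or only relevant records."""


class GenerationError(CrowdScreenError):
    """A synthetic fixture could not be generated under the given spec."""
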