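"""Exception hierarchy.

Validation-type failures (bad files, incoherent tables, malformed queries)
derive from :class:`ValidationError` so the CLI can map them to exit code 2;
everything else maps to exit code 1.
"""


class CredalError(Exception):
    """Base class for all package errors."""


class ValidationError(CredalError):
    """Input failed a structural or semantic validity check."""


class StructuralError(ValidationError):
    """Malformed object: wrong lengths, unknown names, duplicate labels."""


class CoherenceError(ValidationError):
    """Probability intervals admit no distribution (sum constraints broken)."""


class FeasibilityError(ValidationError):
    """A credal-set polytope (intervals + orderings) is empty."""


class SizeGuardError(ValidationError):
    """A combinatorial operation was asked to exceed its configured cap."""


class ParseError(ValidationError):
    """A file could not be parsed against the package's JSON dialect."""

    def __init__(self, message: str, location: str = "") -> None:
        self.location = location
        super().__init__(f"{message}" + (f" (at {location})" if location else ""))


class ScenarioError(ValidationError):
    """A scenario specification references unknown or contradictory items."""


class ConditioningError(CredalError):
    """Evidence has probability zero for every admissible distribution."""


class FitError(CredalError):
    """Classifier training is impossible on the given cohort."""


class PredictionError(CredalError):
    """A record cannot be scored by a fitted classifier."""


class EvaluationError(CredalError):
    """A labelled cohort cannot be used for accuracy evaluation."""


class ConstructionError(CredalError):
    """A synthetic-cohort specification is infeasible."""
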