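"""Exception hierarchy.

Every error raised by detbelt derives from :class:`DetBeltError` so callers
(and the CLI) can distinguish failure stages without string matching.
"""


class DetBeltError(Exception):
    """Base class for all detbelt errors."""


class EmptyStructureError(DetBeltError):
    """The input stream contained no parseable ATOM/HETATM record."""


class InvalidThicknessError(DetBeltError):
    """A half-thickness REMARK was found but its value is unusable."""


class ThicknessUnavailableError(DetBeltError):
    """No half-thickness could be recovered and no override was given."""


class NoHeavyAtomsError(DetBeltError):
    """The structure contains no protein heavy atoms."""


class NoExposedAtomsError(DetBeltError):
    """No transmembrane atom passed the solvent-exposure filter."""


class UnknownDetergentError(DetBeltError):
    """A belt-spec identifier did not resolve in the database."""

    def __init__(self, query: str, suggestions: list[str] | None = None):
        self.query = query
        self.suggestions = suggestions or []
        msg = f"unknown detergent {query!r}"
        if self.suggestions:
            msg += " (did you mean: " + ", ".join(self.suggestions) + "?)"
        super().__init__(msg)


class DatabaseValidationError(DetBeltError):
    """The detergent database failed a consistency check."""


class SpecValidationError(DetBeltError):
    """The belt specification (detergent/count list) is invalid."""


class FixtureError(DetBeltError):
    """A synthetic fixture could not be built under its spacing constraints."""


class BeltComputationError(DetBeltError):
    """A belt-pipeline stage failed; the message names the stage."""
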