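"""Exception hierarchy for rhodoquant.

Every error raised by the package derives from :class:`RhodoquantError`,
so callers can catch one type at a pipeline boundary. Subclasses mark the
contract that was violated rather than the module that raised it.
"""


class RhodoquantError(Exception):
    """Base class for all rhodoquant errors."""


class InvalidInputError(RhodoquantError, ValueError):
    """Input violates a precondition (empty sequence, empty table, bad value)."""


class InvalidCharacterError(InvalidInputError):
    """A sequence contains a symbol outside the amino-acid alphabet."""

    def __init__(self, symbol: str, where: str = ""):
        self.symbol = symbol
        msg = f"invalid character {symbol!r}"
        if where:
            msg += f" in {where}"
        super().__init__(msg)


class UndefinedIdentityError(RhodoquantError, ZeroDivisionError):
    """Percent identity requested with a zero denominator."""


class ConfigurationError(RhodoquantError, ValueError):
    """A configuration object is internally inconsistent or unusable."""


class FormatError(RhodoquantError, ValueError):
    """A tabular/FASTA input does not match the expected schema."""


class NotFoundError(RhodoquantError, KeyError):
    """A requested id (sample, gene, OTU member) is absent."""


class DegenerateNormalizerError(RhodoquantError, ZeroDivisionError):
    """A normalizing denominator (housekeeping coverage, 16S copies) is zero."""


class MismatchError(RhodoquantError, ValueError):
    """Two results that must refer to the same sample/assay do not."""


class InvalidCurveError(RhodoquantError, ValueError):
    """A qPCR standard curve cannot be fit (too few or collinear points)."""


class InvalidSpecError(RhodoquantError, ValueError):
    """A synthetic community specification violates its invariants."""


class PipelineStageError(RhodoquantError, RuntimeError):
    """A pipeline stage failed; carries stage name and input context."""

    def __init__(self, stage: str, message: str, input_path: str | None = None):
        self.stage = stage
        self.input_path = input_path
        ctx = f" [input: {input_path}]" if input_path else ""
        super().__init__(f"stage {stage!r} failed{ctx}: {message}")
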