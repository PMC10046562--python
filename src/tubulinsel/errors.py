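"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`TubulinSelError`, so callers (and
the CLI) can catch one base type and still report precise failure modes.
"""


class TubulinSelError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(TubulinSelError):
    """A delimited-text table is missing a required column or has a bad dtype."""


class IntegrityError(TubulinSelError):
    """Table content violates an invariant (e.g. incomplete species triple)."""


class AlignmentLengthError(TubulinSelError):
    """Pre-aligned sequences do not share a common length."""


class LookupFixtureError(TubulinSelError, KeyError):
    """Unknown packaged-fixture name or context."""


class GenerationError(TubulinSelError):
    """Synthetic-data generation was asked to produce nothing or is invalid."""


class AssemblyError(TubulinSelError):
    """A snapshot free energy cannot be assembled (missing component)."""


class WindowError(TubulinSelError):
    """Time-window selection left a run without snapshots or was ill-posed."""


class CoverageError(TubulinSelError):
    """An isotype with nonzero abundance has no binding-energy estimate."""


class WeightingError(TubulinSelError):
    """All effective Boltzmann weights vanished."""


class DomainError(TubulinSelError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""


class InputError(TubulinSelError):
    """Input data insufficient or malformed for the requested fit/analysis."""


class AlphabetError(TubulinSelError, ValueError):
    """A residue character is not a standard amino-acid letter or gap."""


class InsufficientDataError(TubulinSelError):
    """Fewer shared observations than the minimum for a statistic."""


class PipelineStageError(TubulinSelError):
    """Wraps a stage failure inside the end-to-end pipeline with its stage name."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
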