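"""Exception hierarchy shared across the pipeline stages."""


class FlavorlexError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(FlavorlexError):
    """An input table is missing a mandatory column or is otherwise malformed."""


class ValidationError(FlavorlexError):
    """An argument or record violates a stated precondition or invariant."""


class FormatError(FlavorlexError):
    """A flat file does not conform to its declared line format."""


class OOVLookupError(FlavorlexError):
    """An out-of-vocabulary token was looked up under the strict policy."""


class LabelConflictError(FlavorlexError):
    """A token type inherits contradictory labels from two different lemmas."""


class TaggerError(FlavorlexError):
    """The POS provider failed on a sentence; carries review/sentence context."""

    def __init__(self, message: str, review_id: str | None = None,
                 sentence_index: int | None = None):
        super().__init__(message)
        self.review_id = review_id
        self.sentence_index = sentence_index


class StageError(FlavorlexError):
    """A pipeline stage failed; wraps the underlying error with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


class UntrainedModelError(FlavorlexError):
    """Prediction was requested from a model that has not been fitted."""
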