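"""Exception hierarchy shared across the pipeline."""


class MirqpcrError(Exception):
    """Base class for all package errors."""


class StructureError(MirqpcrError):
    """Malformed table structure: duplicate ids, missing required columns."""


class CtParseError(MirqpcrError):
    """A cell could not be interpreted as a Ct value or undetermined token."""


class ValidationError(MirqpcrError):
    """A parsed value violates a domain invariant (range, vocabulary)."""


class SeparationError(MirqpcrError):
    """Logistic fit failed because classes are perfectly separable."""


class SingularDesignError(MirqpcrError):
    """Design matrix is rank-deficient (e.g. duplicated feature)."""
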