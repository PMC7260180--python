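"""Exception hierarchy with machine-greppable error classes.

Every exception carries an ``error_class`` token that the CLI prints on a
single stderr line (``ERROR:<CLASS>: message``) so wrapping pipelines can
dispatch on failures without parsing prose.
"""


class TolOrfError(Exception):
    """Base class for all tool errors."""

    error_class = "TOLORF_ERROR"


class InputNotFoundError(TolOrfError):
    error_class = "INPUT_NOT_FOUND"


class ValidationError(TolOrfError):
    """An input sequence violates an ORF invariant."""

    error_class = "VALIDATION"


class NonAcgtError(ValidationError):
    error_class = "NON_ACGT"


class BadLengthError(ValidationError):
    error_class = "BAD_LENGTH"


class MissingStartError(ValidationError):
    error_class = "MISSING_START"


class MissingStopError(ValidationError):
    error_class = "MISSING_STOP"


class InternalStopError(ValidationError):
    error_class = "INTERNAL_STOP"


class DuplicateIdError(ValidationError):
    error_class = "DUPLICATE_ID"


class ConfigError(TolOrfError):
    error_class = "CONFIG"


class SplitOutOfRangeError(TolOrfError):
    error_class = "SPLIT_OUT_OF_RANGE"


class ShuffleInfeasibleError(TolOrfError):
    """No permutation can satisfy the adjacency constraint (or none was found
    within the attempt budget)."""

    error_class = "SHUFFLE_INFEASIBLE"


class AdjacencyError(TolOrfError):
    """An element ordering handed to the assembler violates the constraint."""

    error_class = "ADJACENCY"


class IncompleteCoverageError(TolOrfError):
    error_class = "COVERAGE_INCOMPLETE"
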