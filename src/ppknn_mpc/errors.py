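"""Exception hierarchy for the MPC simulation stack."""


class MPCError(Exception):
    """Base class for all protocol-level errors."""


class FieldConfigError(MPCError):
    """Invalid prime, evaluation points, or a width the field cannot mask."""


class RangeError(MPCError):
    """A secret or public operand lies outside the valid range."""


class WidthError(RangeError):
    """An integer does not fit the declared bit width."""


class InsufficientSharesError(MPCError):
    """Fewer shares than degree_bound + 1 were offered for reconstruction.

    Raised instead of ever returning a wrong value: a threshold violation
    must be a visible failure, not silent garbage.
    """


class EngineError(MPCError):
    """Mismatched party counts, degree overflow, or incompatible fields."""


class RandomnessError(MPCError):
    """Joint randomness generation failed repeatedly (degenerate draws)."""


class TieError(MPCError):
    """Strict-mode top-k selection exhausted all bit positions without
    selecting exactly k items (tied or all-zero boundary values).

    The message never names data values, only the fact of failure.
    """


class ParameterError(MPCError):
    """An out-of-range protocol parameter such as k."""


class PartitionError(MPCError):
    """Owner datasets do not form a disjoint, covering partition."""


class FormatError(MPCError):
    """Malformed dataset/query/share file; carries the offending row."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)
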