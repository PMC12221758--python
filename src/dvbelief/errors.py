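"""Exception types shared across the package."""


class DVBeliefError(Exception):
    """Base class for package-specific errors."""


class InvalidArgumentError(DVBeliefError, ValueError):
    """An argument is outside its documented domain."""


class ConvergenceError(DVBeliefError, RuntimeError):
    """An iterative procedure failed to converge."""


class OutOfSupportError(InvalidArgumentError):
    """A value falls outside the support of a gridded belief."""


class DegeneratePriorError(DVBeliefError, ValueError):
    """A conditioning step produced a zero-mass belief."""


class DegenerateColumnError(DVBeliefError, ValueError):
    """A regression column is constant within a block."""

    def __init__(self, column: str, block=None):
        self.column = column
        self.block = block
        msg = f"column {column!r} is constant"
        if block is not None:
            msg += f" within block {block!r}"
        super().__init__(msg)


class CollinearityError(DVBeliefError, ValueError):
    """The design matrix is rank deficient."""


class InvalidSpecError(DVBeliefError, ValueError):
    """A model/agent specification is inconsistent with the data."""


class InsufficientDataError(DVBeliefError, ValueError):
    """Not enough observations to carry out the computation."""


class SchemaError(DVBeliefError, ValueError):
    """A trial table violates the expected schema."""
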