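"""Exception hierarchy shared across the package."""


class CoffoError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgument(CoffoError, ValueError):
    """An argument violates a documented precondition."""


class InvalidConfiguration(CoffoError, ValueError):
    """An optimizer or experiment configuration is inconsistent."""


class BudgetExhausted(CoffoError, RuntimeError):
    """An objective evaluation was requested past the FFE limit."""


class DataError(CoffoError, ValueError):
    """A dataset file could not be parsed or is structurally unusable."""


class InvalidDataset(DataError):
    """A dataset parses but violates an invariant (e.g. a single class)."""
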