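"""Exception hierarchy for the focuslib toolkit.

Exit-code mapping used by the CLI: ConfigError -> 2,
EngineNotFoundError/EnvironmentError -> 3, data errors -> 4.
"""


class FocusLibError(Exception):
    """Base class for all focuslib errors."""


class InputFileError(FocusLibError):
    """A required input file is missing or unreadable."""


class EmptyInputError(FocusLibError):
    """An input that must contain at least one record is empty."""


class FormatError(FocusLibError):
    """A file is syntactically corrupt; the message names the record."""


class ParseError(FocusLibError):
    """A molecule string could not be parsed."""


class RoleError(FocusLibError):
    """A building block was used in a role it does not have."""


class ContractError(FocusLibError):
    """An operation precondition was violated by the caller."""


class ConfigError(FocusLibError):
    """Pipeline configuration is invalid; the message lists fields."""


class EngineNotFoundError(FocusLibError):
    """The external docking engine binary is not on PATH."""


class EngineRunError(FocusLibError):
    """The external docking engine exited nonzero; stderr is attached."""


class EmbeddingError(FocusLibError):
    """3D embedding failed for a species."""


class FitError(FocusLibError):
    """Nonlinear regression did not converge."""


class DegenerateWindowError(FocusLibError):
    """An assay normalization window (total-NSB or stimulated-basal) is empty."""
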