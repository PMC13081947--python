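"""Exception hierarchy shared across the toolkit.

Exit-code mapping used by the CLI: parameter errors -> 2, data/format
errors -> 3, missing upstream dependencies -> 4.
"""


class ModuleScopeError(Exception):
    """Base class for all toolkit errors."""

    exit_code = 1


class ParameterError(ModuleScopeError):
    """An argument value violates an operation's contract."""

    exit_code = 2


class FormatError(ModuleScopeError):
    """An input file is malformed or internally inconsistent."""

    exit_code = 3


class DataError(ModuleScopeError):
    """Input data is structurally valid but unusable (e.g. too few cells)."""

    exit_code = 3


class StateError(ModuleScopeError):
    """An operation was called before its prerequisites were computed."""

    exit_code = 3


class DependencyError(ModuleScopeError):
    """A pipeline stage is missing the outputs of an upstream stage."""

    exit_code = 4
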