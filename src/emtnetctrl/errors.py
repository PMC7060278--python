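"""Exception hierarchy shared by all pipeline stages."""


class EmtNetCtrlError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EmtNetCtrlError):
    """A parameter or configuration value violates its documented bounds."""


class InputError(EmtNetCtrlError):
    """An input value (count, table, universe) violates a precondition."""


class DesignError(EmtNetCtrlError):
    """The experimental design is unusable (e.g. a condition with < 2 replicates)."""


class GeneLookupError(EmtNetCtrlError, KeyError):
    """A gene or condition id is not present in the study."""


class FormatError(EmtNetCtrlError):
    """A file or in-memory structure does not conform to its dialect."""


class ParseError(FormatError):
    """A malformed line in an input file; carries the 1-based line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        where = ""
        if path is not None:
            where = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + where)
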