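"""Exception hierarchy for the isomirome package."""


class IsomiromeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(IsomiromeError):
    """An invalid simulation or run configuration."""


class InputError(IsomiromeError):
    """Invalid values passed to an analysis operation."""


class ParseError(IsomiromeError):
    """A malformed input file; carries the offending line where known."""


class ClassificationError(IsomiromeError):
    """An isomiR sequence that cannot be placed on its canonical axis."""
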