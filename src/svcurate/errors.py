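"""Exception hierarchy shared across svcurate."""


class SvcurateError(Exception):
    """Base class for svcurate-specific errors."""


class DegenerateInputError(SvcurateError):
    """An input set is empty or otherwise too degenerate to compute on."""


class ConfigError(SvcurateError):
    """A curation project configuration is missing or invalid."""


class FormatError(SvcurateError):
    """A file does not conform to its expected format."""
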