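"""Exception hierarchy.

Every error raised by the package derives from :class:`CrossnetError` so
callers (and the CLI) can catch one base class and map it to an exit code.
"""


class CrossnetError(Exception):
    """Base class for all crossnet errors."""


class InputError(CrossnetError):
    """A file could not be read or does not follow the expected format."""


class SchemaError(InputError):
    """A tabular input is missing required columns."""


class EmptyInteractomeError(CrossnetError):
    """No edges survived parsing/cleaning; the background graph is empty."""


class EmptySetError(CrossnetError):
    """A gene set is empty (after filtering / intersection with the graph)."""


class SetNotFoundError(CrossnetError, KeyError):
    """A named record (e.g. a GMT gene set) was not found in a file."""


class ParameterError(CrossnetError, ValueError):
    """An argument is outside its documented domain."""


class ConfigError(CrossnetError):
    """A run configuration is invalid (unknown key, bad enum, missing path)."""
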