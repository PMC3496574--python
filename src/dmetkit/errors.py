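"""Exception taxonomy shared across the package.

Numeric domain violations (negative counts, p-values outside (0, 1], ...)
raise plain :class:`ValueError`; everything tied to files, configuration or
capacity uses one of the classes below so callers (and the CLI) can map each
failure class to a distinct exit status.
"""


class DmetError(Exception):
    """Base class for all package-specific errors."""


class ParseError(DmetError):
    """A file or cell could not be interpreted as DMET genotype data."""


class ValidationError(DmetError):
    """Structurally parseable input that violates a dataset invariant."""


class ConfigurationError(DmetError):
    """An invalid analysis configuration (bad class selection, sort key...)."""


class CapacityError(DmetError):
    """An exact enumeration would exceed the configured table budget."""


class UnknownProbeError(DmetError, KeyError):
    """A requested probe identifier is absent from the dataset."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__(f"unknown probe id(s): {', '.join(self.missing)}")
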