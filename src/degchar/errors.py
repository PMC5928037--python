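"""Exception types shared across the package."""


class DegcharError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DegcharError):
    """A simulation or run configuration field is invalid."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class InputError(DegcharError):
    """An input file or in-memory input violates a contract."""


class GenerationError(DegcharError):
    """Synthetic-data generation produced an inconsistent artifact."""
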