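"""Exception hierarchy."""


class ChloroquenchError(Exception):
    """Base class for all package errors."""


class SchemaError(ChloroquenchError):
    """A file or configuration is missing a required field or column."""


class NoPlantError(ChloroquenchError):
    """Segmentation found no foreground object in an image."""


class CoverageError(ChloroquenchError):
    """A trace or series does not cover a requested time point."""
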