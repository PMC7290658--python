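"""Exception hierarchy.

Each externally visible failure mode gets its own class so the CLI can map
them to distinct exit messages and callers can catch precisely.
"""


class MyofuseError(Exception):
    """Base class for all package errors."""


class ParameterError(MyofuseError, ValueError):
    """Invalid parameter value or combination."""


class CrowdedFieldError(MyofuseError):
    """Rejection sampling could not place all requested objects."""


class MissingInputError(MyofuseError, FileNotFoundError):
    """A referenced input path does not exist."""


class MissingChannelError(MyofuseError):
    """The channel map asks for a channel the image does not have."""


class MissingPixelSizeError(MyofuseError):
    """No pixel size in sidecar, TIFF tags, or explicit argument."""


class SchemaError(MyofuseError):
    """A tabular input lacks required columns or has invalid values."""


class OverflowAtBitDepthError(MyofuseError):
    """Rendered intensities exceed the representable range and clipping is off."""
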