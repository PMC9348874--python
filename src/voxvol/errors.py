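"""Exception hierarchy shared across the package."""


class VoxVolError(Exception):
    """Base class for all voxvol errors."""


class ParseError(VoxVolError):
    """A structure or element file could not be parsed."""


class ParameterError(VoxVolError):
    """A calculation parameter is invalid or inconsistent."""


class ResourceLimitError(VoxVolError):
    """The requested calculation exceeds a configured resource cap."""
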