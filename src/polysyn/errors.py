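"""Exception hierarchy shared across the package."""


class PolysynError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PolysynError, ValueError):
    """A file or dataset violates the expected on-disk format."""


class SchemaError(FormatError):
    """A JSON document violates the synapse-record schema.

    The message names the JSON path of the offending field.
    """


class BoundsError(PolysynError, IndexError):
    """A point coordinate lies outside the associated volume."""


class ShapeError(PolysynError, ValueError):
    """Paired grids disagree in shape."""


class SizeError(PolysynError, ValueError):
    """An input volume is smaller than an operation's receptive field."""


class ConfigError(PolysynError, ValueError):
    """A configuration value or combination of arguments is invalid."""


class DegenerateTrainingError(PolysynError, ValueError):
    """Training data does not contain both classes."""


class GenerationError(PolysynError, RuntimeError):
    """Phantom generation could not satisfy its placement constraints."""
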