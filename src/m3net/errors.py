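"""Exception types shared across the package."""


class M3NetError(Exception):
    """Base class for package errors."""


class ConfigurationError(M3NetError, ValueError):
    """An invalid configuration value or violated config invariant."""


class GeometryError(M3NetError, ValueError):
    """A crop or resampling request that falls outside the image."""


class ShapeError(M3NetError, ValueError):
    """An array with the wrong number of dimensions or channels."""


class DataError(M3NetError, ValueError):
    """Invalid dataset structure (empty split, too few cases, ...)."""
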