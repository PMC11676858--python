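"""Exception hierarchy shared across the package."""


class NetPropError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NetPropError):
    """A file does not conform to the expected dialect (missing column, short line...)."""


class BuildError(NetPropError):
    """Network assembly produced an unusable result (e.g. zero surviving edges)."""


class OrderMismatchError(NetPropError):
    """Two objects that must share a node order do not; silent reindexing is never done."""


class ConfigError(NetPropError):
    """A pipeline configuration value is out of its valid range."""
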