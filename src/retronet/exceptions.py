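"""Exception hierarchy for retronet.

Every error the library raises deliberately derives from :class:`RetronetError`
so callers (and the CLI) can distinguish pipeline failures from programming
errors.
"""


class RetronetError(Exception):
    """Base class for all retronet errors."""


class ConfigurationError(RetronetError, ValueError):
    """A simulation or run configuration violates one of its invariants."""


class FormatError(RetronetError, ValueError):
    """An input file does not conform to the expected dialect."""


class UndefinedDistanceError(RetronetError, ValueError):
    """A pairwise distance is undefined (no comparable sites, or p >= 1)."""


class SaturationError(RetronetError, ValueError):
    """K2P log argument is non-positive; the pair is saturated."""


class ModularityUndefinedError(RetronetError, ValueError):
    """Modularity requested on a graph with no edges."""


class PartitionMismatchError(RetronetError, ValueError):
    """Two partitions do not cover the same identifier set."""
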