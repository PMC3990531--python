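"""Exception types shared across the package."""


class SocnetError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SocnetError, ValueError):
    """A simulation configuration is invalid (bad ranges, unknown keys)."""


class NoCandidateSourceError(SocnetError):
    """Link insertion requested at a node that already receives input from
    every other node, so no new source can be drawn."""


class NoLinkError(SocnetError):
    """Link removal requested at a node without any in-links."""


class NonQuiescentError(SocnetError):
    """An avalanche was started from a state with nodes already active."""


class FitRefusedError(SocnetError):
    """A scaling fit was refused (too few samples in range, degenerate
    support, or too few populated duration classes)."""


class EmptyResultError(SocnetError):
    """A query matched no data (e.g. no avalanche of the requested duration)."""
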