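"""Exception types shared across the package."""


class InvalidConfigError(ValueError):
    """A configuration object violates one of its invariants."""


class OffPairExhaustionError(RuntimeError):
    """No off-pair disjoint from the already-used pairs remains for a prototype."""


class DimensionMismatchError(ValueError):
    """Two objects that must share a dimensionality do not."""
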