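"""Exception hierarchy."""


class ProtknotError(Exception):
    """Base class for all package errors."""


class ParseError(ProtknotError):
    """A structure or notation string could not be parsed."""


class GeometryError(ProtknotError):
    """A geometric precondition failed (degenerate projection, bad closure point...)."""


class TopologyError(ProtknotError):
    """An invariant could not be computed (open diagram where closed expected, ...)."""
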