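"""Typed exceptions raised across the analysis stack."""


class OmdiffError(Exception):
    """Base class for all package errors."""


class ParameterError(OmdiffError, ValueError):
    """Invalid simulation or analysis parameter."""


class SegmentationError(OmdiffError, RuntimeError):
    """Region identification failed; the message names the failed step."""


class DriftError(OmdiffError, RuntimeError):
    """Estimated drift exceeds the discard criterion (cell moved)."""


class NormalizationError(OmdiffError, RuntimeError):
    """Double normalization undefined (non-positive reference or trace)."""


class MaskError(OmdiffError, RuntimeError):
    """Empty or degenerate analysis mask."""


class ParseError(OmdiffError, ValueError):
    """Malformed input table or stack/sidecar mismatch."""
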