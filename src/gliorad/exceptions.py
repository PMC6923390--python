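"""Exception hierarchy for the gliorad pipeline.

Every stage raises a subclass of :class:`GlioradError` so that callers can
distinguish pipeline contract violations from programming errors.
"""


class GlioradError(Exception):
    """Base class for all gliorad errors."""


class DegenerateIntensity(GlioradError):
    """Constant image: Z-score normalization is undefined (sigma = 0)."""


class EmptyRoi(GlioradError):
    """An operation that requires a non-empty region of interest got an empty mask."""


class ImageTooSmall(GlioradError):
    """An image axis is shorter than the wavelet analysis filter."""


class DegeneratePhantom(GlioradError):
    """The phantom generator failed to produce a valid tumor blob."""


class SelectionEmpty(GlioradError):
    """No feature survived the screening stage."""


class EmptyIntersection(GlioradError):
    """The across-fold intersection of selected features is empty; the
    independent validation cannot proceed without user guidance."""


class ConfigError(GlioradError):
    """Invalid or inconsistent configuration."""
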