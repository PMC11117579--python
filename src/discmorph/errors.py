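"""Exception types shared across the package."""


class InvalidSpecError(ValueError):
    """A configuration or phantom specification violates its constraints."""


class SegmentationError(RuntimeError):
    """A segmentation stage produced an empty or unusable result."""


class ContourError(ValueError):
    """A contour is degenerate, self-intersecting, or otherwise unusable."""
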