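"""Shared exception types."""


class InvalidParameterError(ValueError):
    """A user-supplied parameter is outside its valid range."""


class EmptyLatticeError(RuntimeError):
    """The target region is too small to host a single unit cell."""


class ResolutionError(ValueError):
    """Requested voxel pitch is too coarse for the geometry."""
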