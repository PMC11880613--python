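"""Exception types shared across the pipeline stages."""


class ValidationError(ValueError):
    """An input or configuration value violates a documented invariant."""


class PlacementError(RuntimeError):
    """A phantom tumor could not be placed inside the brain after bounded retries."""


class NoForegroundError(ValueError):
    """The ROI reference slice contains no suprathreshold pixel."""


class BoundsError(ValueError):
    """A crop box or depth range exceeds the volume extents."""


class StructuralError(RuntimeError):
    """A model lacks the structure an operation requires (e.g. no output layer)."""


class OrchestrationError(RuntimeError):
    """A pipeline stage dependency is unmet."""
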