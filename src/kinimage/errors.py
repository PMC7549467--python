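"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class FormatError(ValueError):
    """A file does not conform to the marker-trajectory CSV dialect."""


class DetectionFailureError(RuntimeError):
    """Movement onset/offset detection found no movement in the recording."""


class SplitError(RuntimeError):
    """A train/validation split left a class without examples."""


class BuildError(ValueError):
    """A network cannot be built for the requested input geometry."""
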