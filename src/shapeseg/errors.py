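"""Exception hierarchy shared across the toolkit."""


class ShapesegError(Exception):
    """Base class for all toolkit errors."""


class FormatError(ShapesegError):
    """Unknown or unsupported file format."""


class CorruptFileError(ShapesegError):
    """File contents inconsistent with its header."""


class TopologyError(ShapesegError):
    """Mesh does not satisfy a required topological property (e.g. closedness)."""


class DegenerateInputError(ShapesegError):
    """Input is degenerate for the requested operation (empty mask, constant image, ...)."""


class DimensionError(ShapesegError):
    """Array/vector dimensions do not match the model."""


class ConvergenceError(ShapesegError):
    """Iterative optimization failed to converge."""
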