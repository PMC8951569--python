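"""Exception hierarchy shared across the pipeline."""


class AngiotrackError(Exception):
    """Base class for all pipeline errors."""


class FormatError(AngiotrackError):
    """Unreadable or unsupported input file."""


class InputError(AngiotrackError):
    """Structurally valid input that violates a precondition (e.g. too few frames)."""


class ValidationError(AngiotrackError):
    """Parameter or argument outside its documented domain."""


class ScaleError(AngiotrackError):
    """Frame too small for the requested filter scales."""


class DetectionError(AngiotrackError):
    """Automatic contrast-window detection failed; manual window required."""


class BankError(AngiotrackError):
    """Template bank could not be constructed."""


class DegenerateInputError(AngiotrackError):
    """Zero-variance input where a correlation is requested."""


class GenerationError(AngiotrackError):
    """Synthetic phantom generation failed (e.g. geometry leaves the frame)."""
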