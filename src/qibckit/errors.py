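"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Input violates a documented precondition."""


class PlacementError(RuntimeError):
    """Nuclei could not be placed in the field within the attempt cap."""


class DegenerateHistogramError(ValueError):
    """Thresholding was requested on a constant (single-valued) image."""


class InsufficientDataError(ValueError):
    """Too few observations for a population-level estimate."""
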