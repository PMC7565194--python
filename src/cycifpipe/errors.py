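"""Exception hierarchy shared across the pipeline stages."""


class CycifError(Exception):
    """Base class for all errors raised by this package."""


class PanelConfigError(CycifError):
    """Invalid panel / gating configuration."""


class InputError(CycifError):
    """Input data violates a precondition (shape, channel count, frame mismatch)."""


class ParameterError(CycifError):
    """A parameter value is outside its valid range."""


class EstimationError(CycifError):
    """A statistical estimate cannot be computed from the given data."""


class RegistrationError(CycifError):
    """Image registration cannot proceed (e.g. constant input)."""


class CroppingError(CycifError):
    """No common valid region exists across cycles."""


class CapacityError(CycifError):
    """The requested number of cells cannot be placed at the given density."""
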