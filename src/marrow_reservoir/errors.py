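"""Exception hierarchy shared across the package."""


class ValidationError(ValueError):
    """An input violated a documented precondition; the message names the field."""


class DegenerateDataError(ValidationError):
    """Data are valid in shape but statistically degenerate (e.g. zero within-group variance)."""


class IntegrationError(RuntimeError):
    """The ODE integrator produced a non-finite state; the message reports t and h."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""
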