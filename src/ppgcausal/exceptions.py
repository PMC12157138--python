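"""Exception hierarchy shared across the pipeline."""


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInput(PipelineError, ValueError):
    """Input violates a precondition (empty, too short, wrong shape)."""


class DegenerateInput(PipelineError, ValueError):
    """Input is formally valid but statistically degenerate (e.g. constant)."""


class InsufficientData(PipelineError, ValueError):
    """Not enough samples/beats/cycles to compute the quantity reliably."""


class ConfigurationError(PipelineError, ValueError):
    """Parameters outside their admissible range or mutually inconsistent."""
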