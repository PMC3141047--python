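"""Exception hierarchy.

``ValidationError`` covers bad user input (malformed tables, impossible
configurations); everything else that goes wrong during fitting is a
``FitError``.  The CLI maps the former to exit code 1 and the latter to 2.
"""


class GspprError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(GspprError, ValueError):
    """Invalid input data or configuration."""


class ConfigError(ValidationError):
    """Invalid run configuration."""


class FitError(GspprError, RuntimeError):
    """A model-fitting step failed (rank deficiency, degenerate data, ...)."""


class PipelineError(GspprError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
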