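"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: usage/config errors -> 1,
data validation errors -> 2, pipeline/degenerate-result errors -> 3.
"""


class ZhengkitError(Exception):
    """Base class for all package errors."""


class ConfigError(ZhengkitError):
    """Invalid configuration or usage (CLI exit code 1)."""


class ValidationError(ZhengkitError):
    """Input data violates the data model (CLI exit code 2)."""


class PipelineError(ZhengkitError):
    """A pipeline stage produced a degenerate or empty result (CLI exit code 3)."""
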