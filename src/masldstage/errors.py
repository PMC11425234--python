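"""Exception types shared across the package."""


class FormatError(ValueError):
    """Malformed on-disk artifact (readers reject rather than coerce)."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; message names the stage and the cause."""
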