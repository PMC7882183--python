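"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A parameter set violates its invariants (e.g. empty group, negative SD)."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""
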