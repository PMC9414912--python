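"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input failed a structural, range or alphabet check."""


class PipelineError(RuntimeError):
    """A pipeline stage failed at run time (I/O, degenerate data, ...)."""
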