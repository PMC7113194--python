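"""Exception types shared across the pipeline."""


class ParameterError(ValueError):
    """An argument or configuration value is outside its documented range."""


class FormatError(ValueError):
    """An on-disk file does not conform to its declared binary/text layout."""


class DegenerateDataError(ValueError):
    """A model cannot be fit because the data carry no usable variation."""


class PipelineError(RuntimeError):
    """A pipeline stage cannot proceed (e.g. every SNP removed by QC)."""
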