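"""Exception hierarchy shared across the pipeline stages."""


class PipelineError(Exception):
    """Base class for all rrnapipe errors."""


class ModelError(PipelineError):
    """Invalid kinetic model input (negative rate, missing regime, time out of range)."""


class DataError(PipelineError):
    """Observations or counts that a stage cannot consume."""


class SchemaError(DataError):
    """Tabular input whose columns or cells do not match the declared schema."""
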