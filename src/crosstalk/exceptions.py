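"""Exception hierarchy shared across the pipeline stages."""


class CrosstalkError(Exception):
    """Base class for all errors raised by this package."""


class LoadError(CrosstalkError):
    """An input file could not be assembled into a valid object."""


class SchemaError(LoadError):
    """A table is missing required columns or has malformed entries."""


class DegenerateDataError(CrosstalkError):
    """The data carry no usable signal for the requested operation
    (e.g. a constant fraction column handed to the mixture fit)."""


class VocabularyMismatchError(CrosstalkError):
    """Two objects that must share a cell-type vocabulary do not."""


class PipelineError(CrosstalkError):
    """Failure inside an orchestrated multi-stage run; message is stage-tagged."""
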