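"""Exception hierarchy for the pipeline.

Validation problems (bad parameters, malformed inputs) are distinguished from
runtime consistency problems so the CLI can map them to distinct exit codes.
"""


class DiaquantError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(DiaquantError, ValueError):
    """A parameter is outside its documented range."""


class FormatError(DiaquantError, ValueError):
    """An input file does not conform to the expected tabular/FASTA format."""


class IntegrityError(DiaquantError, ValueError):
    """An input violates a uniqueness or non-emptiness constraint."""


class MappingError(DiaquantError, KeyError):
    """A run/sample identifier cannot be resolved against the metadata."""


class ConsistencyError(DiaquantError, ValueError):
    """Two pipeline objects that must agree (e.g. matrix vs. peptide counts) do not."""


class BinningError(DiaquantError, ValueError):
    """A column cannot be partitioned into the requested number of bins."""


class PipelineStageError(DiaquantError, RuntimeError):
    """A pipeline stage failed; carries the stage name and input context."""

    def __init__(self, stage: str, context: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed on {context}: {cause}")
        self.stage = stage
        self.context = context
        self.__cause__ = cause
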