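"""Exception types shared across the package."""


class FragmapError(Exception):
    """Base class for all package errors."""


class ParameterError(FragmapError, ValueError):
    """A user-supplied parameter is outside its valid domain."""


class FastaParseError(FragmapError, ValueError):
    """Malformed FASTA input."""


class FastqParseError(FragmapError, ValueError):
    """Malformed FASTQ input."""


class EvaluationError(FragmapError, ValueError):
    """Predictions cannot be scored against the truth table."""
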