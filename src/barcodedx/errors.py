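"""Exception hierarchy shared across the pipeline."""


class BarcodeDxError(Exception):
    """Base class for all pipeline errors."""


class AlignmentError(BarcodeDxError):
    """Malformed or degenerate alignment (ragged rows, bad characters, empty result)."""


class MetadataError(BarcodeDxError):
    """Sample table does not satisfy the schema or does not cover the alignment."""


class DistanceError(BarcodeDxError):
    """A pairwise distance could not be computed (no comparable sites, saturation)."""


class NetworkError(BarcodeDxError):
    """Haplotype-network construction or query failure."""


class DesignError(BarcodeDxError):
    """Oligo design failure (no conserved window, infeasible constraints, bad input)."""


class QpcrError(BarcodeDxError):
    """qPCR well-table or call-logic contract violation."""
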