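"""Exception hierarchy for phylofoot."""


class PhylofootError(Exception):
    """Base class for all phylofoot errors."""


class MatrixFormatError(PhylofootError):
    """Malformed JASPAR/TRANSFAC matrix record."""


class AlignmentFormatError(PhylofootError):
    """Malformed MAF or aligned-FASTA input."""


class TreeError(PhylofootError):
    """Invalid Newick input or tree-related lookup failure."""


class ParameterError(PhylofootError):
    """Invalid numeric parameter (background, pseudocount, threshold)."""


class CoordinateError(PhylofootError):
    """A coordinate falls outside the sequence, alignment, or anchored region."""
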