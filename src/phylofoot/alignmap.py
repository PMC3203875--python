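"""Multiple-alignment parsing and coordinate conversion.

All coordinates are 1-based inclusive: ``seq_pos`` counts non-gap
characters of one species' row, ``column`` counts alignment columns
including gaps.  The 0-based half-open convention appears only at BED
export time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from io import StringIO

import numpy as np
from Bio import AlignIO

from .exceptions import AlignmentFormatError, CoordinateError
from .pssm import SiteMatch

GAP_CHARS = "-."


@dataclass(frozen=True)
class GenomeAnchor:
    """Genomic location of the reference row: 1-based inclusive interval."""

    assembly: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class Alignment:
    """An ordered multiple alignment of orthologous regulatory regions.

    Rows are (species code, gapped sequence); all rows share one length.
    An optional :class:`GenomeAnchor` places the first (reference) row on
    a genome assembly.
    """

    def __init__(
        self,
        rows: list[tuple[str, str]],
        anchor: GenomeAnchor | None = None,
    ) -> None:
        if not rows:
            raise AlignmentFormatError("alignment has no rows")
        lengths = {len(seq) for _, seq in rows}
        if len(lengths) != 1:
            raise AlignmentFormatError(
                f"rows have unequal lengths: {sorted(lengths)}"
            )
        species = [sp for sp, _ in rows]
        if len(set(species)) != len(species):
            raise AlignmentFormatError("duplicate species codes in alignment")
        self.rows = [(sp, seq.upper()) for sp, seq in rows]
        self.anchor = anchor
        self.alignment_length = lengths.pop()
        self._seqs = dict(self.rows)
        for sp, seq in self.rows:
            if sum(c not in GAP_CHARS for c in seq) < 1:
                raise AlignmentFormatError(f"row {sp!r} is all gaps")
        self._pos_to_col: dict[str, np.ndarray] = {}
        self._col_to_pos: dict[str, np.ndarray] = {}

    @property
    def species(self) -> list[str]:
        return [sp for sp, _ in self.rows]

    @property
    def reference_species(self) -> str:
        return self.rows[0][0]

    def row(self, species: str) -> str:
        try:
            return self._seqs[species]
        except KeyError:
            raise CoordinateError(f"unknown species {species!r}") from None

    def ungapped(self, species: str) -> str:
        row = self.row(species)
        return "".join(c for c in row if c not in GAP_CHARS)

    def _maps(self, species: str) -> tuple[np.ndarray, np.ndarray]:
        if species not in self._pos_to_col:
            row = self.row(species)
            is_base = np.array([c not in GAP_CHARS for c in row])
            cols = np.nonzero(is_base)[0] + 1  # seq_pos (0-idx) -> column (1-based)
            col2pos = np.where(is_base, np.cumsum(is_base), 0)  # 0 marks a gap
            self._pos_to_col[species] = cols
            self._col_to_pos[species] = col2pos
        return self._pos_to_col[species], self._col_to_pos[species]


def seq_to_aln(alignment: Alignment, species: str, seq_pos: int) -> int:
    """Column of the ``seq_pos``-th non-gap character of a species row."""
    cols, _ = alignment._maps(species)
    if not 1 <= seq_pos <= cols.size:
        raise CoordinateError(
            f"position {seq_pos} outside 1..{cols.size} for species {species!r}"
        )
    return int(cols[seq_pos - 1])


def aln_to_seq(alignment: Alignment, species: str, column: int) -> int | None:
    """Ungapped position at an alignment column, or None on a gap."""
    _, col2pos = alignment._maps(species)
    if not 1 <= column <= alignment.alignment_length:
        raise CoordinateError(
            f"column {column} outside 1..{alignment.alignment_length}"
        )
    pos = int(col2pos[column - 1])
    return pos if pos > 0 else None


@dataclass(frozen=True)
class AlignedSite:
    """A motif match carried in both sequence and alignment coordinates.

    ``s``/``e`` are the alignment columns of the match's first and last
    base; ``l`` is the ungapped length in bp (so l <= e - s + 1, with
    equality when the match spans no gap).
    """

    match: SiteMatch
    s: int
    e: int
    l: int

    def __post_init__(self) -> None:
        if not (1 <= self.s <= self.e):
            raise CoordinateError(f"bad aligned interval [{self.s}, {self.e}]")
        if self.l > self.e - self.s + 1:
            raise CoordinateError("ungapped length exceeds aligned span")

    @property
    def species(self) -> str:
        return self.match.species

    @property
    def tf_name(self) -> str:
        return self.match.tf_name

    @property
    def middle(self) -> int:
        return (self.s + self.e) // 2


def project(alignment: Alignment, match: SiteMatch) -> AlignedSite:
    """Lift a sequence-coordinate match into alignment coordinates."""
    s = seq_to_aln(alignment, match.species, match.seq_start)
    e = seq_to_aln(alignment, match.species, match.seq_end)
    return AlignedSite(match=match, s=s, e=e, l=match.length)


def _parse_fasta_alignment(stream: str) -> Alignment:
    try:
        aln = AlignIO.read(StringIO(stream), "fasta")
    except ValueError as exc:
        raise AlignmentFormatError(f"bad aligned FASTA: {exc}") from exc
    return Alignment([(rec.id, str(rec.seq)) for rec in aln])


def _parse_maf(stream: str) -> Alignment:
    """Concatenate MAF blocks per species; species absent from a block are
    padded with gaps so columns stay comparable across blocks."""
    try:
        blocks = list(AlignIO.parse(StringIO(stream), "maf"))
    except Exception as exc:
        raise AlignmentFormatError(f"bad MAF: {exc}") from exc
    if not blocks:
        raise AlignmentFormatError("MAF input contains no alignment blocks")
    parts: dict[str, list[str]] = {}
    order: list[str] = []
    total = 0
    anchor = None
    ref_ungapped = 0
    for block in blocks:
        blen = block.get_alignment_length()
        seen = set()
        for rec in block:
            src = rec.id
            species = src.split(".", 1)[0]
            if species in seen:
                continue  # keep the first row per species within a block
            seen.add(species)
            if species not in parts:
                parts[species] = ["-" * total]
                order.append(species)
            parts[species].append(str(rec.seq))
            if anchor is None and species == order[0]:
                ann = rec.annotations
                chrom = src.split(".", 1)[1] if "." in src else src
                strand = "+" if ann.get("strand", 1) in (1, "+") else "-"
                anchor = [species, chrom, int(ann.get("start", 0)), strand]
            if order and species == order[0]:
                ref_ungapped += sum(
                    c not in GAP_CHARS for c in str(rec.seq)
                )
        for sp in order:
            if sp not in seen:
                parts[sp].append("-" * blen)
        total += blen
    rows = [(sp, "".join(parts[sp])) for sp in order]
    ga = None
    if anchor is not None:
        _, chrom, start0, strand = anchor
        ga = GenomeAnchor(
            assembly=anchor[0],
            chrom=chrom,
            start=start0 + 1,
            end=start0 + ref_ungapped,
            strand=strand,
        )
    return Alignment(rows, anchor=ga)


def parse_alignment(stream: str, format: str = "fasta") -> Alignment:
    """Parse an aligned FASTA or (multi-block) MAF into an :class:`Alignment`."""
    if format == "fasta":
        return _parse_fasta_alignment(stream)
    if format == "maf":
        return _parse_maf(stream)
    raise AlignmentFormatError(f"unknown alignment format {format!r}")


def write_fasta_alignment(alignment: Alignment) -> str:
    out = []
    for sp, seq in alignment.rows:
        out.append(f">{sp}")
        out.append(seq)
    return "\n".join(out) + "\n"
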