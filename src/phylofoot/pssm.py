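"""Position-specific scoring matrices: parsing, clade filtering, and scanning.

A binding motif is modelled as a count matrix over A/C/G/T per position.
Counts are converted to log-odds (bits) against a background distribution
with a pseudocount, and sequences are scanned on both strands.  Match
strength is reported as the matrix similarity score (mss), the min-max
normalised log-odds sum in [0, 1]: 1.0 means the best attainable match
(the consensus), 0.0 the worst.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from io import StringIO
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import motifs as _bio_motifs

from .exceptions import MatrixFormatError, ParameterError

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Uniform background distribution over A, C, G, T.
UNIFORM_BACKGROUND: dict[str, float] = {b: 0.25 for b in BASES}

#: Default matrix-similarity-score cutoff for reporting matches.
DEFAULT_MIN_MSS = 0.8


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ScoringMatrix:
    """One TF binding motif: a count matrix with optional derived log-odds.

    ``counts`` has shape (L, 4) with columns ordered A, C, G, T; every
    count is non-negative and no position is all-zero.  ``log_odds`` (same
    shape, bits) is populated by :func:`to_log_odds`.
    """

    matrix_id: str
    tf_name: str
    source: str  # jaspar | transfac | user
    counts: np.ndarray
    taxon_group: str | None = None
    log_odds: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise MatrixFormatError(
                f"matrix {self.matrix_id!r}: counts must have shape (L, 4)"
            )
        if self.counts.shape[0] < 1:
            raise MatrixFormatError(f"matrix {self.matrix_id!r}: empty matrix")
        if (self.counts < 0).any():
            raise MatrixFormatError(f"matrix {self.matrix_id!r}: negative count")
        if (self.counts.sum(axis=1) == 0).any():
            raise MatrixFormatError(
                f"matrix {self.matrix_id!r}: a position has all-zero counts"
            )

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def consensus(self) -> str:
        """Column-maximum base per position (ties broken A<C<G<T)."""
        return "".join(BASES[i] for i in self.counts.argmax(axis=1))


@dataclass(frozen=True)
class SiteMatch:
    """A motif match on one species' ungapped regional sequence.

    Coordinates are 1-based inclusive on the forward strand; minus-strand
    matches are reported in forward coordinates with ``strand='-'``.
    """

    species: str
    matrix_id: str
    tf_name: str
    seq_start: int
    seq_end: int
    strand: str
    raw_score: float
    mss: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mss <= 1.0 + 1e-12:
            raise ValueError(f"mss out of [0,1]: {self.mss}")

    @property
    def length(self) -> int:
        return self.seq_end - self.seq_start + 1


def _counts_to_array(matrix_id: str, counts: Mapping[str, Sequence[float]]) -> np.ndarray:
    rows = []
    lengths = {len(counts[b]) for b in BASES if b in counts}
    if set(counts) < set(BASES) or len(lengths) != 1:
        raise MatrixFormatError(
            f"matrix {matrix_id!r}: need equal-length rows for all of A,C,G,T"
        )
    for b in BASES:
        rows.append(list(counts[b]))
    return np.asarray(rows, dtype=float).T


def parse_jaspar(
    stream: str, taxon_groups: Mapping[str, str] | None = None
) -> list[ScoringMatrix]:
    """Parse a JASPAR 2010-style flat file (">ID NAME" plus four count rows).

    ``taxon_groups`` optionally maps matrix ids (or TF names) to a taxon
    group such as "vertebrates"; JASPAR flat files carry no taxon field.
    """
    text = stream.strip()
    if not text:
        return []
    try:
        records = _bio_motifs.parse(StringIO(text), "jaspar")
    except Exception as exc:  # biopython raises bare Exception for ragged rows
        raise MatrixFormatError(f"malformed JASPAR input: {exc}") from exc
    out = []
    for rec in records:
        matrix_id = rec.matrix_id or rec.name
        if not matrix_id:
            raise MatrixFormatError("JASPAR record without an identifier")
        arr = _counts_to_array(matrix_id, rec.counts)
        group = None
        if taxon_groups:
            group = taxon_groups.get(matrix_id, taxon_groups.get(rec.name))
        out.append(
            ScoringMatrix(
                matrix_id=matrix_id,
                tf_name=rec.name or matrix_id,
                source="jaspar",
                counts=arr,
                taxon_group=group,
            )
        )
    return out


def parse_transfac(
    stream: str, taxon_groups: Mapping[str, str] | None = None
) -> list[ScoringMatrix]:
    """Parse TRANSFAC flat format (AC/ID/P0 blocks separated by ``//``).

    The consensus column of the count table is ignored.  A block without a
    P0 count table is a format error.
    """
    text = stream.strip()
    if not text:
        return []
    # Bio.motifs silently drops blocks lacking a P0 table; validate up front.
    for block in text.split("//"):
        block = block.strip()
        if not block:
            continue
        lines = [ln for ln in block.splitlines() if ln.strip()]
        if not any(ln.startswith("P0") or ln.startswith("PO") for ln in lines):
            acc = next(
                (ln.split(None, 1)[1] for ln in lines if ln.startswith("AC")), "?"
            )
            raise MatrixFormatError(f"TRANSFAC record {acc!r}: missing P0 count table")
    try:
        records = _bio_motifs.parse(StringIO(text), "transfac")
    except Exception as exc:
        raise MatrixFormatError(f"malformed TRANSFAC input: {exc}") from exc
    out = []
    for rec in records:
        matrix_id = rec.get("AC") or rec.get("ID") or "?"
        tf_name = rec.get("ID") or matrix_id
        arr = _counts_to_array(matrix_id, rec.counts)
        group = None
        if taxon_groups:
            group = taxon_groups.get(matrix_id, taxon_groups.get(tf_name))
        out.append(
            ScoringMatrix(
                matrix_id=matrix_id,
                tf_name=tf_name,
                source="transfac",
                counts=arr,
                taxon_group=group,
            )
        )
    return out


def filter_matrices_by_clade(
    matrices: Iterable[ScoringMatrix], allowed_groups: set[str]
) -> list[ScoringMatrix]:
    """Drop matrices whose taxon group is outside ``allowed_groups``.

    This removes biologically implausible models (e.g. plant-specific
    motifs when scanning mammalian sequence).  Matrices without taxon
    metadata are kept, with a warning, rather than silently lost.
    """
    if not allowed_groups:
        raise ParameterError("allowed_groups must be non-empty")
    kept = []
    for m in matrices:
        if m.taxon_group is None:
            logger.warning(
                "matrix %s has no taxon group; kept despite clade filter", m.matrix_id
            )
            kept.append(m)
        elif m.taxon_group in allowed_groups:
            kept.append(m)
    return kept


def to_log_odds(
    matrix: ScoringMatrix,
    background: Mapping[str, float] | None = None,
    pseudocount: float = 1.0,
) -> ScoringMatrix:
    """Return a copy of ``matrix`` with log-odds (bits) filled in.

    log_odds[i][b] = log2((counts[i][b] + p*q_b) / (N_i + p) / q_b) where
    q is the background, p the total pseudocount (distributed by
    background) and N_i the column count sum.
    """
    background = dict(background or UNIFORM_BACKGROUND)
    bg = np.array([background[b] for b in BASES], dtype=float)
    if abs(bg.sum() - 1.0) > 1e-9 or (bg <= 0).any():
        raise ParameterError("background must be positive and sum to 1")
    if pseudocount < 0:
        raise ParameterError("pseudocount must be non-negative")
    n = matrix.counts.sum(axis=1, keepdims=True)
    probs = (matrix.counts + pseudocount * bg) / (n + pseudocount)
    with np.errstate(divide="ignore"):
        lo = np.log2(probs / bg)
    if not np.isfinite(lo).all():
        raise ParameterError(
            f"matrix {matrix.matrix_id!r}: zero count with pseudocount={pseudocount} "
            "gives infinite log-odds; use a positive pseudocount"
        )
    if abs(float(probs.sum(axis=1)[0]) - 1.0) > 1e-9:
        raise ParameterError("column probabilities do not normalise")
    return replace(matrix, log_odds=lo)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _scan_one_strand(codes: np.ndarray, lo: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Score every window of length L; returns (scores, valid_mask)."""
    L = lo.shape[0]
    n_win = codes.size - L + 1
    scores = np.zeros(n_win, dtype=float)
    valid = np.ones(n_win, dtype=bool)
    safe = np.where(codes < 0, 0, codes)
    bad = codes < 0
    for j in range(L):
        scores += lo[j, safe[j : j + n_win]]
        valid &= ~bad[j : j + n_win]
    return scores, valid


def scan_sequence(
    seq: str,
    matrix: ScoringMatrix,
    min_mss: float = DEFAULT_MIN_MSS,
    species: str = "",
    background: Mapping[str, float] | None = None,
    pseudocount: float = 1.0,
) -> list[SiteMatch]:
    """Scan an ungapped uppercase DNA sequence on both strands.

    Windows containing non-ACGT characters are skipped with a warning.
    Matches with mss >= ``min_mss`` are returned sorted by start position
    then strand ('+' before '-').  mss = (raw - min) / (max - min) with
    min/max the column-wise extreme log-odds sums.
    """
    if not 0.0 <= min_mss <= 1.0:
        raise ParameterError("min_mss must be in [0, 1]")
    if matrix.log_odds is None:
        matrix = to_log_odds(matrix, background=background, pseudocount=pseudocount)
    lo = matrix.log_odds
    L = matrix.length
    n = len(seq)
    if n < L:
        raise ParameterError(f"sequence length {n} < motif length {L}")
    lo_min = float(lo.min(axis=1).sum())
    lo_max = float(lo.max(axis=1).sum())
    span = lo_max - lo_min

    matches: list[SiteMatch] = []
    skipped = 0
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        codes = _encode(s)
        scores, valid = _scan_one_strand(codes, lo)
        skipped += int((~valid).sum())
        for i in np.nonzero(valid)[0]:
            raw = float(scores[i])
            mss = (raw - lo_min) / span if span > 0 else 1.0
            mss = min(max(mss, 0.0), 1.0)
            if mss < min_mss:
                continue
            if strand == "+":
                start = int(i) + 1
            else:
                start = n - int(i) - L + 1
            matches.append(
                SiteMatch(
                    species=species,
                    matrix_id=matrix.matrix_id,
                    tf_name=matrix.tf_name,
                    seq_start=start,
                    seq_end=start + L - 1,
                    strand=strand,
                    raw_score=raw,
                    mss=mss,
                )
            )
    if skipped:
        warnings.warn(
            f"{skipped} window(s) containing non-ACGT characters were skipped",
            stacklevel=2,
        )
    matches.sort(key=lambda m: (m.seq_start, m.strand))
    return matches


def write_jaspar(matrices: Iterable[ScoringMatrix]) -> str:
    """Serialise matrices in the JASPAR flat format (counts as integers
    when integral)."""
    chunks = []
    for m in matrices:
        lines = [f">{m.matrix_id} {m.tf_name}"]
        for bi, b in enumerate(BASES):
            vals = " ".join(
                str(int(v)) if float(v).is_integer() else f"{v:g}"
                for v in m.counts[:, bi]
            )
            lines.append(f"{b} [ {vals} ]")
        chunks.append("\n".join(lines))
    return "\n".join(chunks) + ("\n" if chunks else "")
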