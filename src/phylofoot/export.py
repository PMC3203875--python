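"""Genome-browser track (BED / BED detail) and pattern-table export.

Internal coordinates are 1-based inclusive; BED output follows the UCSC
convention (0-based half-open).  Pattern tracks carry one ``track`` line
per pattern with a unique colour, the branch length score and the origin
node in the description; glyph scores encode the matrix similarity score
(mss 1.0 -> score 1000).
"""

from __future__ import annotations

import colorsys
import dataclasses
import logging
from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import pandas as pd

from .alignmap import GenomeAnchor
from .exceptions import CoordinateError
from .homology import HomologGroup
from .parsimony import CharacterLabeling, SpeciesTree
from .patterns import Pattern

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BedRecord:
    """One BED(9) feature; ``chromStart`` is 0-based, ``chromEnd`` exclusive."""

    chrom: str
    chromStart: int
    chromEnd: int
    name: str
    score: int
    strand: str
    itemRgb: str
    detail_id: str | None = None
    description: str | None = None

    def __post_init__(self) -> None:
        if not self.chromStart < self.chromEnd:
            raise CoordinateError(
                f"chromStart {self.chromStart} !< chromEnd {self.chromEnd}"
            )
        if not 0 <= self.score <= 1000:
            raise CoordinateError(f"BED score {self.score} outside 0..1000")

    def to_line(self, detail: bool = False) -> str:
        fields = [
            self.chrom,
            str(self.chromStart),
            str(self.chromEnd),
            self.name,
            str(self.score),
            self.strand,
            str(self.chromStart),
            str(self.chromEnd),
            self.itemRgb,
        ]
        if detail:
            fields += [self.detail_id or self.name, self.description or ""]
        return "\t".join(fields)


def anchor_to_genome(
    seq_start: int, length: int, anchor: GenomeAnchor | None
) -> tuple[str, int, int]:
    """Map a 1-based regional position + length onto genome coordinates.

    chromStart = anchor.start - 1 + (seq_start - 1); chromEnd exclusive.
    """
    if anchor is None:
        raise CoordinateError("no genome anchor available for BED export")
    if seq_start < 1 or seq_start + length - 1 > anchor.length:
        raise CoordinateError(
            f"site [{seq_start}, {seq_start + length - 1}] outside anchored "
            f"region of length {anchor.length}"
        )
    chrom_start = anchor.start - 1 + (seq_start - 1)
    return anchor.chrom, chrom_start, chrom_start + length


def pattern_palette(n: int, saturation: float = 0.85, value: float = 0.75) -> list[str]:
    """n visually distinct "r,g,b" colours (golden-angle hue stepping)."""
    colors = []
    hue = 0.12
    for _ in range(n):
        r, g, b = colorsys.hsv_to_rgb(hue % 1.0, saturation, value)
        colors.append(f"{round(r * 255)},{round(g * 255)},{round(b * 255)}")
        hue += 0.618033988749895
    return colors


def _mss_score(mss: float) -> int:
    return int(round(1000 * mss))


def _pattern_records(
    pattern: Pattern,
    groups: Mapping[Hashable, HomologGroup],
    reference: str,
    anchor: GenomeAnchor,
    color: str,
) -> list[BedRecord]:
    records = []
    for cid in pattern.members:
        cluster = groups[cid].clusters.get(reference)
        if cluster is None:
            continue
        chrom, start, end = anchor_to_genome(cluster.seq_start, cluster.l, anchor)
        strand = cluster.strand if cluster.strand in "+-" else "."
        records.append(
            BedRecord(
                chrom=chrom,
                chromStart=start,
                chromEnd=end,
                name=cluster.combined_name,
                score=_mss_score(cluster.mss),
                strand=strand,
                itemRgb=color,
            )
        )
    return records


def write_bed(
    anchor: GenomeAnchor,
    reference: str,
    mode: str = "patterns",
    patterns: Sequence[Pattern] = (),
    groups: Mapping[Hashable, HomologGroup] | None = None,
    tree: SpeciesTree | None = None,
    group_bls: Mapping[Hashable, float] | None = None,
    bls_threshold: float = 0.0,
    annotations: Mapping[str, str] | None = None,
    detail: bool = False,
) -> str:
    """Write UCSC custom tracks.

    mode='patterns': one track per pattern (unique colour; description
    carries BLS and origin node, with '!' appended when every member is
    predicted in the reference species); patterns with no member in the
    reference species are omitted.  mode='bls_sites': a single track of
    homolog groups with BLS >= ``bls_threshold``, sorted descending.
    ``detail=True`` adds BED-detail id/description columns, filled from
    ``annotations`` (TF name -> text) when given.
    """
    groups = groups or {}
    lines: list[str] = []
    track_type = "type=bedDetail " if detail else ""
    if mode == "patterns":
        colors = pattern_palette(len(patterns))
        n_written = 0
        for pattern, color in zip(patterns, colors):
            records = _pattern_records(pattern, groups, reference, anchor, color)
            if not records:
                logger.warning(
                    "pattern %d has no member in reference species %s; omitted",
                    pattern.pattern_id, reference,
                )
                continue
            complete = len(records) == len(pattern.members)
            bang = "!" if complete else ""
            node_name = (
                tree.names[pattern.origin_node] if tree is not None
                else str(pattern.origin_node)
            )
            lines.append(
                f'track {track_type}name="pattern_{pattern.pattern_id}{bang}" '
                f'description="BLS={pattern.bls:.4g} origin={node_name}'
                f'({pattern.origin_type}){bang}" itemRgb="On"'
            )
            for rec in records:
                if detail and annotations is not None:
                    rec = dataclasses.replace(
                        rec, description=annotations.get(rec.name, "")
                    )
                lines.append(rec.to_line(detail=detail))
            n_written += 1
        if n_written == 0:
            logger.warning("no patterns written; emitting a valid empty file")
    elif mode == "bls_sites":
        group_bls = group_bls or {}
        kept = [
            (gid, g) for gid, g in groups.items()
            if group_bls.get(gid, 0.0) >= bls_threshold
        ]
        kept.sort(key=lambda item: (-group_bls.get(item[0], 0.0), str(item[0])))
        lines.append(
            f'track {track_type}name="bls_sites" '
            f'description="TFBS with branch length score >= {bls_threshold:g}" '
            f'itemRgb="On"'
        )
        for gid, g in kept:
            cluster = g.clusters.get(reference)
            if cluster is None:
                continue
            chrom, start, end = anchor_to_genome(cluster.seq_start, cluster.l, anchor)
            desc = (annotations or {}).get(g.name, "") if detail else None
            rec = BedRecord(
                chrom=chrom,
                chromStart=start,
                chromEnd=end,
                name=g.name,
                score=_mss_score(cluster.mss),
                strand=cluster.strand if cluster.strand in "+-" else ".",
                itemRgb="0,0,0",
                description=desc,
            )
            lines.append(rec.to_line(detail=detail))
    else:
        raise ValueError(f"unknown BED mode {mode!r}")
    return "\n".join(lines) + "\n"


def write_bed_detail(
    anchor: GenomeAnchor,
    reference: str,
    annotations: Mapping[str, str] | None = None,
    **kwargs,
) -> str:
    """BED detail variant: two extra columns (id, description), with
    descriptions drawn from an offline annotation table."""
    return write_bed(
        anchor, reference, annotations=annotations, detail=True, **kwargs
    )


def read_bed(text: str) -> tuple[list[str], list[BedRecord]]:
    """Strict reader for the BED dialect written here (round-trip checks)."""
    tracks: list[str] = []
    records: list[BedRecord] = []
    for ln in text.splitlines():
        if not ln.strip():
            continue
        if ln.startswith("track "):
            tracks.append(ln)
            continue
        f = ln.split("\t")
        if len(f) not in (9, 11):
            raise CoordinateError(f"unexpected BED column count {len(f)}")
        records.append(
            BedRecord(
                chrom=f[0],
                chromStart=int(f[1]),
                chromEnd=int(f[2]),
                name=f[3],
                score=int(f[4]),
                strand=f[5],
                itemRgb=f[8],
                detail_id=f[9] if len(f) == 11 else None,
                description=f[10] if len(f) == 11 else None,
            )
        )
    return tracks, records


def write_pattern_table(
    patterns: Sequence[Pattern],
    groups: Mapping[Hashable, HomologGroup],
    tree: SpeciesTree,
    detail: bool = False,
) -> str:
    """TSV with one row per pattern, ordered by descending BLS.

    Columns: id, BLS, origin node + event type, members with alignment
    coordinates/lengths, supporting species and the spacing vector;
    ``detail=True`` adds per-member per-species presence and matrix ids.
    """
    rows = []
    for p in sorted(patterns, key=lambda x: (-x.bls, x.pattern_id)):
        member_desc = ";".join(
            f"{groups[c].name}@{groups[c].footprint_s}-{groups[c].footprint_e}"
            f"/{_common_length(groups[c])}"
            for c in p.members
        )
        row = {
            "pattern_id": p.pattern_id,
            "bls": round(p.bls, 6),
            "origin_node": tree.names[p.origin_node],
            "origin_type": p.origin_type,
            "n_members": len(p.members),
            "members": member_desc,
            "supporting_species": ",".join(sorted(p.supporting_species)),
            "spacings": ",".join(str(d) for d in p.spacings),
        }
        if detail:
            row["member_presence"] = ";".join(
                f"{groups[c].name}:{','.join(sorted(groups[c].species))}"
                for c in p.members
            )
            row["matrix_ids"] = ";".join(
                ",".join(groups[c].matrix_ids) for c in p.members
            )
        rows.append(row)
    columns = [
        "pattern_id", "bls", "origin_node", "origin_type", "n_members",
        "members", "supporting_species", "spacings",
    ]
    if detail:
        columns += ["member_presence", "matrix_ids"]
    frame = pd.DataFrame(rows, columns=columns)
    return frame.to_csv(sep="\t", index=False)


def _common_length(group: HomologGroup) -> str:
    lengths = {c.l for c in group.clusters.values()}
    return str(lengths.pop()) if len(lengths) == 1 else "var"
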