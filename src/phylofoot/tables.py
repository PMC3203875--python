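"""TSV serialisation of intermediate results, shared by the CLI stages.

The formats are plain tab-separated tables so each pipeline stage can be
run, inspected and resumed from the shell.
"""

from __future__ import annotations

from typing import Hashable, Mapping, Sequence

import pandas as pd

from .alignmap import AlignedSite, Alignment, project
from .homology import HomologGroup, SiteCluster
from .parsimony import GainLossEvent, SpeciesTree
from .pssm import SiteMatch

MATCH_COLUMNS = [
    "species", "matrix_id", "tf_name", "seq_start", "seq_end", "strand",
    "raw_score", "mss",
]


def matches_to_frame(matches: Sequence[SiteMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {c: getattr(m, c) for c in MATCH_COLUMNS}
            for m in matches
        ],
        columns=MATCH_COLUMNS,
    )


def matches_from_frame(frame: pd.DataFrame) -> list[SiteMatch]:
    return [
        SiteMatch(
            species=str(r.species), matrix_id=str(r.matrix_id),
            tf_name=str(r.tf_name), seq_start=int(r.seq_start),
            seq_end=int(r.seq_end), strand=str(r.strand),
            raw_score=float(r.raw_score), mss=float(r.mss),
        )
        for r in frame.itertuples()
    ]


def sites_to_frame(sites: Sequence[AlignedSite]) -> pd.DataFrame:
    rows = []
    for site in sites:
        row = {c: getattr(site.match, c) for c in MATCH_COLUMNS}
        row.update(s=site.s, e=site.e, l=site.l)
        rows.append(row)
    return pd.DataFrame(rows, columns=MATCH_COLUMNS + ["s", "e", "l"])


def sites_from_frame(frame: pd.DataFrame, alignment: Alignment) -> list[AlignedSite]:
    return [project(alignment, m) for m in matches_from_frame(frame)]


def groups_to_frame(groups: Mapping[Hashable, HomologGroup]) -> pd.DataFrame:
    """One row per homolog group; per-species data packed as
    ``species=seq_start:l:mss:strand`` joined with ';'."""
    rows = []
    for gid in sorted(groups, key=str):
        g = groups[gid]
        packed = ";".join(
            f"{sp}={c.seq_start}:{c.l}:{c.mss:.6f}:{c.strand}"
            for sp, c in sorted(g.clusters.items())
        )
        rows.append({
            "group_id": gid,
            "name": g.name,
            "footprint_s": g.footprint_s,
            "footprint_e": g.footprint_e,
            "n_species": len(g.species),
            "members": packed,
            "matrix_ids": ",".join(g.matrix_ids),
        })
    return pd.DataFrame(
        rows,
        columns=["group_id", "name", "footprint_s", "footprint_e",
                 "n_species", "members", "matrix_ids"],
    )


def _cluster_stub(species: str, name: str, seq_start: int, l: int,
                  mss: float, strand: str, s: int, e: int,
                  cluster_id: int) -> SiteCluster:
    from .pssm import SiteMatch
    from .alignmap import AlignedSite
    match = SiteMatch(
        species=species, matrix_id="", tf_name=name,
        seq_start=seq_start, seq_end=seq_start + l - 1, strand=strand
        if strand in "+-" else "+", raw_score=0.0, mss=mss,
    )
    site = AlignedSite(match=match, s=s, e=e, l=l)
    return SiteCluster(
        cluster_id=cluster_id, species=species, combined_name=name,
        members=(site,), s=s, e=e, l=l, strand=strand,
    )


def groups_from_frame(frame: pd.DataFrame) -> dict[Hashable, HomologGroup]:
    """Rebuild lightweight groups (enough for parsimony, mining, export)."""
    groups: dict[Hashable, HomologGroup] = {}
    cid = 0
    for r in frame.itertuples():
        clusters = {}
        for chunk in str(r.members).split(";"):
            sp, rest = chunk.split("=")
            seq_start, l, mss, strand = rest.split(":")
            cid += 1
            clusters[sp] = _cluster_stub(
                species=sp, name=str(r.name), seq_start=int(seq_start),
                l=int(l), mss=float(mss), strand=strand,
                s=int(r.footprint_s), e=int(r.footprint_e), cluster_id=cid,
            )
        gid: Hashable = int(r.group_id) if str(r.group_id).isdigit() else r.group_id
        groups[gid] = HomologGroup(
            group_id=gid, name=str(r.name), clusters=clusters,
            footprint_s=int(r.footprint_s), footprint_e=int(r.footprint_e),
        )
    return groups


def events_to_frame(events: Sequence[GainLossEvent], tree: SpeciesTree) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "character": e.character,
                "parent": e.parent,
                "child": e.child,
                "parent_name": tree.names[e.parent],
                "child_name": tree.names[e.child],
                "type": e.type,
            }
            for e in events
        ],
        columns=["character", "parent", "child", "parent_name", "child_name",
                 "type"],
    )


def events_from_frame(frame: pd.DataFrame) -> list[GainLossEvent]:
    return [
        GainLossEvent(
            character=int(r.character) if str(r.character).isdigit()
            else r.character,
            parent=int(r.parent), child=int(r.child), type=str(r.type),
        )
        for r in frame.itertuples()
    ]
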