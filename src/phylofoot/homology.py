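"""Redundancy clustering and cross-species homolog groups.

Within one species, overlapping predictions for the same (or homologous)
factor are collapsed into a :class:`SiteCluster`.  Across species,
clusters that essentially overlap in the alignment and are bound by the
same or homologous factors form a :class:`HomologGroup` — the binary
presence/absence character later reconstructed on the species tree.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .alignmap import AlignedSite

logger = logging.getLogger(__name__)

_NON_LETTER = re.compile(r"[^a-z]+")


def normalize_tf_name(name: str) -> str:
    """Strip digits, spaces and punctuation and lowercase (Sox2 -> sox).

    Similarly named factors in motif databases are paralogs binding
    near-identical motifs, so the number-free stem identifies the family.
    An all-symbol name falls back to its lowercased original.
    """
    stem = _NON_LETTER.sub("", name.lower())
    return stem or name.lower()


class HomologyTable:
    """Cross-species TF homology groups (HomoloGene-style local snapshot).

    Rows are (group_id, species, gene_symbol); symbols are compared
    case-insensitively.
    """

    def __init__(self, rows: Iterable[tuple[int, str, str]] = ()) -> None:
        self._groups_by_symbol: dict[str, set[int]] = {}
        self.rows: list[tuple[int, str, str]] = []
        for gid, species, symbol in rows:
            self.rows.append((int(gid), species, symbol))
            self._groups_by_symbol.setdefault(symbol.lower(), set()).add(int(gid))

    @classmethod
    def from_tsv(cls, text: str) -> "HomologyTable":
        rows = []
        for ln in text.splitlines():
            ln = ln.strip()
            if not ln or ln.startswith("#") or ln.lower().startswith("group_id"):
                continue
            gid, species, symbol = ln.split("\t")[:3]
            rows.append((int(gid), species, symbol))
        return cls(rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["group_id", "species", "gene_symbol"])

    def groups_of(self, symbol: str) -> set[int]:
        return self._groups_by_symbol.get(symbol.lower(), set())


def tfs_homologous(name_a: str, name_b: str, table: HomologyTable | None) -> bool:
    """True iff both symbols occur in one homology group (case-insensitive)."""
    if table is None:
        return False
    return bool(table.groups_of(name_a) & table.groups_of(name_b))


@dataclass(frozen=True)
class SiteCluster:
    """Same-species equivalence class of redundant/joined predictions."""

    cluster_id: int
    species: str
    combined_name: str
    members: tuple[AlignedSite, ...]
    s: int
    e: int
    l: int
    strand: str  # '+', '-', or 'mixed'

    @property
    def mss(self) -> float:
        return max(m.match.mss for m in self.members)

    @property
    def seq_start(self) -> int:
        return self._best().match.seq_start

    @property
    def matrix_ids(self) -> tuple[str, ...]:
        return tuple(sorted({m.match.matrix_id for m in self.members}))

    @property
    def tf_names(self) -> tuple[str, ...]:
        return tuple(sorted({m.tf_name for m in self.members}))

    def _best(self) -> AlignedSite:
        return max(
            self.members, key=lambda m: (m.match.mss, -m.s, -m.e, m.match.matrix_id)
        )


def _site_key(site: AlignedSite) -> tuple:
    return (site.species, site.s, site.e, site.match.matrix_id, site.match.strand)


def _combined_name(members: Sequence[AlignedSite]) -> str:
    stems = {normalize_tf_name(m.tf_name) for m in members}
    if len(stems) == 1:
        return stems.pop().capitalize()
    return "/".join(sorted({m.tf_name for m in members}))


def _components_to_clusters(
    sites: Sequence[AlignedSite], graph: nx.Graph, start_id: int = 1
) -> list[SiteCluster]:
    comps = [sorted(c, key=lambda i: _site_key(sites[i])) for c in
             nx.connected_components(graph)]
    comps.sort(key=lambda c: _site_key(sites[c[0]]))
    clusters = []
    for cid, comp in enumerate(comps, start=start_id):
        members = tuple(sites[i] for i in comp)
        strands = {m.match.strand for m in members}
        best = max(members, key=lambda m: (m.match.mss, -m.s, -m.e, m.match.matrix_id))
        clusters.append(
            SiteCluster(
                cluster_id=cid,
                species=members[0].species,
                combined_name=_combined_name(members),
                members=members,
                s=best.s,
                e=best.e,
                l=best.l,
                strand=strands.pop() if len(strands) == 1 else "mixed",
            )
        )
    return clusters


def _names_compatible(a: AlignedSite, b: AlignedSite, table: HomologyTable | None) -> bool:
    return normalize_tf_name(a.tf_name) == normalize_tf_name(b.tf_name) or tfs_homologous(
        a.tf_name, b.tf_name, table
    )


def cluster_redundant(
    sites: Sequence[AlignedSite], table: HomologyTable | None = None
) -> list[SiteCluster]:
    """Collapse redundant same-species predictions (rigid matching rule).

    Two sites link iff their bp length is equal, they share the start,
    middle (floor((s+e)/2)) or end alignment coordinate, and their TF
    names normalise equal or are homologous.  Clusters are the connected
    components; output order is deterministic in the site coordinates.
    """
    sites = sorted(sites, key=_site_key)
    _require_single_species(sites)
    g = nx.Graph()
    g.add_nodes_from(range(len(sites)))
    for i in range(len(sites)):
        a = sites[i]
        for j in range(i + 1, len(sites)):
            b = sites[j]
            if a.l != b.l:
                continue
            if not (a.s == b.s or a.e == b.e or a.middle == b.middle):
                continue
            if _names_compatible(a, b, table):
                g.add_edge(i, j)
    return _components_to_clusters(sites, g)


def join_overlapping(
    sites: Sequence[AlignedSite],
    mode: str = "same_tf",
    table: HomologyTable | None = None,
) -> list[SiteCluster]:
    """Join same-species predictions that simply overlap (relaxed rule).

    mode='same_tf' requires equal normalised names; mode='homologs'
    additionally accepts pairs homologous per the table.  Joining is
    closed transitively (chains merge).
    """
    if mode not in ("same_tf", "homologs"):
        raise ValueError(f"unknown join mode {mode!r}")
    sites = sorted(sites, key=_site_key)
    _require_single_species(sites)
    g = nx.Graph()
    g.add_nodes_from(range(len(sites)))
    for i in range(len(sites)):
        a = sites[i]
        for j in range(i + 1, len(sites)):
            b = sites[j]
            if a.s > b.e or b.s > a.e:
                continue  # no overlap
            same = normalize_tf_name(a.tf_name) == normalize_tf_name(b.tf_name)
            if mode == "same_tf":
                ok = same
            else:
                ok = same or tfs_homologous(a.tf_name, b.tf_name, table)
            if ok:
                g.add_edge(i, j)
    return _components_to_clusters(sites, g)


def singleton_clusters(sites: Sequence[AlignedSite]) -> list[SiteCluster]:
    """One cluster per site — the clustering-disabled degenerate case."""
    sites = sorted(sites, key=_site_key)
    clusters = []
    for cid, site in enumerate(sites, start=1):
        clusters.append(
            SiteCluster(
                cluster_id=cid,
                species=site.species,
                combined_name=_combined_name([site]),
                members=(site,),
                s=site.s,
                e=site.e,
                l=site.l,
                strand=site.match.strand,
            )
        )
    return clusters


def _require_single_species(sites: Sequence[AlignedSite]) -> None:
    species = {s.species for s in sites}
    if len(species) > 1:
        raise ValueError(f"sites from multiple species: {sorted(species)}")


def essentially_overlapping(a: SiteCluster, b: SiteCluster) -> bool:
    """True iff the beginnings or the endings of two aligned predictions
    overlap.

    The beginning of a site is the closed alignment interval [s, s+l],
    the ending [e-l, e].  Comparing these l-sized flanks rather than the
    whole [s, e] span keeps predictions that merely bracket a long
    insertion from being called homologous to everything inside it.
    """
    beg = max(a.s, b.s) <= min(a.s + a.l, b.s + b.l)
    end = max(a.e - a.l, b.e - b.l) <= min(a.e, b.e)
    return beg or end


@dataclass(frozen=True)
class HomologGroup:
    """Cross-species equivalence class of clusters: one tree character.

    At most one cluster per species; ``footprint`` spans all members in
    alignment coordinates.
    """

    group_id: int
    name: str
    clusters: Mapping[str, SiteCluster]
    footprint_s: int
    footprint_e: int

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self.clusters)

    def seq_start(self, species: str) -> int | None:
        c = self.clusters.get(species)
        return c.seq_start if c is not None else None

    def bp_length(self, species: str) -> int | None:
        c = self.clusters.get(species)
        return c.l if c is not None else None

    @property
    def matrix_ids(self) -> tuple[str, ...]:
        ids: set[str] = set()
        for c in self.clusters.values():
            ids.update(c.matrix_ids)
        return tuple(sorted(ids))


def _clusters_homologous(
    a: SiteCluster, b: SiteCluster, table: HomologyTable | None
) -> bool:
    if not essentially_overlapping(a, b):
        return False
    if normalize_tf_name(a.combined_name) == normalize_tf_name(b.combined_name):
        return True
    for na in a.tf_names:
        for nb in b.tf_names:
            if normalize_tf_name(na) == normalize_tf_name(nb):
                return True
            if tfs_homologous(na, nb, table):
                return True
    return False


def build_homolog_groups(
    clusters: Sequence[SiteCluster], table: HomologyTable | None = None
) -> list[HomologGroup]:
    """Link clusters of different species that essentially overlap and are
    bound by the same or homologous factors; groups are the connected
    components.

    If a component captures two clusters of one species, the one with the
    higher best-member mss is kept and the conflict is logged.
    """
    clusters = sorted(
        clusters, key=lambda c: (c.species, c.s, c.e, c.combined_name, c.cluster_id)
    )
    g = nx.Graph()
    g.add_nodes_from(range(len(clusters)))
    for i in range(len(clusters)):
        a = clusters[i]
        for j in range(i + 1, len(clusters)):
            b = clusters[j]
            if a.species == b.species:
                continue
            if _clusters_homologous(a, b, table):
                g.add_edge(i, j)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (clusters[c[0]].s, clusters[c[0]].e,
                              clusters[c[0]].species, clusters[c[0]].cluster_id))
    groups = []
    for gid, comp in enumerate(comps, start=1):
        by_species: dict[str, SiteCluster] = {}
        for idx in comp:
            c = clusters[idx]
            prev = by_species.get(c.species)
            if prev is None:
                by_species[c.species] = c
            else:
                keep = max((prev, c), key=lambda x: (x.mss, -x.s, -x.e, x.cluster_id))
                logger.warning(
                    "species %s contributes two clusters (%s, %s) to one homolog "
                    "group; keeping the higher-scoring one",
                    c.species, prev.combined_name, c.combined_name,
                )
                by_species[c.species] = keep
        member_list = list(by_species.values())
        names = sorted({c.combined_name for c in member_list})
        name = names[0] if len(names) == 1 else "/".join(names)
        groups.append(
            HomologGroup(
                group_id=gid,
                name=name,
                clusters=dict(sorted(by_species.items())),
                footprint_s=min(c.s for c in member_list),
                footprint_e=max(c.e for c in member_list),
            )
        )
    return groups
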