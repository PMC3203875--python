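"""Gain/loss pattern mining and branch length scoring.

A pattern is a transcriptional module: two or more homolog groups gained
(or lost) at the same tree node, whose start-to-start spacing in bp is
identical in every species carrying both members.  Patterns and single
predictions are ranked by the branch length score (BLS): the summed
branch lengths of the subtree(s) in which every leaf carries the
prediction — a measure of evolutionary spread.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx

from .exceptions import TreeError
from .homology import HomologGroup
from .parsimony import GainLossEvent, SpeciesTree


def pairwise_spacing(
    group_a: HomologGroup, group_b: HomologGroup, species: str
) -> int | None:
    """Start-to-start distance (bp, ungapped species coordinates) or None
    if either group lacks a member in that species."""
    sa = group_a.seq_start(species)
    sb = group_b.seq_start(species)
    if sa is None or sb is None:
        return None
    return sb - sa


def spacing_conserved(group_a: HomologGroup, group_b: HomologGroup) -> bool:
    """True iff every species carrying both groups shows one and the same
    spacing (and at least one such species exists)."""
    shared = group_a.species & group_b.species
    spacings = {pairwise_spacing(group_a, group_b, sp) for sp in shared}
    return len(spacings) == 1 and len(shared) >= 1


@dataclass(frozen=True)
class Pattern:
    """A module of >= 2 characters co-gained/lost at one node.

    ``members`` are ordered by alignment footprint start; ``spacings``
    holds the conserved start-to-start bp distance between consecutive
    members; ``supporting_species`` are the leaves carrying every member.
    """

    pattern_id: int
    members: tuple[Hashable, ...]
    origin_node: int
    origin_type: str  # 'gain' | 'loss'
    spacings: tuple[int, ...]
    supporting_species: frozenset[str]
    bls: float

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a pattern needs at least 2 member characters")
        if len(self.spacings) != len(self.members) - 1:
            raise ValueError("spacing vector length must be member count - 1")


def branch_length_score(tree: SpeciesTree, presence: Iterable[str]) -> float:
    """Sum of branch lengths inside the maximal subtrees whose leaves all
    carry the prediction.

    For each maximal node whose descendant leaves are all in ``presence``
    (no qualifying ancestor), the lengths of every branch within that
    subtree are summed; the stem branch above it is excluded, so a
    prediction confined to a single leaf scores 0.
    """
    presence = set(presence)
    unknown = presence - set(tree.leaf_ids)
    if unknown:
        raise TreeError(f"unknown leaves in presence set: {sorted(unknown)}")
    all_in: list[bool] = [False] * tree.n_nodes
    subtree_bl: list[float] = [0.0] * tree.n_nodes
    for v in tree.postorder:
        if tree.is_leaf(v):
            all_in[v] = tree.names[v] in presence
        else:
            all_in[v] = all(all_in[c] for c in tree.children[v])
            subtree_bl[v] = sum(
                subtree_bl[c] + tree.branch_length[c] for c in tree.children[v]
            )
    score = 0.0
    for v in range(tree.n_nodes):
        if not all_in[v]:
            continue
        p = tree.parent[v]
        if p is None or not all_in[p]:
            score += subtree_bl[v]
    return score


def _spacing_value(a: HomologGroup, b: HomologGroup) -> int:
    """The unique conserved spacing between two compatible groups."""
    for sp in sorted(a.species & b.species):
        d = pairwise_spacing(a, b, sp)
        if d is not None:
            return d
    raise ValueError("groups share no species; spacing undefined")


def mine_patterns(
    events: Sequence[GainLossEvent],
    groups: Mapping[Hashable, HomologGroup],
    tree: SpeciesTree,
    gains_only: bool = True,
    include_extant: bool = False,
) -> list[Pattern]:
    """Mine maximal conserved-spacing modules from gain/loss events.

    Events are bucketed by (node, type); within a bucket, characters are
    vertices of a compatibility graph with edges where the pairwise
    spacing is conserved, and every maximal clique of size >= 2 becomes
    a pattern.  By default only gains are considered (gains being more
    informative than parsimony's loss-prone reconstructions) and events
    on extant species (leaf nodes) are ignored.  A module gained
    independently at several nodes yields one pattern per origin node.
    """
    buckets: dict[tuple[int, str], list[Hashable]] = {}
    for ev in events:
        if gains_only and ev.type != "gain":
            continue
        if not include_extant and tree.is_leaf(ev.child):
            continue
        if ev.character not in groups:
            continue
        buckets.setdefault((ev.child, ev.type), []).append(ev.character)

    def char_order(cid: Hashable) -> tuple:
        g = groups[cid]
        return (g.footprint_s, g.footprint_e, str(cid))

    patterns: list[Pattern] = []
    pid = 0
    for (node, etype) in sorted(buckets, key=lambda k: (k[0], k[1])):
        chars = sorted(set(buckets[(node, etype)]), key=char_order)
        if len(chars) < 2:
            continue
        g = nx.Graph()
        g.add_nodes_from(chars)
        for i in range(len(chars)):
            for j in range(i + 1, len(chars)):
                if spacing_conserved(groups[chars[i]], groups[chars[j]]):
                    g.add_edge(chars[i], chars[j])
        cliques = [
            sorted(c, key=char_order) for c in nx.find_cliques(g) if len(c) >= 2
        ]
        cliques.sort(key=lambda c: [char_order(x) for x in c])
        for clique in cliques:
            spacings = tuple(
                _spacing_value(groups[a], groups[b])
                for a, b in zip(clique, clique[1:])
            )
            support = frozenset.intersection(
                *(groups[c].species for c in clique)
            )
            pid += 1
            patterns.append(
                Pattern(
                    pattern_id=pid,
                    members=tuple(clique),
                    origin_node=node,
                    origin_type=etype,
                    spacings=spacings,
                    supporting_species=support,
                    bls=branch_length_score(tree, support),
                )
            )
    return patterns


def rank_and_filter(
    items: Sequence,
    by: str = "bls",
    threshold: float | None = None,
    top_n: int | None = None,
) -> list:
    """Sort descending by a score attribute, drop items below threshold,
    and truncate to the top n.  Ties keep stable id order."""

    def ident(x):
        for attr in ("pattern_id", "group_id", "cluster_id", "matrix_id"):
            if hasattr(x, attr):
                return getattr(x, attr)
        return 0

    kept = [x for x in items if threshold is None or getattr(x, by) >= threshold]
    kept.sort(key=lambda x: (-getattr(x, by), ident(x)))
    if top_n is not None:
        kept = kept[:top_n]
    return kept
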