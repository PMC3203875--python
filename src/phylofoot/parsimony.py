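"""Species trees and Fitch parsimony ancestral presence/absence.

Each homolog group is a binary character on the leaves of a rooted
species tree.  The classic two-pass Fitch procedure reconstructs the
most parsimonious internal states; every edge whose endpoint states
differ is a gain or loss event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping

import dendropy

from .exceptions import TreeError

ABSENT, PRESENT = 0, 1


class SpeciesTree:
    """Rooted species tree with branch lengths, indexed in preorder.

    Wraps a :class:`dendropy.Tree`; node ids are preorder indices (root
    is 0), so parents precede children.  Polytomies are permitted.
    """

    def __init__(self, tree: dendropy.Tree) -> None:
        self._tree = tree
        self.parent: list[int | None] = []
        self.children: list[list[int]] = []
        self.branch_length: list[float] = []
        self.names: list[str] = []
        self._nodes: list[dendropy.Node] = []
        for idx, node in enumerate(tree.preorder_node_iter()):
            node._pf_id = idx
            self._nodes.append(node)
            self.parent.append(node.parent_node._pf_id if node.parent_node else None)
            self.children.append([])
            if node.parent_node is not None:
                self.children[node.parent_node._pf_id].append(idx)
            bl = node.edge.length
            self.branch_length.append(float(bl) if bl is not None else 0.0)
            if node.is_leaf():
                label = node.taxon.label if node.taxon else (node.label or "")
            else:
                label = node.label or f"n{idx}"
            self.names.append(label)
        self.leaves: list[int] = [
            i for i, ch in enumerate(self.children) if not ch
        ]
        self.leaf_ids: dict[str, int] = {}
        for i in self.leaves:
            name = self.names[i]
            if name in self.leaf_ids:
                raise TreeError(f"duplicate leaf name {name!r}")
            self.leaf_ids[name] = i
        if len(self.leaves) < 2:
            raise TreeError("tree must have at least 2 leaves")
        self.postorder: list[int] = list(range(self.n_nodes))[::-1]

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def root(self) -> int:
        return 0

    @property
    def leaf_names(self) -> list[str]:
        return [self.names[i] for i in self.leaves]

    def is_leaf(self, node_id: int) -> bool:
        return not self.children[node_id]

    def descendant_leaves(self, node_id: int) -> frozenset[str]:
        if self.is_leaf(node_id):
            return frozenset([self.names[node_id]])
        out: set[str] = set()
        stack = [node_id]
        while stack:
            v = stack.pop()
            if self.is_leaf(v):
                out.add(self.names[v])
            else:
                stack.extend(self.children[v])
        return frozenset(out)

    def total_branch_length(self) -> float:
        return sum(self.branch_length[1:]) if self.n_nodes > 1 else 0.0

    def newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()


def parse_newick(text: str) -> SpeciesTree:
    """Parse a rooted Newick tree; missing branch lengths default to 0
    with a warning."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise TreeError(f"bad Newick: {exc}") from exc
    missing = sum(
        1
        for node in tree.preorder_node_iter()
        if node.parent_node is not None and node.edge.length is None
    )
    if missing:
        warnings.warn(
            f"{missing} edge(s) without branch length; defaulting to 0",
            stacklevel=2,
        )
    return SpeciesTree(tree)


@dataclass
class CharacterLabeling:
    """Resolved presence/absence per node for each character.

    ``states[char][node_id]`` is 0/1 after the top-down pass;
    ``state_sets`` keeps the bottom-up Fitch sets for inspection.
    """

    states: dict[Hashable, list[int]]
    state_sets: dict[Hashable, list[frozenset[int]]]

    def present_nodes(self, char: Hashable) -> list[int]:
        return [i for i, st in enumerate(self.states[char]) if st == PRESENT]


@dataclass(frozen=True)
class GainLossEvent:
    """A state change on one edge: gain (absent->present) or loss."""

    character: Hashable
    parent: int
    child: int
    type: str  # 'gain' | 'loss'


def fitch_reconstruct(
    tree: SpeciesTree,
    leaf_presence: Mapping[Hashable, Iterable[str]],
    missing: str = "absent",
    observed: Iterable[str] | None = None,
) -> CharacterLabeling:
    """Two-pass Fitch parsimony on binary presence/absence characters.

    Bottom-up, a node's state set is the intersection of its children's
    sets when non-empty, else the union; on polytomies this generalises
    to the states attaining the maximum child count (ties keep both).
    Top-down, the root resolves to absent on ties, and a child takes its
    parent's state whenever its set allows, else its own single state.

    ``observed`` names the species with sequence data (default: all tree
    leaves).  Observed leaves not listed for a character are absent;
    unobserved leaves (e.g. species with no alignment row) are treated as
    absent (``missing='absent'``) or excluded from the reconstruction
    (``missing='exclude'``).
    """
    if missing not in ("absent", "exclude"):
        raise ValueError(f"unknown missing-data mode {missing!r}")
    states: dict[Hashable, list[int]] = {}
    sets: dict[Hashable, list[frozenset[int]]] = {}
    leaf_name_set = set(tree.leaf_ids)
    observed_set = leaf_name_set if observed is None else (
        set(observed) & leaf_name_set
    )
    for char, species in leaf_presence.items():
        species = set(species)
        unknown = species - leaf_name_set
        if unknown:
            raise TreeError(f"character {char!r}: unknown species {sorted(unknown)}")
        node_sets: list[frozenset[int] | None] = [None] * tree.n_nodes
        for v in tree.postorder:
            if tree.is_leaf(v):
                name = tree.names[v]
                if name in species:
                    node_sets[v] = frozenset([PRESENT])
                elif name in observed_set or missing == "absent":
                    node_sets[v] = frozenset([ABSENT])
                else:
                    node_sets[v] = None  # unobserved leaf: excluded
            else:
                child_sets = [node_sets[c] for c in tree.children[v]
                              if node_sets[c] is not None]
                if not child_sets:
                    node_sets[v] = None
                    continue
                count = {ABSENT: 0, PRESENT: 0}
                for cs in child_sets:
                    for st in cs:
                        count[st] += 1
                best = max(count.values())
                node_sets[v] = frozenset(
                    st for st, c in count.items() if c == best
                )
        resolved = [ABSENT] * tree.n_nodes
        for v in range(tree.n_nodes):  # preorder
            ns = node_sets[v]
            if ns is None:
                # excluded leaf / empty subtree: inherit the parent state
                p = tree.parent[v]
                resolved[v] = resolved[p] if p is not None else ABSENT
                continue
            p = tree.parent[v]
            if p is None:
                resolved[v] = ABSENT if len(ns) > 1 else next(iter(ns))
            elif resolved[p] in ns:
                resolved[v] = resolved[p]
            elif len(ns) == 1:
                resolved[v] = next(iter(ns))
            else:
                resolved[v] = ABSENT
        states[char] = resolved
        sets[char] = [ns if ns is not None else frozenset() for ns in node_sets]
    return CharacterLabeling(states=states, state_sets=sets)


def extract_events(
    labeling: CharacterLabeling, tree: SpeciesTree
) -> list[GainLossEvent]:
    """One gain/loss event per edge whose endpoint states differ.

    Sorted by character then parent preorder index; a character constant
    on the tree yields no events.
    """
    try:
        chars = sorted(labeling.states)
    except TypeError:
        chars = sorted(labeling.states, key=str)
    events: list[GainLossEvent] = []
    for char in chars:
        resolved = labeling.states[char]
        for v in range(1, tree.n_nodes):
            p = tree.parent[v]
            if resolved[p] == resolved[v]:
                continue
            etype = "gain" if resolved[v] == PRESENT else "loss"
            events.append(GainLossEvent(character=char, parent=p, child=v, type=etype))
    return events


def parsimony_score(labeling: CharacterLabeling, tree: SpeciesTree,
                    char: Hashable) -> int:
    """Number of state changes implied by the resolved labeling."""
    resolved = labeling.states[char]
    return sum(
        1 for v in range(1, tree.n_nodes) if resolved[tree.parent[v]] != resolved[v]
    )
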