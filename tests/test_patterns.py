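"""Spacing conservation, pattern mining and branch length scoring."""

import numpy as np
import pytest

from phylofoot import (
    SiteCluster,
    TreeError,
    branch_length_score,
    mine_patterns,
    pairwise_spacing,
    parse_newick,
    rank_and_filter,
    spacing_conserved,
)
from phylofoot.homology import HomologGroup
from phylofoot.parsimony import GainLossEvent

from conftest import make_site
from oracles import maximal_conserved_subsets


def make_group(gid, name, per_species, l=8):
    """per_species: dict species -> seq_start (alignment coords == seq
    coords for these gapless test groups)."""
    clusters = {}
    for i, (sp, start) in enumerate(sorted(per_species.items())):
        site = make_site(sp, name, s=start, e=start + l - 1, l=l,
                         seq_start=start, matrix_id=f"{gid}.{i}")
        clusters[sp] = SiteCluster(
            cluster_id=gid * 100 + i, species=sp, combined_name=name,
            members=(site,), s=start, e=start + l - 1, l=l, strand="+")
    starts = list(per_species.values())
    return HomologGroup(group_id=gid, name=name, clusters=clusters,
                        footprint_s=min(starts), footprint_e=max(starts) + l - 1)


class TestSpacing:
    def test_pairwise_distance(self):
        a = make_group(1, "A", {"mouse": 20, "rat": 20})
        b = make_group(2, "B", {"mouse": 32, "rat": 32})
        assert pairwise_spacing(a, b, "mouse") == 12

    def test_undefined_when_member_missing(self):
        a = make_group(1, "A", {"mouse": 20})
        b = make_group(2, "B", {"rat": 32})
        assert pairwise_spacing(a, b, "rat") is None

    def test_antisymmetry(self):
        a = make_group(1, "A", {"mouse": 20})
        b = make_group(2, "B", {"mouse": 35})
        assert pairwise_spacing(a, b, "mouse") == -pairwise_spacing(b, a, "mouse")

    def test_conserved_iff_single_shared_distance(self):
        a = make_group(1, "A", {"m": 10, "r": 15, "h": 20})
        b = make_group(2, "B", {"m": 22, "r": 27, "h": 32})
        assert spacing_conserved(a, b)  # 12 everywhere
        c = make_group(3, "C", {"m": 22, "r": 28, "h": 32})
        assert not spacing_conserved(a, c)  # {12, 13, 12}

    def test_not_conserved_without_shared_species(self):
        a = make_group(1, "A", {"m": 10})
        b = make_group(2, "B", {"r": 22})
        assert not spacing_conserved(a, b)


class TestBranchLengthScore:
    def test_hand_values(self, cherry_tree):
        assert branch_length_score(cherry_tree, {"A", "B"}) == pytest.approx(0.3)
        assert branch_length_score(cherry_tree, {"A", "B", "C"}) == pytest.approx(1.0)
        assert branch_length_score(cherry_tree, {"C"}) == pytest.approx(0.0)

    def test_unknown_leaf_rejected(self, cherry_tree):
        with pytest.raises(TreeError):
            branch_length_score(cherry_tree, {"Z"})

    def test_two_disjoint_clades_sum(self):
        tree = parse_newick("(((A:1,B:1):1,C:1):1,(D:2,E:2):1);")
        # {A,B} clade (2) plus {D,E} clade (4); stems excluded
        assert branch_length_score(tree, {"A", "B", "D", "E"}) == pytest.approx(6.0)

    def test_monotone_in_presence(self):
        rng = np.random.default_rng(5)
        from phylofoot import make_tree
        tree = make_tree(7, seed=9)
        leaves = tree.leaf_names
        for _ in range(25):
            k = int(rng.integers(0, len(leaves)))
            base = set(rng.choice(leaves, size=k, replace=False))
            extra = set(base)
            remaining = [l for l in leaves if l not in base]
            if remaining:
                extra.add(remaining[int(rng.integers(0, len(remaining)))])
            assert branch_length_score(tree, extra) >= \
                branch_length_score(tree, base) - 1e-12


class TestMiner:
    def _events(self, tree, node, chars, etype="gain"):
        return [GainLossEvent(character=c, parent=tree.parent[node],
                              child=node, type=etype) for c in chars]

    def test_three_conserved_characters_one_pattern(self):
        tree = parse_newick("(((A:1,B:1):1,C:1):1,D:1);")
        node = tree.parent[tree.leaf_ids["A"]]  # ancestor of A,B
        groups = {
            1: make_group(1, "X", {"A": 10, "B": 10}),
            2: make_group(2, "Y", {"A": 25, "B": 25}),
            3: make_group(3, "Z", {"A": 41, "B": 41}),
        }
        pats = mine_patterns(self._events(tree, node, [1, 2, 3]), groups, tree)
        assert len(pats) == 1
        p = pats[0]
        assert p.members == (1, 2, 3)
        assert p.spacings == (15, 16)
        assert p.supporting_species == {"A", "B"}
        assert p.origin_node == node

    def test_characters_at_different_nodes_do_not_combine(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        n_ab = tree.parent[tree.leaf_ids["A"]]
        n_cd = tree.parent[tree.leaf_ids["C"]]
        groups = {1: make_group(1, "X", {"A": 10, "B": 10}),
                  2: make_group(2, "Y", {"C": 25, "D": 25})}
        events = self._events(tree, n_ab, [1]) + self._events(tree, n_cd, [2])
        assert mine_patterns(events, groups, tree) == []

    def test_losses_excluded_by_default_included_on_request(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        node = tree.parent[tree.leaf_ids["A"]]
        groups = {1: make_group(1, "X", {"C": 10, "D": 10}),
                  2: make_group(2, "Y", {"C": 30, "D": 30})}
        loss_events = self._events(tree, node, [1, 2], etype="loss")
        assert mine_patterns(loss_events, groups, tree) == []
        pats = mine_patterns(loss_events, groups, tree, gains_only=False)
        assert len(pats) == 1 and pats[0].origin_type == "loss"

    def test_extant_gains_ignored_by_default(self):
        tree = parse_newick("((A:1,B:1):1,C:1);")
        leaf = tree.leaf_ids["A"]
        groups = {1: make_group(1, "X", {"A": 10}),
                  2: make_group(2, "Y", {"A": 30})}
        events = self._events(tree, leaf, [1, 2])
        assert mine_patterns(events, groups, tree) == []
        pats = mine_patterns(events, groups, tree, include_extant=True)
        assert len(pats) == 1 and pats[0].origin_node == leaf

    @pytest.mark.parametrize("seed", range(12))
    def test_equals_brute_force_maximal_subsets(self, seed):
        """Mined patterns equal exhaustive maximal conserved-spacing
        subset enumeration on random buckets of up to 12 characters."""
        rng = np.random.default_rng(seed)
        tree = parse_newick("(((A:1,B:1):1,(C:1,D:1):1):1,E:1);")
        node = 1  # internal
        species = ["A", "B", "C", "D"]
        n_chars = int(rng.integers(2, 13))
        groups = {}
        for cid in range(1, n_chars + 1):
            # random subset of species and starts; occasional shared
            # offsets create conserved pairs
            carriers = [sp for sp in species if rng.random() < 0.8] or ["A"]
            base = int(rng.integers(1, 50))
            per_species = {}
            for sp in carriers:
                jitter = int(rng.integers(0, 3)) if rng.random() < 0.4 else 0
                per_species[sp] = base + 17 * species.index(sp) // 2 + jitter
            groups[cid] = make_group(cid, f"T{cid}", per_species)
        events = [GainLossEvent(character=c, parent=0, child=node, type="gain")
                  for c in groups]
        pats = mine_patterns(events, groups, tree)
        expected = maximal_conserved_subsets(
            list(groups),
            lambda a, b: spacing_conserved(groups[a], groups[b]),
        )
        assert {frozenset(p.members) for p in pats} == expected

    def test_every_pattern_has_conserved_spacing_vector(self):
        rng = np.random.default_rng(3)
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        groups = {c: make_group(c, f"T{c}", {
            sp: int(rng.integers(1, 40))
            for sp in ["A", "B"] if rng.random() < 0.9})
            for c in range(1, 8)}
        groups = {c: g for c, g in groups.items() if g.species}
        events = [GainLossEvent(character=c, parent=0, child=1, type="gain")
                  for c in groups]
        for p in mine_patterns(events, groups, tree):
            assert len(p.members) >= 2
            assert len(p.spacings) == len(p.members) - 1
            for sp in p.supporting_species:
                got = tuple(
                    pairwise_spacing(groups[a], groups[b], sp)
                    for a, b in zip(p.members, p.members[1:])
                )
                assert got == p.spacings


class TestRanking:
    class Item:
        def __init__(self, pid, bls):
            self.pattern_id = pid
            self.bls = bls

    def test_threshold_and_order(self):
        items = [self.Item(1, 0.9), self.Item(2, 0.3), self.Item(3, 0.5)]
        out = rank_and_filter(items, by="bls", threshold=0.4)
        assert [i.bls for i in out] == [0.9, 0.5]

    def test_top_n(self):
        items = [self.Item(1, 0.9), self.Item(2, 0.3)]
        assert [i.pattern_id for i in rank_and_filter(items, top_n=1)] == [1]

    def test_ties_keep_id_order(self):
        items = [self.Item(3, 0.5), self.Item(1, 0.5), self.Item(2, 0.5)]
        assert [i.pattern_id for i in rank_and_filter(items)] == [1, 2, 3]
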