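"""Name normalisation, redundancy clustering and homolog-group building."""

import itertools

import numpy as np
import pytest

from phylofoot import (
    HomologyTable,
    build_homolog_groups,
    cluster_redundant,
    essentially_overlapping,
    join_overlapping,
    normalize_tf_name,
    singleton_clusters,
    tfs_homologous,
)
from phylofoot.homology import SiteCluster


@pytest.mark.parametrize(
    "name,expected",
    [
        ("Sox2", "sox"),
        ("Sox17", "sox"),
        ("STAT 3", "stat"),
        ("POU5F1", "pouf"),
        ("p53", "p"),
        ("123", "123"),  # all-symbol name falls back to lowercased original
    ],
)
def test_normalize_tf_name(name, expected):
    assert normalize_tf_name(name) == expected


class TestHomologyTable:
    def test_symbols_sharing_group_are_homologous(self):
        table = HomologyTable([(1, "mouse", "Pou5f1"), (1, "human", "POU5F1")])
        assert tfs_homologous("Pou5f1", "POU5F1", table)

    def test_different_groups_not_homologous(self):
        table = HomologyTable([(1, "mouse", "Gata1"), (2, "mouse", "Lef1")])
        assert not tfs_homologous("Gata1", "Lef1", table)

    def test_absent_symbol_and_empty_table(self):
        table = HomologyTable([(1, "mouse", "Sox2")])
        assert not tfs_homologous("Sox2", "Oct4", table)
        assert not tfs_homologous("Sox2", "Sox2", HomologyTable())

    def test_tsv_round_trip(self):
        table = HomologyTable.from_tsv(
            "group_id\tspecies\tgene_symbol\n1\tmouse\tSox2\n1\thuman\tSOX2\n"
        )
        assert tfs_homologous("sox2", "SOX2", table)


class TestClusterRedundant:
    def test_same_family_same_coords_merge_with_combined_name(self, site_factory):
        a = site_factory("mouse", "Sox2", s=100, e=107, l=8, matrix_id="MA1")
        b = site_factory("mouse", "SOX17", s=100, e=107, l=8, matrix_id="MA2")
        clusters = cluster_redundant([a, b])
        assert len(clusters) == 1
        assert clusters[0].combined_name == "Sox"
        assert len(clusters[0].members) == 2

    def test_unrelated_names_stay_apart(self, site_factory):
        a = site_factory("mouse", "Gata1", s=100, e=107, l=8)
        b = site_factory("mouse", "Lef1", s=100, e=107, l=8)
        assert len(cluster_redundant([a, b])) == 2

    def test_homology_table_can_link_different_names(self, site_factory):
        a = site_factory("mouse", "Pou5f1", s=50, e=57, l=8, matrix_id="M1")
        b = site_factory("mouse", "Oct4", s=50, e=57, l=8, matrix_id="M2")
        table = HomologyTable([(7, "mouse", "Pou5f1"), (7, "human", "Oct4")])
        merged = cluster_redundant([a, b], table)
        assert len(merged) == 1
        assert merged[0].combined_name == "Oct4/Pou5f1"

    def test_shared_middle_links(self, site_factory):
        # middle = floor((s+e)/2): (10+17)//2 == (11+16)//2 == 13
        a = site_factory("m", "Sox2", s=10, e=17, l=6, matrix_id="M1")
        b = site_factory("m", "Sox9", s=11, e=16, l=6, matrix_id="M2")
        assert len(cluster_redundant([a, b])) == 1

    def test_different_lengths_never_merge(self, site_factory):
        a = site_factory("m", "Sox2", s=10, e=17, l=8)
        b = site_factory("m", "Sox2", s=10, e=17, l=6)
        clusters = cluster_redundant([a, b])
        assert len(clusters) == 2
        for c in clusters:
            assert len({m.l for m in c.members}) == 1

    def test_order_independence(self, site_factory):
        rng = np.random.default_rng(0)
        sites = []
        for i in range(30):
            s = int(rng.integers(1, 80))
            l = int(rng.integers(5, 9))
            name = rng.choice(["Sox2", "Sox9", "Gata1", "Lef1"])
            sites.append(site_factory("m", str(name), s=s, e=s + l - 1, l=l,
                                      matrix_id=f"M{i}"))
        ref = cluster_redundant(sites)
        for perm_seed in range(5):
            perm = list(np.random.default_rng(perm_seed).permutation(30))
            shuffled = [sites[i] for i in perm]
            out = cluster_redundant(shuffled)
            assert [(c.species, c.s, c.e, c.combined_name,
                     tuple(sorted(m.match.matrix_id for m in c.members)))
                    for c in out] == \
                   [(c.species, c.s, c.e, c.combined_name,
                     tuple(sorted(m.match.matrix_id for m in c.members)))
                    for c in ref]

    def test_mixed_strand_recorded(self, site_factory):
        a = site_factory("m", "Sox2", s=5, e=12, l=8, strand="+", matrix_id="M1")
        b = site_factory("m", "Sox9", s=5, e=12, l=8, strand="-", matrix_id="M2")
        assert cluster_redundant([a, b])[0].strand == "mixed"


class TestJoinOverlapping:
    def test_same_tf_overlap_joined(self, site_factory):
        a = site_factory("m", "Sox2", s=100, e=107, l=8, matrix_id="M1")
        b = site_factory("m", "Sox2", s=104, e=111, l=8, matrix_id="M2")
        assert len(join_overlapping([a, b], mode="same_tf")) == 1

    def test_different_tf_overlap_not_joined(self, site_factory):
        a = site_factory("m", "Sox2", s=100, e=107, l=8)
        b = site_factory("m", "Oct4", s=104, e=111, l=8)
        assert len(join_overlapping([a, b], mode="same_tf")) == 2
        assert len(join_overlapping([a, b], mode="homologs")) == 2

    def test_homologs_mode_uses_table(self, site_factory):
        a = site_factory("m", "Pou5f1", s=100, e=107, l=8, matrix_id="M1")
        b = site_factory("m", "Oct4", s=104, e=111, l=8, matrix_id="M2")
        table = HomologyTable([(7, "m", "Pou5f1"), (7, "h", "Oct4")])
        assert len(join_overlapping([a, b], mode="homologs", table=table)) == 1

    def test_transitive_closure_of_chains(self, site_factory):
        a = site_factory("m", "Sox2", s=1, e=8, l=8, matrix_id="M1")
        b = site_factory("m", "Sox2", s=6, e=13, l=8, matrix_id="M2")
        c = site_factory("m", "Sox2", s=12, e=19, l=8, matrix_id="M3")
        # a overlaps b, b overlaps c, a does not overlap c
        clusters = join_overlapping([a, b, c], mode="same_tf")
        assert len(clusters) == 1
        assert len(clusters[0].members) == 3


class TestEssentialOverlap:
    def _cluster(self, species, s, e, l, name="Sox2"):
        from conftest import make_site
        site = make_site(species, name, s=s, e=e, l=l)
        return SiteCluster(cluster_id=1, species=species, combined_name=name,
                           members=(site,), s=s, e=e, l=l, strand="+")

    def test_beginnings_overlap(self):
        a = self._cluster("m", 10, 25, 10)
        b = self._cluster("r", 18, 30, 10)
        # beginnings [10,20] and [18,28] intersect
        assert essentially_overlapping(a, b)

    def test_disjoint_sites(self):
        a = self._cluster("m", 10, 14, 5)
        b = self._cluster("r", 40, 44, 5)
        assert not essentially_overlapping(a, b)

    def test_self_overlap(self):
        a = self._cluster("m", 10, 17, 8)
        assert essentially_overlapping(a, a)

    def test_gapped_site_bracketing_insertion_not_linked(self):
        # a spans a 30-column insertion (l=8 but e-s is large); b sits
        # inside the insertion: neither beginnings nor endings touch.
        a = self._cluster("m", 10, 48, 8)
        b = self._cluster("r", 25, 32, 8)
        assert not essentially_overlapping(a, b)


class TestHomologGroups:
    def test_three_species_same_columns_one_group(self, site_factory):
        clusters = []
        for i, sp in enumerate(["mouse", "rat", "human"]):
            site = site_factory(sp, "Sox2", s=100 + i, e=107 + i, l=8)
            clusters.append(SiteCluster(
                cluster_id=i + 1, species=sp, combined_name="Sox",
                members=(site,), s=100 + i, e=107 + i, l=8, strand="+"))
        groups = build_homolog_groups(clusters)
        assert len(groups) == 1
        assert groups[0].species == {"mouse", "rat", "human"}
        assert groups[0].footprint_s == 100 and groups[0].footprint_e == 109

    def test_same_name_disjoint_columns_separate_groups(self, site_factory):
        mk = TestEssentialOverlap()._cluster
        a = mk("mouse", 10, 17, 8)
        b = mk("rat", 60, 67, 8)
        groups = build_homolog_groups([a, b])
        assert len(groups) == 2

    def test_duplicate_species_keeps_best_mss(self, site_factory, caplog):
        from conftest import make_site
        hi = make_site("mouse", "Sox2", s=10, e=17, l=8, mss=0.95, matrix_id="M1")
        lo = make_site("mouse", "Sox9", s=11, e=18, l=8, mss=0.85, matrix_id="M2")
        rat = make_site("rat", "Sox2", s=10, e=17, l=8, mss=0.9, matrix_id="M3")
        cl = [
            SiteCluster(1, "mouse", "Sox", (hi,), 10, 17, 8, "+"),
            SiteCluster(2, "mouse", "Sox", (lo,), 11, 18, 8, "+"),
            SiteCluster(3, "rat", "Sox", (rat,), 10, 17, 8, "+"),
        ]
        with caplog.at_level("WARNING"):
            groups = build_homolog_groups(cl)
        assert len(groups) == 1
        assert groups[0].clusters["mouse"].mss == pytest.approx(0.95)
        assert "two clusters" in caplog.text

    def test_matches_brute_force_components(self, site_factory):
        """Groups equal connected components of the pairwise predicate."""
        from phylofoot.homology import _clusters_homologous
        rng = np.random.default_rng(42)
        clusters = []
        cid = 0
        for sp in ["m", "r", "h", "d"]:
            for _ in range(5):
                s = int(rng.integers(1, 60))
                l = int(rng.integers(5, 9))
                name = str(rng.choice(["Sox2", "Gata1", "Lef1"]))
                cid += 1
                site = site_factory(sp, name, s=s, e=s + l - 1, l=l,
                                    matrix_id=f"M{cid}")
                clusters.append(SiteCluster(cid, sp, name, (site,),
                                            s, s + l - 1, l, "+"))
        groups = build_homolog_groups(clusters)
        # brute force union-find over all pairs
        parent = list(range(len(clusters)))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for i, j in itertools.combinations(range(len(clusters)), 2):
            a, b = clusters[i], clusters[j]
            if a.species != b.species and _clusters_homologous(a, b, None):
                parent[find(i)] = find(j)
        comp = {}
        for i in range(len(clusters)):
            comp.setdefault(find(i), set()).add(clusters[i].cluster_id)
        expected = {frozenset(v) for v in comp.values()}
        got = set()
        for g in groups:
            ids = set()
            for c in g.clusters.values():
                ids.add(c.cluster_id)
            got.add(frozenset(ids))
        # groups drop duplicate same-species clusters; compare components
        # by checking each group is a subset of exactly one component
        for ids in got:
            assert sum(1 for e in expected if ids <= e) == 1
        assert len(got) == len([e for e in expected])

    def test_singletons_when_clustering_disabled(self, site_factory):
        sites = [
            site_factory("m", "Sox2", s=10, e=17, l=8, matrix_id="M1"),
            site_factory("m", "Sox9", s=10, e=17, l=8, matrix_id="M2"),
        ]
        clusters = singleton_clusters(sites)
        assert len(clusters) == 2
        assert all(len(c.members) == 1 for c in clusters)
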