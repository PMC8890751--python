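import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import min_pure_clades_over_rootings, random_topology
from vertmark import treeio
from vertmark.likelihood import as_graph
from vertmark.metrics import (MetricError, ab_stem_length, bootstrap_trees,
                              check_reciprocal_monophyly, cluster_blocks,
                              mad_root, relative_ab_distance,
                              root_to_tip_stats, split_score)
from vertmark.treeio import domain_map_from_prefixes


class TestMonophyly:
    def test_clean_split_true(self, two_domain_tree, two_domain_map):
        assert check_reciprocal_monophyly(two_domain_tree, two_domain_map)

    def test_interleaved_false(self):
        t = treeio.parse_newick("((A_1:1,B_1:1):1,(A_2:1,B_2:1):1);")
        tmap = domain_map_from_prefixes(["A_1", "A_2", "B_1", "B_2"])
        assert not check_reciprocal_monophyly(t, tmap)

    def test_single_domain_errors(self):
        t = treeio.parse_newick("((A_1:1,A_2:1):1,A_3:1,A_4:1);")
        tmap = domain_map_from_prefixes(["A_1", "A_2", "A_3", "A_4"])
        with pytest.raises(MetricError, match="single-domain"):
            check_reciprocal_monophyly(t, tmap)


class TestAbStem:
    def test_central_edge_length(self, two_domain_tree, two_domain_map):
        res = ab_stem_length(two_domain_tree, two_domain_map)
        assert res.ab_branch_length == pytest.approx(2.0)
        assert res.total_tree_length == pytest.approx(6.0)
        assert res.ab_proportion == pytest.approx(2.0 / 6.0)

    def test_zero_stem_zero_proportion(self):
        t = treeio.parse_newick("((A_1:1,A_2:1):0,(B_1:1,B_2:1):0);")
        tmap = domain_map_from_prefixes(["A_1", "A_2", "B_1", "B_2"])
        assert ab_stem_length(t, tmap).ab_proportion == 0.0

    def test_nonmonophyletic_instructs_constrained_search(self):
        t = treeio.parse_newick("((A_1:1,B_1:1):1,(A_2:1,B_2:1):1);")
        tmap = domain_map_from_prefixes(["A_1", "A_2", "B_1", "B_2"])
        with pytest.raises(MetricError, match="constrained"):
            ab_stem_length(t, tmap)


class TestClusterBlocks:
    def test_monophyletic_cluster_one_block(self, two_domain_tree):
        assert cluster_blocks(two_domain_tree, {"A_1", "A_2"}) == 1

    def test_three_scattered_leaves_three_blocks(self):
        t = treeio.parse_newick("((c1:1,x1:1):1,(c2:1,x2:1):1,(c3:1,x3:1):1);")
        assert cluster_blocks(t, {"c1", "c2", "c3"}) == 3

    def test_singleton_and_full_cluster(self, two_domain_tree):
        assert cluster_blocks(two_domain_tree, {"A_1"}) == 1
        assert cluster_blocks(two_domain_tree,
                              {"A_1", "A_2", "B_1", "B_2"}) == 1

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_matches_min_pure_clades_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        labels = [f"t{i}" for i in range(n)]
        g = random_topology(rng, labels)
        k = int(rng.integers(1, n))
        cluster = frozenset(rng.choice(labels, size=k, replace=False))
        assert cluster_blocks(g, set(cluster)) == \
            min_pure_clades_over_rootings(g, cluster)


class TestSplitScore:
    def test_perfectly_monophyletic_scores_zero(self, two_domain_tree, two_domain_map):
        res = split_score([two_domain_tree] * 10, two_domain_map)
        assert res.mean_total_splits == 0.0
        assert res.normalized_score == 0.0

    def test_single_broken_cluster(self):
        broken = treeio.parse_newick(
            "((A_1:1,B_1:1):1,((A_2:1,A_3:1):1,(B_2:1,B_3:1):1):1);")
        tmap = domain_map_from_prefixes(
            ["A_1", "A_2", "A_3", "B_1", "B_2", "B_3"])
        res = split_score([broken], tmap)
        # both domains split into 2 blocks -> 2 extra blocks total
        assert res.mean_total_splits == 2.0
        assert res.normalized_score == pytest.approx(2.0 / 6.0)

    def test_averaging_over_bootstrap_trees(self, two_domain_map, two_domain_tree):
        broken = treeio.parse_newick("((A_1:1,B_1:1):1,(A_2:1,B_2:1):1);")
        trees = [two_domain_tree] * 50 + [broken] * 50
        res = split_score(trees, two_domain_map)
        assert res.mean_total_splits == pytest.approx(
            (0 * 50 + 2 * 50) / 100.0)

    def test_small_cluster_flagged(self):
        t = treeio.parse_newick("((A_1:1,A_2:1):1,(B_1:1,A_3:1):1);")
        tmap = domain_map_from_prefixes(["A_1", "A_2", "A_3", "B_1"])
        res = split_score([t], tmap)
        assert "B" in res.skipped_clusters

    def test_within_domain_ranks(self):
        t = treeio.parse_newick(
            "(((A_1:1,A_2:1):1,(A_3:1,A_4:1):1):1,(B_1:1,B_2:1):0);")
        taxa = ["A_1", "A_2", "A_3", "A_4", "B_1", "B_2"]
        tmap = domain_map_from_prefixes(taxa)
        for t_i in taxa:
            dom = t_i.split("_")[0]
            tmap.clusters[t_i] = {
                "class": "c1" if t_i in ("A_1", "A_3") else "c2",
                "phylum": "p1",
            }
        res = split_score([t], tmap, level="within_domain")
        # class c1 = {A_1, A_3} split across the two archaeal cherries
        assert res.mean_total_splits == 2.0

    def test_score_zero_iff_all_monophyletic(self, two_domain_map, two_domain_tree):
        broken = treeio.parse_newick("((A_1:1,B_1:1):1,(A_2:1,B_2:1):1);")
        assert split_score([two_domain_tree], two_domain_map).normalized_score == 0
        assert split_score([two_domain_tree, broken],
                           two_domain_map).normalized_score > 0


class TestRelativeAbDistance:
    def test_symmetric_quartet_hand_value(self):
        # terminals 1, stem s: score = s / (2 + s)
        for s, want in ((2.0, 0.5), (0.0, 0.0), (6.0, 0.75)):
            t = treeio.parse_newick(f"((A_1:1,A_2:1):{s},(B_1:1,B_2:1):0);")
            tmap = domain_map_from_prefixes(["A_1", "A_2", "B_1", "B_2"])
            assert relative_ab_distance(t, tmap) == pytest.approx(want)

    def test_monotone_in_stem(self):
        tmap = domain_map_from_prefixes(["A_1", "A_2", "B_1", "B_2"])
        vals = [relative_ab_distance(
            treeio.parse_newick(f"((A_1:1,A_2:1):{s},(B_1:1,B_2:1):0);"), tmap)
            for s in (0.5, 1.0, 2.0, 4.0)]
        assert np.all(np.diff(vals) > 0)

    def test_defined_for_nonmonophyletic_trees(self):
        t = treeio.parse_newick("((A_1:1,B_1:1):1,(A_2:1,B_2:1):1);")
        tmap = domain_map_from_prefixes(["A_1", "A_2", "B_1", "B_2"])
        assert np.isfinite(relative_ab_distance(t, tmap))


class TestMadRooting:
    def test_ultrametric_tree_recovers_clock_root(self):
        t = treeio.parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        rooted, pos = mad_root(t)
        assert pos.rms_deviation == pytest.approx(0.0, abs=1e-12)
        mean, mn, mx = root_to_tip_stats(rooted)
        assert mn == pytest.approx(mx) == pytest.approx(2.0)

    def test_three_leaf_oracle(self):
        # lengths a:1, b:1, c:3 -> root on c's edge, 1 from the hub
        t = treeio.parse_newick("(a:1,b:1,c:3);")
        rooted, pos = mad_root(t)
        g = as_graph(t)
        u, v = pos.edge
        assert g.label.get(v) == "c" or g.label.get(u) == "c"
        mean, mn, mx = root_to_tip_stats(rooted)
        assert mn == pytest.approx(2.0) and mx == pytest.approx(2.0)
        assert pos.rms_deviation <= _grid_rms_minimum(t) + 1e-6

    def test_closed_form_beats_grid_search(self):
        t = treeio.parse_newick("((a:0.7,b:1.9):0.4,(c:0.2,d:2.4):0.9);")
        _, pos = mad_root(t)
        assert pos.rms_deviation <= _grid_rms_minimum(t) + 1e-6

    def test_invariant_to_leaf_relabeling(self):
        t1 = treeio.parse_newick("((a:1,b:2):0.5,(c:0.3,d:1.7):0.5);")
        t2 = treeio.parse_newick("((d:1,c:2):0.5,(b:0.3,a:1.7):0.5);")
        _, p1 = mad_root(t1)
        _, p2 = mad_root(t2)
        assert p1.rms_deviation == pytest.approx(p2.rms_deviation, abs=1e-12)

    def test_all_zero_lengths_error(self):
        t = treeio.parse_newick("((a:0,b:0):0,c:0,d:0);")
        with pytest.raises(MetricError):
            mad_root(t)


def _grid_rms_minimum(tree, n_grid=2000):
    """Brute-force MAD objective over a fine grid of root positions."""
    g = as_graph(tree)
    leaves = sorted(g.leaves(), key=lambda n: g.label[n])
    dist = {}
    for lf in leaves:
        d = {lf: 0.0}
        stack = [lf]
        while stack:
            x = stack.pop()
            for y, t in g.adj[x].items():
                if y not in d:
                    d[y] = d[x] + t
                    stack.append(y)
        dist[lf] = d
    best = np.inf
    for u, v in g.edges():
        d_uv = g.adj[u][v]
        side_v = g.side_leaves(u, v)
        us = [l for l in leaves if g.label[l] not in side_v]
        vs = [l for l in leaves if g.label[l] in side_v]
        for x in np.linspace(0, d_uv, n_grid):
            devs = []
            for b in us:
                for c in vs:
                    dbc = dist[b][u] + d_uv + dist[c][v]
                    if dbc > 0:
                        devs.append((2 * (x + dist[b][u]) / dbc - 1) ** 2)
            if devs:
                best = min(best, float(np.sqrt(np.mean(devs))))
    return best


class TestRootToTip:
    def test_hand_built_tree(self):
        t = treeio.parse_newick("((a:1,b:2):0.5,(c:0.25,d:1):1.5);", rooted=True)
        # paths: a=0.5+1, b=0.5+2, c=1.5+0.25, d=1.5+1
        mean, mn, mx = root_to_tip_stats(t)
        assert (mn, mx) == (1.5, 2.5)
        assert mean == pytest.approx((1.5 + 2.5 + 1.75 + 2.5) / 4)

    def test_scaling_property(self):
        t1 = treeio.parse_newick("((a:1,b:2):0.5,(c:0.25,d:1):1.5);", rooted=True)
        t2 = treeio.parse_newick("((a:2,b:4):1,(c:0.5,d:2):3);", rooted=True)
        m1 = root_to_tip_stats(t1)
        m2 = root_to_tip_stats(t2)
        assert np.allclose(np.array(m2), 2 * np.array(m1))


class TestScoreRelationships:
    def test_stem_and_relative_ab_distance_positively_correlated(self):
        # across simulated families with varying stem lengths, the two
        # proximity measures move together
        from vertmark.simulate import SimulationConfig, simulate_species_tree
        from vertmark.toptests import pearson_correlation
        stems, rels = [], []
        for i, s in enumerate(np.linspace(0.1, 3.0, 12)):
            cfg = SimulationConfig(n_taxa_A=5, n_taxa_B=5, stem_length=float(s),
                                   seed=100 + i)
            sp = simulate_species_tree(cfg)
            tmap = domain_map_from_prefixes(
                [l.taxon.label for l in sp.leaf_node_iter()])
            stems.append(ab_stem_length(sp, tmap).ab_branch_length)
            rels.append(relative_ab_distance(sp, tmap))
        R, p = pearson_correlation(stems, rels)
        assert R > 0.8 and p < 0.01


class TestBootstrapTrees:
    def test_reproducible_and_clamped(self):
        rng = np.random.default_rng(0)
        from vertmark.alignment import AMINO_ACIDS, Alignment
        chars = np.array(list(AMINO_ACIDS))
        data = chars[rng.integers(20, size=(6, 120))]
        aln = Alignment([f"t{i}" for i in range(6)], data)
        b1 = bootstrap_trees(aln, n_replicates=5, seed=9)
        b2 = bootstrap_trees(aln, n_replicates=5, seed=9)
        assert [t.to_newick() for t in b1] == [t.to_newick() for t in b2]
        assert all(g.adj[u][v] >= 0 for g in b1 for u, v in g.edges())
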