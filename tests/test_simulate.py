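import numpy as np
import pytest

from vertmark.likelihood import as_graph
from vertmark.metrics import check_reciprocal_monophyly
from vertmark.model import equal_rates_model, lg_model
from vertmark.simulate import (SimulationConfig, SimulationError,
                               merge_paralogs, simulate_alignment,
                               simulate_family, simulate_gene_tree,
                               simulate_species_tree)
from vertmark.treeio import domain_map_from_prefixes, tree_to_newick


class TestSpeciesTree:
    def test_four_leaf_central_edge_is_stem(self):
        cfg = SimulationConfig(n_taxa_A=2, n_taxa_B=2, stem_length=1.0, seed=0)
        sp = simulate_species_tree(cfg)
        g = as_graph(sp)
        split = frozenset({"A_1", "A_2"})
        u, v = g.find_bipartition_edge(split)
        assert g.adj[u][v] == pytest.approx(1.0)

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=42)
        s1 = tree_to_newick(simulate_species_tree(cfg))
        s2 = tree_to_newick(simulate_species_tree(cfg))
        assert s1 == s2

    def test_zero_stem_still_bipartitions_domains(self):
        cfg = SimulationConfig(n_taxa_A=3, n_taxa_B=3, stem_length=0.0, seed=1)
        sp = simulate_species_tree(cfg)
        tmap = domain_map_from_prefixes([l.taxon.label for l in sp.leaf_node_iter()])
        assert check_reciprocal_monophyly(sp, tmap)

    def test_ultrametric_with_requested_height(self):
        cfg = SimulationConfig(n_taxa_A=6, n_taxa_B=4, stem_length=0.8,
                               domain_tree_height=1.3, seed=5)
        sp = simulate_species_tree(cfg)
        depths = [l.distance_from_root() for l in sp.leaf_node_iter()]
        assert np.ptp(depths) < 1e-9
        assert depths[0] == pytest.approx(0.4 + 1.3)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(SimulationError):
            SimulationConfig(n_taxa_A=1)


class TestGeneTree:
    def test_no_transfers_is_identity_topology(self):
        cfg = SimulationConfig(n_taxa_A=4, n_taxa_B=4, seed=3)
        sp = simulate_species_tree(cfg)
        gt, log = simulate_gene_tree(sp, cfg)
        assert log.records == []
        g1, g2 = as_graph(sp), as_graph(gt)
        leaves = frozenset(g1.label.values())
        norm = lambda g: {min(s, leaves - s, key=sorted)
                          for s in g.bipartitions().values()}
        assert norm(g1) == norm(g2)

    @pytest.mark.parametrize("seed", range(5))
    def test_interdomain_transfer_breaks_monophyly(self, seed):
        cfg = SimulationConfig(n_taxa_A=5, n_taxa_B=5, n_transfers=1, seed=seed)
        sp = simulate_species_tree(cfg)
        gt, log = simulate_gene_tree(sp, cfg)
        tmap = domain_map_from_prefixes([l.taxon.label for l in gt.leaf_node_iter()])
        assert not check_reciprocal_monophyly(gt, tmap)
        assert len(log.records) == 1 and log.records[0]["event"] == "transfer"

    def test_transfers_preserve_leaf_depths(self):
        cfg = SimulationConfig(n_taxa_A=5, n_taxa_B=5, n_transfers=3, seed=7)
        sp = simulate_species_tree(cfg)
        gt, _ = simulate_gene_tree(sp, cfg)
        before = {l.taxon.label: l.distance_from_root()
                  for l in sp.leaf_node_iter()}
        after = {l.taxon.label: l.distance_from_root()
                 for l in gt.leaf_node_iter()}
        for taxon in before:
            assert after[taxon] == pytest.approx(before[taxon], abs=1e-9)

    def test_event_log_reproducible(self):
        cfg = SimulationConfig(n_taxa_A=5, n_taxa_B=5, n_transfers=2, seed=11)
        sp = simulate_species_tree(cfg)
        _, log1 = simulate_gene_tree(sp, cfg)
        _, log2 = simulate_gene_tree(sp, cfg)
        assert log1.records == log2.records


class TestMergeParalogs:
    def _two_trees(self, seed=13):
        cfg = SimulationConfig(n_taxa_A=4, n_taxa_B=4, seed=seed)
        sp = simulate_species_tree(cfg)
        t1, _ = simulate_gene_tree(sp, cfg)
        t2, _ = simulate_gene_tree(sp, SimulationConfig(
            **{**cfg.__dict__, "seed": seed + 1}))
        return t1, t2

    def test_fraction_zero_keeps_copy_one(self):
        t1, t2 = self._two_trees()
        merged, log = merge_paralogs(t1, t2, 0.0, seed=1)
        assert log.records[0]["affected_leaves"] == ""
        assert sorted(l.taxon.label for l in merged.leaf_node_iter()) == \
            sorted(l.taxon.label for l in t1.leaf_node_iter())

    def test_fraction_one_keeps_copy_two(self):
        t1, t2 = self._two_trees()
        merged, log = merge_paralogs(t1, t2, 1.0, seed=1)
        assert len(log.records[0]["affected_leaves"].split(",")) == 8

    def test_mixed_family_matches_event_log(self):
        t1, t2 = self._two_trees()
        merged, log = merge_paralogs(t1, t2, 0.5, seed=21)
        from_copy2 = set(log.records[0]["affected_leaves"].split(","))
        labels = {l.taxon.label for l in merged.leaf_node_iter()}
        assert labels == {l.taxon.label for l in t1.leaf_node_iter()}
        assert 0 < len(from_copy2) < 8

    def test_invalid_fraction_rejected(self):
        t1, t2 = self._two_trees()
        with pytest.raises(SimulationError):
            merge_paralogs(t1, t2, 1.5, seed=0)


class TestAlignmentSimulation:
    def test_zero_length_tree_gives_constant_columns(self):
        from vertmark import treeio
        tree = treeio.parse_newick("((a:0,b:0):0,(c:0,d:0):0);", rooted=True)
        cfg = SimulationConfig(alignment_length=50, seed=2)
        aln = simulate_alignment(tree, cfg, lg_model(K=2))
        assert all(len(set(aln.data[:, j])) == 1 for j in range(50))

    def test_two_taxon_identity_fraction_closed_form(self):
        # equal-frequency symmetric chain: E[identical] known in closed form
        from vertmark import treeio
        t = 0.5
        tree = treeio.parse_newick(f"(x:{t/2},y:{t/2});", rooted=True)
        n = 50000
        cfg = SimulationConfig(alignment_length=n, n_gamma_categories=1,
                               gamma_shape=1.0, seed=4)
        aln = simulate_alignment(tree, cfg, equal_rates_model(K=1), seed=17)
        frac = float((aln.data[0] == aln.data[1]).mean())
        expect = 1 / 20 + (19 / 20) * np.exp(-(20 / 19) * t)
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(frac - expect) < 3 * se

    def test_single_profile_equals_homogeneous(self):
        # one-profile mixture must reproduce the homogeneous distribution
        from vertmark import treeio
        from vertmark.model import load_lg, mixture_model
        from scipy import stats
        tree = treeio.parse_newick("(x:0.3,y:0.3);", rooted=True)
        _, pi = load_lg()
        cfg = SimulationConfig(alignment_length=4000, seed=6)
        a1 = simulate_alignment(tree, cfg, lg_model(K=2, alpha=0.5), seed=30)
        a2 = simulate_alignment(tree, cfg,
                                mixture_model([(pi, 1.0)], K=2, alpha=0.5),
                                seed=31)
        from vertmark.alignment import AMINO_ACIDS
        c1 = np.array([(a1.data == aa).sum() for aa in AMINO_ACIDS])
        c2 = np.array([(a2.data == aa).sum() for aa in AMINO_ACIDS])
        _, p = stats.chisquare(c2, c1 / c1.sum() * c2.sum())
        assert p > 0.001

    def test_branch_scale_scales_divergence(self):
        cfg1 = SimulationConfig(n_taxa_A=3, n_taxa_B=3, alignment_length=800,
                                branch_scale=1.0, seed=19)
        cfg3 = SimulationConfig(**{**cfg1.__dict__, "branch_scale": 3.0})
        sp = simulate_species_tree(cfg1)
        m = lg_model(K=2)
        a1 = simulate_alignment(sp, cfg1, m, seed=40)
        a3 = simulate_alignment(sp, cfg3, m, seed=40)
        div1 = (a1.data[0] != a1.data[1]).mean()
        div3 = (a3.data[0] != a3.data[1]).mean()
        assert div3 > div1

    def test_bit_reproducible(self):
        cfg = SimulationConfig(n_taxa_A=3, n_taxa_B=3, alignment_length=100, seed=23)
        m = lg_model(K=2)
        _, _, a1, _ = simulate_family(cfg, m)
        _, _, a2, _ = simulate_family(cfg, m)
        assert np.array_equal(a1.data, a2.data)
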