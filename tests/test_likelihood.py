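import numpy as np
import pytest

from _oracles import brute_force_site_loglik, random_topology
from vertmark.alignment import AMINO_ACIDS, Alignment
from vertmark.likelihood import (LikelihoodEngine, PhyloGraph, as_graph,
                                 estimate_gamma_shape, log_likelihood,
                                 site_rate_posteriors)
from vertmark.model import equal_rates_model, lg_model, mixture_model
from vertmark.search import ml_distance
from vertmark.simulate import SimulationConfig, simulate_alignment
from vertmark import treeio


def random_case(seed, max_leaves=5, max_sites=3, p_missing=0.15):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_leaves + 1))
    labels = [f"t{i}" for i in range(n)]
    if n == 2:
        g = PhyloGraph()
        g.add_edge(g.new_node("t0"), g.new_node("t1"), rng.uniform(0.05, 0.5))
    else:
        g = random_topology(rng, labels)
    L = int(rng.integers(1, max_sites + 1))
    chars = list(AMINO_ACIDS)
    seqs = {}
    for lab in labels:
        seqs[lab] = "".join(
            "-" if rng.random() < p_missing else chars[rng.integers(20)]
            for _ in range(L))
    aln = Alignment(labels, np.array([list(seqs[l]) for l in labels]))
    return g, aln, seqs


class TestPruningOracle:
    @pytest.mark.parametrize("seed", range(30))
    def test_matches_enumeration_lg_gamma(self, seed):
        g, aln, seqs = random_case(seed)
        model = lg_model(alpha=0.6, K=2)
        res = log_likelihood(g, aln, model)
        oracle = brute_force_site_loglik(g, seqs, model)
        assert np.abs(res.site_ll - oracle).max() < 1e-8

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_profile_mixture(self, seed):
        g, aln, seqs = random_case(100 + seed, max_leaves=4)
        rng = np.random.default_rng(7)
        profs = [(rng.dirichlet(np.ones(20)), 0.4), (rng.dirichlet(np.ones(20)), 0.6)]
        model = mixture_model(profs, alpha=0.8, K=2)
        res = log_likelihood(g, aln, model)
        oracle = brute_force_site_loglik(g, seqs, model)
        assert np.abs(res.site_ll - oracle).max() < 1e-8


class TestLikelihoodInvariances:
    def test_total_is_sum_of_site_lls(self, lg_g4, quartet_tree, toy_alignment):
        res = log_likelihood(quartet_tree, toy_alignment, lg_g4)
        assert res.total == pytest.approx(res.site_ll.sum(), abs=1e-8)

    def test_root_placement_irrelevant(self, lg_g4, toy_alignment, quartet_tree):
        g = as_graph(quartet_tree)
        engine = LikelihoodEngine(g, toy_alignment, lg_g4)
        lls = [float(engine.pattern_ll(root) @ engine.pattern_counts)
               for root in g.nodes]
        assert np.ptp(lls) < 1e-8

    def test_duplicated_column_adds_its_site_ll(self, lg_g4, quartet_tree):
        a1 = Alignment(list("abcd"), np.array([["A"], ["C"], ["A"], ["D"]]))
        dup = Alignment(list("abcd"), np.repeat(a1.data, 2, axis=1))
        r1 = log_likelihood(quartet_tree, a1, lg_g4)
        r2 = log_likelihood(quartet_tree, dup, lg_g4)
        assert r2.total == pytest.approx(2 * r1.total, abs=1e-9)

    def test_leaf_order_permutation_invariant(self, lg_g4, quartet_tree, toy_alignment):
        perm = toy_alignment.take_taxa(["d", "b", "a", "c"])
        r1 = log_likelihood(quartet_tree, toy_alignment, lg_g4)
        r2 = log_likelihood(quartet_tree, perm, lg_g4)
        assert r1.total == pytest.approx(r2.total, abs=1e-10)

    def test_missing_leaf_sequence_errors(self, lg_g4, quartet_tree):
        aln = Alignment(list("abc"), np.array([["A"], ["C"], ["A"]]))
        with pytest.raises(Exception, match="d"):
            log_likelihood(quartet_tree, aln, lg_g4)

    def test_posteriors_sum_to_one(self, lg_g4, quartet_tree, toy_alignment):
        res = log_likelihood(quartet_tree, toy_alignment, lg_g4)
        assert np.allclose(res.gamma_posteriors.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(res.mixture_posteriors.sum(axis=1), 1.0, atol=1e-12)


class TestBranchOptimization:
    def test_two_taxon_matches_analytic_inversion(self):
        # equal-rates chain: ML distance inverts the mismatch fraction
        rng = np.random.default_rng(3)
        model = equal_rates_model(K=1)
        tree = treeio.parse_newick("(x:0.25,y:0.25);", rooted=True)
        cfg = SimulationConfig(alignment_length=4000, gamma_shape=1.0,
                               n_gamma_categories=1, seed=0)
        aln = simulate_alignment(tree, cfg, model, seed=11)
        p_hat = float((aln.data[0] != aln.data[1]).mean())
        analytic = -(19 / 20) * np.log(1 - (20 / 19) * p_hat)
        d_ml = ml_distance(aln, aln.taxa[0], aln.taxa[1], model)
        assert d_ml == pytest.approx(analytic, abs=1e-3)

    def test_second_optimization_pass_is_noop(self, lg_g4):
        cfg = SimulationConfig(n_taxa_A=3, n_taxa_B=3, stem_length=0.8,
                               alignment_length=300, seed=2)
        from vertmark.simulate import simulate_species_tree
        sp = simulate_species_tree(cfg)
        aln = simulate_alignment(sp, cfg, lg_g4)
        g = as_graph(sp).copy()
        engine = LikelihoodEngine(g, aln, lg_g4)
        ll1 = engine.optimize_all_edges()
        ll2 = engine.optimize_all_edges(max_rounds=1)
        assert ll2 >= ll1 - 1e-9
        assert ll2 - ll1 < 1e-4

    def test_time_reversibility_subtree_swap(self, lg_g4, toy_alignment):
        # the two orientations of a quartet around its internal edge
        t1 = treeio.parse_newick("((a:0.1,b:0.2):0.15,c:0.3,d:0.25);")
        t2 = treeio.parse_newick("((c:0.3,d:0.25):0.15,a:0.1,b:0.2);")
        r1 = log_likelihood(t1, toy_alignment, lg_g4)
        r2 = log_likelihood(t2, toy_alignment, lg_g4)
        assert r1.total == pytest.approx(r2.total, abs=1e-10)


class TestEstimatorConsistency:
    def test_branch_error_shrinks_with_site_count(self):
        model = lg_model(alpha=0.7, K=4)
        from vertmark.simulate import simulate_species_tree
        errs = {}
        for L in (800, 8000):
            cfg = SimulationConfig(n_taxa_A=3, n_taxa_B=3, stem_length=0.8,
                                   alignment_length=L, gamma_shape=0.7, seed=14)
            sp = simulate_species_tree(cfg)
            aln = simulate_alignment(sp, cfg, model, seed=15)
            g = as_graph(sp).copy()
            engine = LikelihoodEngine(g, aln, model)
            engine.optimize_all_edges()
            gt = as_graph(sp)
            leaves = set(gt.label.values())
            est = {}
            for u, v in g.edges():
                s = g.side_leaves(u, v)
                est[s] = est[frozenset(leaves - s)] = g.adj[u][v]
            rel = [abs(est[gt.side_leaves(u, v)] - gt.adj[u][v]) / gt.adj[u][v]
                   for u, v in gt.edges() if gt.adj[u][v] >= 0.05]
            errs[L] = float(np.mean(rel))
        assert errs[8000] < errs[800]


class TestGammaShape:
    def test_recovery_from_simulated_data(self):
        model = lg_model(alpha=0.5, K=4)
        cfg = SimulationConfig(n_taxa_A=3, n_taxa_B=3, stem_length=0.5,
                               alignment_length=4000, gamma_shape=0.5, seed=8)
        from vertmark.simulate import simulate_species_tree
        sp = simulate_species_tree(cfg)
        aln = simulate_alignment(sp, cfg, model)
        res = estimate_gamma_shape(sp, aln, model)
        assert 0.4 <= res.alpha <= 0.6
        assert not res.at_boundary

    def test_homogeneous_data_hits_upper_bound(self):
        model = lg_model(alpha=1.0, K=4)
        gen = lg_model(alpha=1.0, K=1)   # no rate variation
        cfg = SimulationConfig(n_taxa_A=3, n_taxa_B=3, stem_length=0.5,
                               alignment_length=1500, n_gamma_categories=1,
                               seed=9)
        from vertmark.simulate import simulate_species_tree
        sp = simulate_species_tree(cfg)
        aln = simulate_alignment(sp, cfg, gen)
        res = estimate_gamma_shape(sp, aln, model, bounds=(0.05, 8.0))
        assert res.at_boundary and res.alpha > 7.9


class TestSitePosteriors:
    def test_invariant_column_prefers_slowest_category(self, lg_g4, quartet_tree):
        aln = Alignment(list("abcd"),
                        np.array([["A", "A"], ["A", "C"], ["A", "D"], ["A", "W"]]))
        post = site_rate_posteriors(quartet_tree, aln, lg_g4)
        assert post[0].argmax() == 0          # invariant site -> slowest
        assert post[1].argmax() > 0           # scattered site -> faster
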