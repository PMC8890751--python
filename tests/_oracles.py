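"""Independent oracles used by the test suite.

These deliberately avoid the package's pruning/counting code paths:
likelihoods are computed by explicit enumeration over internal-node
state assignments, and split counts by minimising pure-clade counts
over all rootings.
"""

from __future__ import annotations

import numpy as np

from vertmark.alignment import AA_INDEX
from vertmark.likelihood import PhyloGraph
from vertmark.model import SubstitutionModel, build_rate_matrix, transition_probs


def brute_force_site_loglik(graph: PhyloGraph, seqs: dict[str, str],
                            model: SubstitutionModel) -> np.ndarray:
    """Per-site log-likelihood by summing over all internal-node states.

    Missing characters ('-'/'X') at leaves are marginalised by treating
    the leaf as a free node in the enumeration.
    """
    nodes = sorted(graph.adj)
    leaves = {n for n in nodes if len(graph.adj[n]) == 1}
    n_sites = len(next(iter(seqs.values())))
    rates = model.rates
    K = model.K

    # build rooted edge list from an arbitrary internal node
    root = next(n for n in nodes if n not in leaves) if len(nodes) > 2 else nodes[0]
    edges = []
    seen = {root}
    stack = [root]
    while stack:
        x = stack.pop()
        for y in sorted(graph.adj[x]):
            if y not in seen:
                seen.add(y)
                edges.append((x, y, graph.adj[x][y]))
                stack.append(y)

    out = np.zeros(n_sites)
    for site in range(n_sites):
        total = 0.0
        # a leaf with missing data contributes Σ_j P_ij = 1, so its edge
        # drops out; only internal nodes are enumerated (20^3 at most here)
        fixed = {}
        missing = set()
        for n in leaves:
            ch = seqs[graph.label[n]][site]
            if ch in AA_INDEX:
                fixed[n] = AA_INDEX[ch]
            else:
                missing.add(n)
        site_edges = [(x, y, t) for (x, y, t) in edges if y not in missing]
        free = [n for n in nodes if n not in leaves]
        if root in leaves and root in missing:
            free = free + [root]
        for (pi, w) in model.profiles:
            Q = build_rate_matrix(model.S, pi)
            for k in range(K):
                P = {(x, y): transition_probs(Q, rates[k] * t, pi)
                     for (x, y, t) in site_edges}
                grids = np.meshgrid(*[np.arange(20)] * len(free), indexing="ij") \
                    if free else []
                assign = {n: g.ravel() for n, g in zip(free, grids)}

                def state(n):
                    return assign[n] if n in assign else fixed[n]

                vals = pi[state(root)] * np.ones(
                    len(assign[free[0]]) if free else 1)
                for (x, y, t) in site_edges:
                    vals = vals * P[(x, y)][state(x), state(y)]
                total += w * float(vals.sum()) / K
        out[site] = np.log(total)
    return out


def min_pure_clades_over_rootings(graph: PhyloGraph, cluster: frozenset[str]) -> int:
    """Minimal number of pure clades covering the cluster, over all rootings."""
    best = None
    for (u, v) in graph.edges():
        clades = []

        def collect(x, parent):
            kids = [w for w in graph.adj[x] if w != parent]
            if not kids:
                s = frozenset([graph.label[x]])
            else:
                s = frozenset()
                for k in kids:
                    s = s | collect(k, x)
            clades.append(s)
            return s

        collect(u, v)
        collect(v, u)
        pure = [c for c in clades if c <= cluster]
        maximal = [c for c in pure if not any(c < d for d in pure)]
        covered = set().union(*maximal) if maximal else set()
        if covered == set(cluster):
            n = len(maximal)
            best = n if best is None else min(best, n)
    return best


def random_topology(rng: np.random.Generator, labels: list[str],
                    length_scale: float = 0.3) -> PhyloGraph:
    """Random unrooted binary tree by sequential leaf addition."""
    g = PhyloGraph()
    hub = g.new_node()
    for lab in labels[:3]:
        g.add_edge(g.new_node(lab), hub, rng.uniform(0.05, length_scale))
    for lab in labels[3:]:
        u, v = g.edges()[rng.integers(len(g.edges()))]
        t = g.adj[u][v]
        g.remove_edge(u, v)
        m = g.new_node()
        g.add_edge(u, m, t / 2)
        g.add_edge(m, v, t / 2)
        g.add_edge(m, g.new_node(lab), rng.uniform(0.05, length_scale))
    return g
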