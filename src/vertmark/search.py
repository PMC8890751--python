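"""Tree search: ML pairwise distances, neighbor joining, NNI hill-climbing.

The NNI search is a desk-scale verification tool, not a production
tree-search replacement: greedy hill-climbing over all
nearest-neighbour-interchange neighbourhoods, re-optimising the five
branch lengths local to each candidate move and all branch lengths on
accepted moves.  An optional bipartition constraint (the A|B split)
restricts the search to domain-monophyletic topologies.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from .alignment import Alignment
from .likelihood import (MIN_BRANCH, LikelihoodEngine,
                         LikelihoodError, PhyloGraph, as_graph)
from .model import SubstitutionModel
from . import treeio

ML_DISTANCE_CAP = 10.0


def ml_distance(alignment: Alignment, taxon_a: str, taxon_b: str,
                model: SubstitutionModel) -> float:
    """Two-sequence ML distance under the model, capped at 10 subst/site."""
    sub = alignment.take_taxa([taxon_a, taxon_b])
    g = PhyloGraph()
    u = g.new_node(taxon_a)
    v = g.new_node(taxon_b)
    g.add_edge(u, v, 0.1)
    engine = LikelihoodEngine(g, sub, model)
    f = engine.edge_ll_function(u, v)
    res = minimize_scalar(lambda t: -f(t), bounds=(MIN_BRANCH, ML_DISTANCE_CAP),
                          method="bounded", options={"xatol": 1e-8})
    return float(res.x)


def ml_distance_matrix(alignment: Alignment, model: SubstitutionModel,
                       taxa: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    taxa = list(taxa or alignment.taxa)
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = ml_distance(alignment, taxa[i], taxa[j], model)
    return D, taxa


def _tree_from_distances(D: np.ndarray, taxa: list[str]) -> PhyloGraph:
    """Neighbor joining (scikit-bio) with negative edges clamped to 0."""
    newick = str(skbio_nj(DistanceMatrix(D, ids=taxa)))
    g = PhyloGraph.from_dendropy(treeio.parse_newick(newick))
    for u, v in g.edges():
        if g.adj[u][v] < 0:
            g.set_edge_length(u, v, 0.0)
    return g


def neighbor_joining(alignment: Alignment, model: SubstitutionModel,
                     taxa: list[str] | None = None) -> PhyloGraph:
    """NJ tree on pairwise ML distances."""
    taxa = list(taxa or alignment.taxa)
    if len(taxa) < 4:
        raise LikelihoodError("neighbor joining needs at least 4 taxa")
    D, taxa = ml_distance_matrix(alignment, model, taxa)
    return _tree_from_distances(D, taxa)


def _subtree_from_distances(D: np.ndarray, taxa: list[str],
                            g: PhyloGraph) -> int:
    """Build a subtree for `taxa` inside graph g; return its root node.

    Handles the degenerate 1-, 2- and 3-taxon cases that plain NJ
    cannot.  The returned node is a hub to which the joining stem
    attaches.
    """
    if len(taxa) == 1:
        return g.new_node(taxa[0])
    hub = g.new_node()
    if len(taxa) <= 3:
        for t in taxa:
            g.add_edge(g.new_node(t), hub, 0.05)
        return hub
    sub = _tree_from_distances(D, taxa)
    # graft a copy of `sub` into g, splitting its first edge with the hub
    mapping = {}
    for node in sub.nodes:
        mapping[node] = g.new_node(sub.label.get(node))
    for u, v in sub.edges():
        g.add_edge(mapping[u], mapping[v], sub.adj[u][v])
    u, v = sub.edges()[0]
    t = sub.adj[u][v]
    g.remove_edge(mapping[u], mapping[v])
    g.add_edge(mapping[u], hub, t / 2)
    g.add_edge(hub, mapping[v], t / 2)
    return hub


def constrained_nj(alignment: Alignment, model: SubstitutionModel,
                   split: frozenset[str], stem_length: float = 0.5) -> PhyloGraph:
    """Per-side NJ subtrees joined by a stem, guaranteeing the split."""
    side_a = [t for t in alignment.taxa if t in split]
    side_b = [t for t in alignment.taxa if t not in split]
    if not side_a or not side_b:
        raise LikelihoodError("constraint split leaves one side empty")
    g = PhyloGraph()
    hubs = []
    for side in (side_a, side_b):
        if len(side) >= 4:
            D, _ = ml_distance_matrix(alignment, model, side)
        else:
            D = None
        hubs.append(_subtree_from_distances(D, side, g))
    g.add_edge(hubs[0], hubs[1], stem_length)
    g._suppress_degree_two()
    return g


# ---------------------------------------------------------------------------
# NNI search
# ---------------------------------------------------------------------------

def _internal_edges(g: PhyloGraph) -> list[tuple[int, int]]:
    return [(u, v) for u, v in g.edges()
            if len(g.adj[u]) > 1 and len(g.adj[v]) > 1]


def _apply_nni(g: PhyloGraph, u: int, v: int, b: int, c: int) -> None:
    """Swap subtree b (neighbour of u) with subtree c (neighbour of v)."""
    tb = g.adj[u][b]
    tc = g.adj[v][c]
    g.remove_edge(u, b)
    g.remove_edge(v, c)
    g.add_edge(v, b, tb)
    g.add_edge(u, c, tc)


def nni_search(alignment: Alignment, model: SubstitutionModel,
               start_tree=None, constraint: frozenset[str] | None = None,
               max_iters: int = 200, tol: float = 1e-6):
    """Greedy NNI hill-climbing, optionally constrained to keep a split.

    Returns ``(PhyloGraph, LikelihoodResult)`` at a local optimum.  If
    ``constraint`` is given every accepted topology contains that
    bipartition; a start tree violating it is repaired by constrained
    neighbor joining before the search begins.
    """
    if start_tree is None:
        start_tree = neighbor_joining(alignment, model)
    g = as_graph(start_tree).copy()
    if constraint is not None and not g.has_bipartition(constraint):
        g = constrained_nj(alignment, model, constraint)

    engine = LikelihoodEngine(g, alignment, model)
    # coarse optimisation while climbing; a final polish happens on exit
    climb_tol = max(tol, 1e-3)
    current_ll = engine.optimize_all_edges(tol=climb_tol)

    for _ in range(max_iters):
        best = None  # (ll, u, v, b, c)
        for u, v in _internal_edges(g):
            if constraint is not None:
                side = g.side_leaves(u, v)
                if side == constraint or side == frozenset(g.label.values()) - constraint:
                    continue  # NNI across this edge would destroy the split
            nbr_u = [w for w in sorted(g.adj[u]) if w != v]
            nbr_v = [w for w in sorted(g.adj[v]) if w != u]
            for c in nbr_v:
                cand = g.copy()
                _apply_nni(cand, u, v, nbr_u[0], c)
                ce = LikelihoodEngine(cand, alignment, model)
                local = {(u, v), (u, nbr_u[1]), (u, c),
                         (v, nbr_v[0] if c != nbr_v[0] else nbr_v[1]), (v, nbr_u[0])}
                for (x, y) in local:
                    if y in cand.adj.get(x, {}):
                        ce.optimize_edge(x, y, xatol=1e-4)
                ll = ce.total_ll()
                if ll > current_ll + 1e-9 and (best is None or ll > best[0]):
                    best = (ll, u, v, nbr_u[0], c)
        if best is None:
            break
        _, u, v, b, c = best
        _apply_nni(g, u, v, b, c)
        engine = LikelihoodEngine(g, alignment, model)
        current_ll = engine.optimize_all_edges(tol=climb_tol)

    engine.optimize_all_edges(tol=tol)
    return g, engine.result()


def free_and_constrained_search(alignment: Alignment, model: SubstitutionModel,
                                split: frozenset[str], start_tree=None):
    """Free and domain-constrained ML searches with a consistency guard.

    Greedy NNI searches are local: occasionally the constrained search,
    which starts from a different (constraint-repaired) tree, ends on a
    better topology than the free search.  Since the constrained space
    is a subset of the free space, the free search is then restarted
    from the constrained tree, guaranteeing ll_free >= ll_constrained.

    Returns ``(free_tree, free_result, constrained_tree, constrained_result)``.
    """
    free_tree, free_res = nni_search(alignment, model, start_tree=start_tree)
    cons_tree, cons_res = nni_search(alignment, model, start_tree=free_tree,
                                     constraint=split)
    if cons_res.total > free_res.total + 1e-9:
        tree2, res2 = nni_search(alignment, model, start_tree=cons_tree)
        if res2.total > free_res.total:
            free_tree, free_res = tree2, res2
        if free_res.total < cons_res.total:  # constrained tree is in free space
            free_tree, free_res = cons_tree, cons_res
    return free_tree, free_res, cons_tree, cons_res
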