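"""Felsenstein pruning over profile-mixture models, and branch optimisation.

The engine works on :class:`PhyloGraph`, a minimal unrooted-tree
adjacency structure (integer nodes, labelled leaves, edge lengths).
Alignment columns are compressed to unique site patterns; gaps and
``X`` contribute all-ones partial vectors; every mixture component
(profile m × gamma category k) is propagated together in one stacked
array, with per-pattern log-scaling to avoid underflow.

Per-edge likelihoods use the standard two-directional factorisation
L(t) = Σ_i π_i F_i [P(t) G]_i, where F and G are the conditional
likelihoods of the two half-trees at the edge's endpoints, so a branch
length can be optimised by 1-D search at the cost of a dot product per
evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .alignment import AA_INDEX, Alignment
from .model import N_STATES, SubstitutionModel
from . import treeio

MIN_BRANCH = 1e-8
MAX_BRANCH = 50.0
MISSING_STATE = N_STATES  # sentinel index for '-' / 'X'


class LikelihoodError(ValueError):
    pass


# ---------------------------------------------------------------------------
# tree structure
# ---------------------------------------------------------------------------

class PhyloGraph:
    """Unrooted phylogeny as an undirected tree graph.

    Nodes are integers; leaves carry taxon labels.  This is the working
    representation for likelihood computation and topology moves;
    conversion to/from ``dendropy.Tree`` happens at the API boundary.
    """

    def __init__(self) -> None:
        self.adj: dict[int, dict[int, float]] = {}
        self.label: dict[int, str] = {}
        self._next_id = 0

    # -- construction --------------------------------------------------
    def new_node(self, label: str | None = None) -> int:
        nid = self._next_id
        self._next_id += 1
        self.adj[nid] = {}
        if label is not None:
            self.label[nid] = label
        return nid

    def add_edge(self, u: int, v: int, length: float) -> None:
        if length < 0:
            raise LikelihoodError("negative branch length")
        self.adj[u][v] = float(length)
        self.adj[v][u] = float(length)

    def remove_edge(self, u: int, v: int) -> None:
        del self.adj[u][v]
        del self.adj[v][u]

    def remove_node(self, u: int) -> None:
        for v in list(self.adj[u]):
            self.remove_edge(u, v)
        del self.adj[u]
        self.label.pop(u, None)

    def copy(self) -> "PhyloGraph":
        g = PhyloGraph()
        g.adj = {u: dict(nbrs) for u, nbrs in self.adj.items()}
        g.label = dict(self.label)
        g._next_id = self._next_id
        return g

    # -- queries -------------------------------------------------------
    @property
    def nodes(self) -> list[int]:
        return list(self.adj)

    def leaves(self) -> list[int]:
        return [u for u in self.adj if len(self.adj[u]) == 1]

    def leaf_labels(self) -> list[str]:
        return [self.label[u] for u in sorted(self.leaves())]

    def edges(self) -> list[tuple[int, int]]:
        """Edges as (u, v) with u < v, in sorted order (deterministic)."""
        out = []
        for u in sorted(self.adj):
            for v in self.adj[u]:
                if u < v:
                    out.append((u, v))
        return out

    def edge_length(self, u: int, v: int) -> float:
        return self.adj[u][v]

    def set_edge_length(self, u: int, v: int, t: float) -> None:
        self.adj[u][v] = t
        self.adj[v][u] = t

    def total_length(self) -> float:
        return sum(t for u, v in self.edges() for t in [self.adj[u][v]])

    def scale_edges(self, factor: float) -> None:
        for u, v in self.edges():
            self.set_edge_length(u, v, self.adj[u][v] * factor)

    def side_leaves(self, u: int, v: int) -> frozenset[str]:
        """Labels of leaves on v's side of the edge (u, v)."""
        seen, stack, out = {u, v}, [v], []
        while stack:
            x = stack.pop()
            if len(self.adj[x]) == 1 and x in self.label:
                out.append(self.label[x])
            for y in self.adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return frozenset(out)

    def bipartitions(self) -> dict[tuple[int, int], frozenset[str]]:
        return {(u, v): self.side_leaves(u, v) for u, v in self.edges()}

    def has_bipartition(self, split: frozenset[str]) -> bool:
        all_leaves = frozenset(self.label.values())
        other = all_leaves - split
        for u, v in self.edges():
            side = self.side_leaves(u, v)
            if side == split or side == other:
                return True
        return False

    def find_bipartition_edge(self, split: frozenset[str]) -> tuple[int, int] | None:
        all_leaves = frozenset(self.label.values())
        other = all_leaves - split
        for u, v in self.edges():
            side = self.side_leaves(u, v)
            if side == split or side == other:
                return (u, v)
        return None

    # -- conversion ----------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "PhyloGraph":
        g = cls()
        node_of = {}
        for nd in tree.preorder_node_iter():
            label = nd.taxon.label if (nd.is_leaf() and nd.taxon) else None
            node_of[nd] = g.new_node(label)
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None:
                g.add_edge(node_of[nd.parent_node], node_of[nd],
                           max(nd.edge.length or 0.0, 0.0))
        g._suppress_degree_two()
        return g

    def _suppress_degree_two(self) -> None:
        for u in [n for n in self.nodes if len(self.adj[n]) == 2 and n not in self.label]:
            (a, ta), (b, tb) = self.adj[u].items()
            self.remove_node(u)
            self.add_edge(a, b, ta + tb)

    def to_newick(self, root: int | None = None) -> str:
        if root is None:
            internals = [u for u in sorted(self.adj) if len(self.adj[u]) > 1]
            root = internals[0] if internals else sorted(self.adj)[0]

        def sub(u: int, parent: int | None) -> str:
            kids = [v for v in sorted(self.adj[u]) if v != parent]
            if not kids:
                return self.label.get(u, str(u))
            inner = ",".join(
                f"{sub(v, u)}:{self.adj[u][v]:.10g}" for v in kids
            )
            return f"({inner})"

        return sub(root, None) + ";"

    def to_dendropy(self, rooted: bool = False) -> dendropy.Tree:
        return treeio.parse_newick(self.to_newick(), rooted=rooted)


def as_graph(tree) -> PhyloGraph:
    if isinstance(tree, PhyloGraph):
        return tree
    return PhyloGraph.from_dendropy(tree)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class LikelihoodResult:
    """Total and per-site log-likelihoods plus per-site posteriors."""

    total: float
    site_ll: np.ndarray                 # (n_sites,)
    gamma_posteriors: np.ndarray        # (n_sites, K)
    mixture_posteriors: np.ndarray      # (n_sites, M)


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------

class LikelihoodEngine:
    """Pruning likelihood for one (tree, alignment, model) triple.

    The tree may be modified in place (branch lengths, NNI moves)
    between calls; caches are invalidated explicitly via
    :meth:`invalidate`.
    """

    def __init__(self, graph: PhyloGraph, alignment: Alignment,
                 model: SubstitutionModel) -> None:
        self.graph = graph
        self.model = model
        self.n_sites = alignment.n_sites

        leaf_nodes = graph.leaves()
        for u in leaf_nodes:
            if graph.label.get(u) not in alignment.taxa:
                raise LikelihoodError(
                    f"leaf '{graph.label.get(u)}' has no sequence in the alignment"
                )
        rows = [alignment.taxa.index(graph.label[u]) for u in leaf_nodes]
        coded = np.full((len(rows), alignment.n_sites), MISSING_STATE, dtype=np.int8)
        for r, row in enumerate(rows):
            for aa, idx in AA_INDEX.items():
                coded[r, alignment.data[row] == aa] = idx
        patterns, self.pattern_of_site, counts = np.unique(
            coded.T, axis=0, return_inverse=True, return_counts=True)
        self.pattern_counts = counts.astype(float)
        self.n_patterns = patterns.shape[0]

        MK = model.n_profiles * model.K
        self.MK = MK
        # per-component stationary frequencies and log mixture weights
        self.pis = np.repeat(model.freqs, model.K, axis=0)          # (MK, 20)
        self.logw = np.repeat(np.log(model.weights), model.K) - np.log(model.K)

        # leaf conditionals: (node -> (npat, 21) one-hot with missing=ones)
        eye = np.vstack([np.eye(N_STATES), np.ones(N_STATES)])
        self.leaf_cond = {
            u: eye[patterns[:, r]] for r, u in zip(range(len(rows)), leaf_nodes)
        }
        self._pmat_cache: dict[float, np.ndarray] = {}
        self._msg_cache: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}

    # -- caching -------------------------------------------------------
    def invalidate(self) -> None:
        self._msg_cache.clear()

    def _pmats(self, t: float) -> np.ndarray:
        P = self._pmat_cache.get(t)
        if P is None:
            P = self.model.transition_matrices(t)
            if len(self._pmat_cache) > 4096:
                self._pmat_cache.clear()
            self._pmat_cache[t] = P
        return P

    # -- messages ------------------------------------------------------
    def _message(self, u: int, v: int) -> tuple[np.ndarray, np.ndarray]:
        """Conditional likelihood of data on u's side of edge (u, v).

        Returns (partials (MK, npat, 20), log-scale (MK, npat)),
        conditioned on the state at u.  Iterative post-order evaluation.
        """
        key = (u, v)
        if key in self._msg_cache:
            return self._msg_cache[key]
        stack = [key]
        while stack:
            a, b = stack[-1]
            if (a, b) in self._msg_cache:
                stack.pop()
                continue
            kids = [w for w in sorted(self.graph.adj[a]) if w != b]
            if not kids:  # leaf
                arr = np.broadcast_to(
                    self.leaf_cond[a][None, :, :], (self.MK, self.n_patterns, N_STATES)
                )
                self._msg_cache[(a, b)] = (arr, np.zeros((self.MK, self.n_patterns)))
                stack.pop()
                continue
            missing = [w for w in kids if (w, a) not in self._msg_cache]
            if missing:
                stack.extend((w, a) for w in missing)
                continue
            terms = []
            for w in kids:
                terms.append(self._transmit(self.graph.adj[a][w],
                                            self._msg_cache[(w, a)]))
            self._msg_cache[(a, b)] = self._mul(terms)
            stack.pop()
        return self._msg_cache[key]

    def _transmit(self, t: float, msg) -> tuple[np.ndarray, np.ndarray]:
        """Push a message through an edge: T_i = Σ_j P_ij(t) L_j."""
        arr, scale = msg
        P = self._pmats(t)
        return np.matmul(arr, P.transpose(0, 2, 1)), scale

    @staticmethod
    def _mul(msgs) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise product of messages with rescaling."""
        arr = msgs[0][0].copy()
        scale = msgs[0][1].copy()
        for a2, s2 in msgs[1:]:
            arr *= a2
            scale += s2
        m = arr.max(axis=2)
        safe = np.where(m > 0, m, 1.0)
        arr /= safe[:, :, None]
        scale += np.log(safe)
        return arr, scale

    # -- likelihood ----------------------------------------------------
    def component_site_ll(self, root: int | None = None) -> np.ndarray:
        """Per-component per-pattern log-likelihoods, (MK, npat)."""
        if root is None:
            internals = [u for u in sorted(self.graph.adj) if len(self.graph.adj[u]) > 1]
            root = internals[0] if internals else sorted(self.graph.adj)[0]
        terms = []
        if len(self.graph.adj[root]) == 1 and root in self.leaf_cond:
            arr0 = np.broadcast_to(self.leaf_cond[root][None, :, :],
                                   (self.MK, self.n_patterns, N_STATES))
            terms.append((arr0, np.zeros((self.MK, self.n_patterns))))
        for w in sorted(self.graph.adj[root]):
            terms.append(self._transmit(self.graph.adj[root][w],
                                        self._message(w, root)))
        arr, scale = self._mul(terms)
        lik = np.einsum("ci,cpi->cp", self.pis, arr)
        return np.log(np.maximum(lik, 1e-300)) + scale

    def pattern_ll(self, root: int | None = None) -> np.ndarray:
        comp = self.component_site_ll(root)
        return logsumexp(comp + self.logw[:, None], axis=0)

    def total_ll(self, root: int | None = None) -> float:
        return float(self.pattern_ll(root) @ self.pattern_counts)

    def result(self) -> LikelihoodResult:
        comp = self.component_site_ll()                     # (MK, npat)
        weighted = comp + self.logw[:, None]
        patt_ll = logsumexp(weighted, axis=0)
        M, K = self.model.n_profiles, self.model.K
        bymk = weighted.reshape(M, K, self.n_patterns)
        log_gamma = logsumexp(bymk, axis=0) - patt_ll[None, :]      # (K, npat)
        log_mix = logsumexp(bymk, axis=1) - patt_ll[None, :]        # (M, npat)
        idx = self.pattern_of_site
        return LikelihoodResult(
            total=float(patt_ll @ self.pattern_counts),
            site_ll=patt_ll[idx],
            gamma_posteriors=np.exp(log_gamma).T[idx],
            mixture_posteriors=np.exp(log_mix).T[idx],
        )

    # -- per-edge machinery --------------------------------------------
    def _edge_ll_closure(self, F, Fs, G, Gs):
        scale = Fs + Gs
        piF = self.pis[:, None, :] * F

        def ll(t: float) -> float:
            P = self._pmats(t)
            PG = np.matmul(G, P.transpose(0, 2, 1))     # Σ_j P_ij G_j
            lik = (piF * PG).sum(axis=2)
            comp = np.log(np.maximum(lik, 1e-300)) + scale
            return float(logsumexp(comp + self.logw[:, None], axis=0)
                         @ self.pattern_counts)

        return ll

    def edge_ll_function(self, u: int, v: int):
        """Closure t -> total log-likelihood with edge (u, v) set to t."""
        F, Fs = self._message(u, v)
        G, Gs = self._message(v, u)
        return self._edge_ll_closure(F, Fs, G, Gs)

    def _brent_edge(self, llfun, t0: float, xatol: float) -> float:
        res = minimize_scalar(lambda t: -llfun(t),
                              bounds=(MIN_BRANCH, MAX_BRANCH),
                              method="bounded", options={"xatol": xatol})
        if not np.isfinite(res.fun):
            raise LikelihoodError("non-finite likelihood during branch optimisation")
        t_new = float(res.x)
        return t_new if llfun(t_new) >= llfun(t0) else t0

    def optimize_edge(self, u: int, v: int, xatol: float = 1e-8) -> float:
        llfun = self.edge_ll_function(u, v)
        t_new = self._brent_edge(llfun, self.graph.adj[u][v], xatol)
        self.graph.set_edge_length(u, v, t_new)
        self.invalidate()
        return llfun(t_new)

    def _dfs_optimize(self, x: int, parent: int | None, up, xatol: float):
        """Optimise all edges below x; returns x's updated down-message.

        ``up`` is the product of everything on the parent side of x,
        conditioned at x's end (i.e. L(x, child)-style without the
        child subtrees).  Down-messages in ``_msg_cache`` are fresh for
        any subtree not yet visited this round and are overwritten with
        updated ones as the recursion unwinds, so every edge is
        optimised with exact messages.
        """
        g = self.graph
        kids = [w for w in sorted(g.adj[x]) if w != parent]
        down = {c: self._msg_cache[(c, x)] for c in kids}
        trans = {c: self._transmit(g.adj[x][c], down[c]) for c in kids}
        for c in kids:
            terms = ([up] if up is not None else []) + \
                [trans[s] for s in kids if s != c]
            if not terms:
                continue
            F, Fs = self._mul(terms) if len(terms) > 1 else terms[0]
            G, Gs = down[c]
            llfun = self._edge_ll_closure(F, Fs, G, Gs)
            t_new = self._brent_edge(llfun, g.adj[x][c], xatol)
            g.set_edge_length(x, c, t_new)
            if len(g.adj[c]) > 1:  # internal child: recurse with fresh up
                up_c = self._transmit(t_new, (F, Fs))
                down[c] = self._dfs_optimize(c, x, up_c, xatol)
                self._msg_cache[(c, x)] = down[c]
            trans[c] = self._transmit(t_new, down[c])
        return self._mul([trans[c] for c in kids]) if kids else None

    def optimize_all_edges(self, tol: float = 1e-6, max_rounds: int = 20,
                           xatol: float = 1e-8) -> float:
        """One DFS sweep of exact per-edge Brent optimisations per round."""
        internals = [u for u in sorted(self.graph.adj)
                     if len(self.graph.adj[u]) > 1]
        root = internals[0] if internals else sorted(self.graph.adj)[0]
        last = self.total_ll()
        for _ in range(max_rounds):
            self.invalidate()
            for w in sorted(self.graph.adj[root]):
                self._message(w, root)   # fill fresh down-messages
            up0 = None
            if root in self.leaf_cond:   # 2-leaf tree: root is itself a leaf
                arr0 = np.broadcast_to(
                    self.leaf_cond[root][None, :, :],
                    (self.MK, self.n_patterns, N_STATES))
                up0 = (arr0, np.zeros((self.MK, self.n_patterns)))
            self._dfs_optimize(root, None, up0, xatol)
            self.invalidate()
            cur = self.total_ll()
            if cur - last < tol:
                return cur
            last = cur
        return last


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def log_likelihood(tree, alignment: Alignment,
                   model: SubstitutionModel) -> LikelihoodResult:
    """Pruning log-likelihood with per-site vectors and posteriors."""
    return LikelihoodEngine(as_graph(tree), alignment, model).result()


def site_rate_posteriors(tree, alignment: Alignment,
                         model: SubstitutionModel) -> np.ndarray:
    """(n_sites, K) posterior over gamma categories, mixture marginalised."""
    return log_likelihood(tree, alignment, model).gamma_posteriors


def optimize_branch_lengths(tree, alignment: Alignment, model: SubstitutionModel,
                            tol: float = 1e-6, max_rounds: int = 20):
    """Round-robin Brent optimisation of all branch lengths (fixed topology).

    Returns ``(tree, LikelihoodResult)``; the returned tree matches the
    input type (dendropy in → dendropy out).
    """
    graph = as_graph(tree).copy() if isinstance(tree, PhyloGraph) else as_graph(tree)
    engine = LikelihoodEngine(graph, alignment, model)
    engine.optimize_all_edges(tol=tol, max_rounds=max_rounds)
    res = engine.result()
    if isinstance(tree, PhyloGraph):
        return graph, res
    return graph.to_dendropy(), res


@dataclass
class GammaShapeResult:
    alpha: float
    log_likelihood: float
    at_boundary: bool
    tree: object


def estimate_gamma_shape(tree, alignment: Alignment, model: SubstitutionModel,
                         bounds: tuple[float, float] = (0.05, 20.0),
                         outer_rounds: int = 2) -> GammaShapeResult:
    """Profile-likelihood estimate of the gamma shape parameter.

    Alternates branch-length optimisation with 1-D Brent search on
    alpha (two outer rounds by default).  A boundary optimum is
    flagged, signalling effectively rate-homogeneous data at the upper
    bound.
    """
    graph = as_graph(tree).copy()
    alpha = model.alpha
    best_ll = -np.inf
    for _ in range(outer_rounds):
        engine = LikelihoodEngine(graph, alignment, model.with_alpha(alpha))
        engine.optimize_all_edges()

        def neg(a: float) -> float:
            e = LikelihoodEngine(graph, alignment, model.with_alpha(a))
            return -e.total_ll()

        res = minimize_scalar(neg, bounds=bounds, method="bounded",
                              options={"xatol": 1e-3})
        alpha, best_ll = float(res.x), -float(res.fun)
    at_boundary = min(alpha - bounds[0], bounds[1] - alpha) < 1e-2
    out_tree = graph if isinstance(tree, PhyloGraph) else graph.to_dendropy()
    return GammaShapeResult(alpha, best_ll, at_boundary, out_tree)
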