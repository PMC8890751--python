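"""Tree-shape statistics for marker-gene verticality.

Implements the quantities used to score how vertically a gene family
evolves: reciprocal domain monophyly, the length of the Archaea-
Bacteria (AB) stem and its share of total tree length, split scores
over bootstrap tree sets, the relative AB distance contrasting
between- vs within-domain tip-to-tip distances, minimal-ancestor-
deviation (MAD) rooting and root-to-tip rate proxies.

Split counting uses a root-independent edge-deletion definition:
delete every edge that lies on a path between two leaves outside the
cluster, and count the remaining components that contain cluster
members.  This equals the minimal number of pure clades over all
rootings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment
from .likelihood import PhyloGraph, as_graph
from .model import SubstitutionModel
from .treeio import TaxonMap
from . import search as _search


class MetricError(ValueError):
    pass


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class StemResult:
    gene_id: str
    monophyletic: bool
    ab_branch_length: float
    total_tree_length: float

    @property
    def ab_proportion(self) -> float:
        if self.total_tree_length <= 0:
            return 0.0
        return self.ab_branch_length / self.total_tree_length


@dataclass
class SplitScoreResult:
    gene_id: str
    level: str                            # between_domain | within_domain
    cluster_means: dict[str, float]       # mean split count per cluster
    mean_total_splits: float
    sd_total_splits: float
    n_mapped_taxa: int
    n_bootstrap_trees: int
    skipped_clusters: list[str] = field(default_factory=list)

    @property
    def normalized_score(self) -> float:
        if self.n_mapped_taxa == 0:
            return 0.0
        return self.mean_total_splits / self.n_mapped_taxa


# ---------------------------------------------------------------------------
# monophyly and the AB stem
# ---------------------------------------------------------------------------

def _domain_split(g: PhyloGraph, taxon_map: TaxonMap) -> frozenset[str]:
    leaves = set(g.label.values())
    a = frozenset(t for t in leaves if taxon_map.domain_of(t) == "A")
    b = leaves - a
    if not a or not b:
        raise MetricError("single-domain tree: both domains need leaves")
    return a


def check_reciprocal_monophyly(tree, taxon_map: TaxonMap) -> bool:
    """True iff the unrooted tree has an edge splitting exactly A from B."""
    g = as_graph(tree)
    split = _domain_split(g, taxon_map)
    if len(split) == 1 or len(g.label) - len(split) == 1:
        return True  # a single leaf on one side is trivially a clade
    return g.has_bipartition(split)


def ab_stem_length(tree, taxon_map: TaxonMap, gene_id: str = "") -> StemResult:
    """Length of the unique A|B edge, plus total length and proportion.

    Errors if the domains are not reciprocally monophyletic; in that
    case estimate the stem from a tree constrained to domain monophyly
    (``search.nni_search`` with the A|B constraint) and call this on
    the result.
    """
    g = as_graph(tree)
    split = _domain_split(g, taxon_map)
    edge = g.find_bipartition_edge(split)
    if edge is None:
        raise MetricError(
            "domains are not reciprocally monophyletic; estimate the stem "
            "from a constrained topology search instead"
        )
    u, v = edge
    return StemResult(
        gene_id=gene_id,
        monophyletic=True,
        ab_branch_length=g.adj[u][v],
        total_tree_length=g.total_length(),
    )


# ---------------------------------------------------------------------------
# split scores
# ---------------------------------------------------------------------------

def cluster_blocks(tree, cluster: set[str]) -> int:
    """Number of blocks a leaf cluster is broken into (root-independent).

    Deletes every edge lying on a path between two non-cluster leaves
    and counts connected components containing at least one cluster
    leaf.  A monophyletic cluster gives 1; ``splits = blocks - 1``.
    """
    g = as_graph(tree)
    leaves = set(g.label.values())
    cluster = set(cluster) & leaves
    if not cluster:
        raise MetricError("empty cluster")
    if cluster == leaves:
        return 1
    non_c = leaves - cluster
    # an edge survives iff one of its sides contains no non-cluster leaf
    parent: dict[int, int] = {n: n for n in g.nodes}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in g.edges():
        side = g.side_leaves(u, v)
        if not (side & non_c) or not ((leaves - side) & non_c):
            ru, rv = find(u), find(v)
            parent[ru] = rv
    comps = {find(n) for n in g.nodes
             if n in g.label and g.label[n] in cluster}
    return len(comps)


def _clusters_for_level(taxa, taxon_map: TaxonMap, level: str,
                        ranks: dict[str, str] | None) -> dict[str, set[str]]:
    present = set(taxa)
    if level == "between_domain":
        return {
            dom: {t for t in present if taxon_map.domain_of(t) == dom}
            for dom in ("A", "B")
        }
    if level != "within_domain":
        raise MetricError(f"unknown split-score level '{level}'")
    ranks = ranks or {"A": "class", "B": "phylum"}
    clusters: dict[str, set[str]] = {}
    for t in sorted(present):
        dom = taxon_map.domain_of(t)
        label = taxon_map.cluster_of(t, ranks[dom])
        clusters.setdefault(f"{dom}:{label}", set()).add(t)
    return clusters


def split_score(bootstrap_trees, taxon_map: TaxonMap,
                level: str = "between_domain",
                ranks: dict[str, str] | None = None,
                gene_id: str = "") -> SplitScoreResult:
    """Mean split count over bootstrap trees, per cluster and normalised.

    ``level='between_domain'`` scores the clusters {A, B};
    ``'within_domain'`` scores one cluster per taxonomic label at the
    configured rank (archaeal class and bacterial phylum by default).
    Clusters with fewer than two members contribute 0 and are flagged.
    The normalised score divides mean total splits by the number of
    taxa mapped into scored clusters; it is 0 iff every cluster is
    monophyletic in every tree.
    """
    if not isinstance(bootstrap_trees, (list, tuple)):
        bootstrap_trees = [bootstrap_trees]
    if not bootstrap_trees:
        raise MetricError("need at least one tree")
    graphs = [as_graph(t) for t in bootstrap_trees]
    taxa = sorted(graphs[0].label.values())
    clusters = _clusters_for_level(taxa, taxon_map, level, ranks)
    skipped = sorted(name for name, members in clusters.items()
                     if len(members) < 2)
    scored = {name: members for name, members in clusters.items()
              if len(members) >= 2}
    per_cluster = {name: [] for name in clusters}
    totals = []
    for g in graphs:
        total = 0
        for name in sorted(clusters):
            if name in scored:
                splits = cluster_blocks(g, scored[name]) - 1
            else:
                splits = 0
            per_cluster[name].append(splits)
            total += splits
        totals.append(total)
    totals = np.array(totals, dtype=float)
    n_mapped = sum(len(m) for m in scored.values())
    return SplitScoreResult(
        gene_id=gene_id,
        level=level,
        cluster_means={n: float(np.mean(v)) for n, v in per_cluster.items()},
        mean_total_splits=float(totals.mean()),
        sd_total_splits=float(totals.std(ddof=0)),
        n_mapped_taxa=n_mapped,
        n_bootstrap_trees=len(graphs),
        skipped_clusters=skipped,
    )


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def leaf_distance_matrix(g: PhyloGraph) -> tuple[np.ndarray, list[str]]:
    """Patristic distances between all leaves (BFS from each leaf)."""
    leaves = sorted(g.leaves(), key=lambda n: g.label[n])
    labels = [g.label[n] for n in leaves]
    index = {n: i for i, n in enumerate(leaves)}
    D = np.zeros((len(leaves), len(leaves)))
    for src in leaves:
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, t in g.adj[x].items():
                if y not in dist:
                    dist[y] = dist[x] + t
                    stack.append(y)
        for n, i in index.items():
            D[index[src], i] = dist[n]
    return D, labels


def relative_ab_distance(tree, taxon_map: TaxonMap) -> float:
    """(mean AB − mean within-domain) / mean AB tip-to-tip distance.

    Contrasts the average between-domain patristic distance with the
    average of the two within-domain means; defined whether or not the
    domains are monophyletic.
    """
    g = as_graph(tree)
    D, labels = leaf_distance_matrix(g)
    dom = np.array([taxon_map.domain_of(t) for t in labels])
    a_idx = np.flatnonzero(dom == "A")
    b_idx = np.flatnonzero(dom == "B")
    if len(a_idx) < 2 or len(b_idx) < 2:
        raise MetricError("relative AB distance needs >=2 leaves per domain")
    d_ab = D[np.ix_(a_idx, b_idx)].mean()
    if d_ab <= 0:
        raise MetricError("zero between-domain distance")
    d_aa = D[np.ix_(a_idx, a_idx)][np.triu_indices(len(a_idx), 1)].mean()
    d_bb = D[np.ix_(b_idx, b_idx)][np.triu_indices(len(b_idx), 1)].mean()
    return float((d_ab - 0.5 * (d_aa + d_bb)) / d_ab)


# ---------------------------------------------------------------------------
# MAD rooting and root-to-tip rates
# ---------------------------------------------------------------------------

@dataclass
class RootPosition:
    edge: tuple[int, int]
    offset: float          # distance from the first edge endpoint
    rms_deviation: float


def mad_root(tree):
    """Minimal-ancestor-deviation rooting (Tria et al. 2017).

    For every edge and continuous position on it, the relative
    deviations |2·d(root, b)/d(b, c) − 1| over all straddling leaf
    pairs (b, c) measure departure from a molecular clock; the root is
    placed at the global minimiser of their root-mean-square (closed
    form per edge).  Ties break on the first edge in canonical order.
    Returns ``(rooted dendropy tree, RootPosition)``.
    """
    g = as_graph(tree).copy()
    if g.total_length() <= 0:
        raise MetricError("all edge lengths are zero; MAD rooting undefined")
    leaves = sorted(g.leaves(), key=lambda n: g.label[n])
    # node-to-leaf distances via BFS from each leaf
    dist_to_leaf = {}
    for lf in leaves:
        dist = {lf: 0.0}
        stack = [lf]
        while stack:
            x = stack.pop()
            for y, t in g.adj[x].items():
                if y not in dist:
                    dist[y] = dist[x] + t
                    stack.append(y)
        dist_to_leaf[lf] = dist

    best = None
    for u, v in g.edges():
        d_uv = g.adj[u][v]
        side_v = g.side_leaves(u, v)
        side_u_leaves = [lf for lf in leaves if g.label[lf] not in side_v]
        side_v_leaves = [lf for lf in leaves if g.label[lf] in side_v]
        a_terms, e_terms = [], []
        for b in side_u_leaves:
            d_ub = dist_to_leaf[b][u]
            for c in side_v_leaves:
                d_bc = d_ub + d_uv + dist_to_leaf[c][v]
                if d_bc <= 0:
                    continue
                a_terms.append(2.0 / d_bc)
                e_terms.append(2.0 * d_ub / d_bc - 1.0)
        if not a_terms:
            continue
        a = np.array(a_terms)
        e = np.array(e_terms)
        denom = (a * a).sum()
        x = float(np.clip(-(a * e).sum() / denom, 0.0, d_uv)) if denom > 0 else 0.0
        rms = float(np.sqrt(np.mean((a * x + e) ** 2)))
        if best is None or rms < best.rms_deviation - 1e-12:
            best = RootPosition(edge=(u, v), offset=x, rms_deviation=rms)
    if best is None:
        raise MetricError("no valid root position found")

    u, v = best.edge
    d_uv = g.adj[u][v]
    g.remove_edge(u, v)
    root = g.new_node()
    g.add_edge(u, root, best.offset)
    g.add_edge(root, v, d_uv - best.offset)
    from . import treeio
    rooted = treeio.parse_newick(g.to_newick(root=root), rooted=True)
    return rooted, best


def root_to_tip_stats(rooted_tree) -> tuple[float, float, float]:
    """(mean, min, max) of root-to-leaf path lengths of a rooted tree."""
    dists = [lf.distance_from_root() for lf in rooted_tree.leaf_node_iter()]
    if not dists:
        raise MetricError("tree has no leaves")
    return float(np.mean(dists)), float(min(dists)), float(max(dists))


# ---------------------------------------------------------------------------
# bootstrap tree sets
# ---------------------------------------------------------------------------

def poisson_distance_matrix(alignment: Alignment) -> tuple[np.ndarray, list[str]]:
    """Poisson-corrected 20-state distances (fast bootstrap distances)."""
    taxa = list(alignment.taxa)
    n = len(taxa)
    miss = alignment.gap_matrix()
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(miss[i] | miss[j])
            if ok.sum() == 0:
                d = _search.ML_DISTANCE_CAP
            else:
                p = float((alignment.data[i, ok] != alignment.data[j, ok]).mean())
                arg = 1.0 - (20.0 / 19.0) * p
                d = -(19.0 / 20.0) * np.log(arg) if arg > 1e-6 \
                    else _search.ML_DISTANCE_CAP
            D[i, j] = D[j, i] = min(d, _search.ML_DISTANCE_CAP)
    return D, taxa


def bootstrap_trees(alignment: Alignment, model: SubstitutionModel | None = None,
                    n_replicates: int = 100, method: str = "nj-poisson",
                    seed: int = 0) -> list[PhyloGraph]:
    """Nonparametric bootstrap: resample sites, rebuild a tree per replicate.

    ``method='nj-poisson'`` (default) uses neighbor joining on
    Poisson-corrected distances — the fast choice for split-score
    averaging; ``'nj-ml'`` uses pairwise ML distances under ``model``.
    """
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(n_replicates):
        idx = rng.integers(alignment.n_sites, size=alignment.n_sites)
        boot = Alignment(list(alignment.taxa), alignment.data[:, idx])
        if method == "nj-poisson":
            D, taxa = poisson_distance_matrix(boot)
        elif method == "nj-ml":
            if model is None:
                raise MetricError("nj-ml bootstrap needs a model")
            D, taxa = _search.ml_distance_matrix(boot, model)
        else:
            raise MetricError(f"unknown bootstrap method '{method}'")
        trees.append(_search._tree_from_distances(D, taxa))
    return trees
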