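"""Synthetic gene families with controlled verticality violations.

The generator emulates the statistical structure the verticality
analysis assumes: a two-domain species tree (two ultrametric Yule
subtrees of height ``domain_tree_height`` joined by a stem of length
``stem_length``, leaves prefixed ``A_``/``B_``), gene trees derived
from it by depth-preserving subtree-prune-regraft transfers and
optional hidden-paralogy merging, and alignments evolved under a
reversible amino-acid model with discrete-gamma rates and optional
site-specific frequency profiles.

Every operation draws from one seeded :class:`numpy.random.Generator`
in a documented order, so runs are bit-reproducible and ground-truth
event logs are replayable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .alignment import AMINO_ACIDS, Alignment
from .model import SubstitutionModel


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Knobs for one simulated gene family.

    Defaults give a vertically evolving family on a 10+10-taxon species
    tree with a 2.0 substitutions/site inter-domain stem (the order of
    magnitude recovered for curated marker concatenates), strong rate
    heterogeneity (alpha = 0.5) and no transfers.
    """

    n_taxa_A: int = 10
    n_taxa_B: int = 10
    stem_length: float = 2.0
    domain_tree_height: float = 1.0
    n_transfers: int = 0
    transfer_mode: str = "inter_domain"   # inter_domain | intra_domain | mixed
    paralog_merge: bool = False
    paralog_fraction: float = 0.5
    alignment_length: int = 300
    gamma_shape: float = 0.5
    n_gamma_categories: int = 4
    profile_set: list | None = None
    branch_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa_A < 2 or self.n_taxa_B < 2:
            raise SimulationError("each domain needs at least 2 taxa")
        if self.stem_length < 0 or self.domain_tree_height <= 0:
            raise SimulationError("invalid tree dimensions")
        if self.alignment_length < 1:
            raise SimulationError("alignment_length must be positive")
        if self.gamma_shape <= 0 or self.n_gamma_categories < 1:
            raise SimulationError("invalid gamma settings")
        if self.branch_scale <= 0:
            raise SimulationError("branch_scale must be positive")
        if self.transfer_mode not in ("inter_domain", "intra_domain", "mixed"):
            raise SimulationError(f"unknown transfer_mode '{self.transfer_mode}'")
        if self.profile_set is not None:
            wsum = sum(w for _, w in self.profile_set)
            if abs(wsum - 1.0) > 1e-8:
                raise SimulationError("profile weights must sum to 1")


@dataclass
class EventLog:
    """Ground-truth record of the events applied to a gene family."""

    records: list[dict] = field(default_factory=list)

    def add(self, event: str, donor: str, recipient: str,
            affected_leaves: list[str]) -> None:
        self.records.append({
            "event": event,
            "donor_edge": donor,
            "recipient_edge": recipient,
            "affected_leaves": ",".join(affected_leaves),
        })

    def to_tsv(self, path) -> None:
        import pandas as pd
        cols = ["event", "donor_edge", "recipient_edge", "affected_leaves"]
        pd.DataFrame(self.records, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def _yule_subtree(rng: np.random.Generator, n: int, height: float,
                  prefix: str, tns: dendropy.TaxonNamespace) -> dendropy.Node:
    """Ultrametric pure-birth subtree of n leaves, root-to-tip = height."""
    root = dendropy.Node()
    root.birth = 0.0
    active = [root]
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        idx = rng.integers(len(active))
        parent = active.pop(int(idx))
        parent.split_time = t
        for _ in range(2):
            child = dendropy.Node()
            child.birth = t
            parent.add_child(child)
            active.append(child)
    t_end = t + rng.exponential(1.0 / n)
    # measure time from the root's first split so subtree height is exact
    t0 = root.split_time
    scale = height / (t_end - t0) if t_end > t0 else 1.0
    for i, leaf in enumerate(active, start=1):
        leaf.taxon = tns.require_taxon(label=f"{prefix}{i}")
    # a node exists from its birth (parent's split) to its own split or t_end
    for node in root.preorder_iter():
        end = getattr(node, "split_time", t_end)
        node.edge.length = (end - node.birth) * scale
    root.edge.length = 0.0
    return root


def simulate_species_tree(config: SimulationConfig) -> dendropy.Tree:
    """Two-domain species tree: Yule subtrees joined by the AB stem.

    The returned tree is rooted at the midpoint of the stem (so both
    domain roots sit ``stem_length / 2`` from the root and every leaf
    at depth ``stem_length / 2 + domain_tree_height``); derooting
    yields the canonical unrooted tree with a single central A|B edge
    of length ``stem_length``.
    """
    rng = np.random.default_rng(config.seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root_a = _yule_subtree(rng, config.n_taxa_A, config.domain_tree_height, "A_", tns)
    root_b = _yule_subtree(rng, config.n_taxa_B, config.domain_tree_height, "B_", tns)
    tree.seed_node.add_child(root_a)
    tree.seed_node.add_child(root_b)
    root_a.edge.length = config.stem_length / 2.0
    root_b.edge.length = config.stem_length / 2.0
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# gene tree: depth-preserving SPR transfers
# ---------------------------------------------------------------------------

def _depths(tree: dendropy.Tree) -> None:
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node.depth = 0.0
        else:
            node.depth = node.parent_node.depth + (node.edge.length or 0.0)


def _domain_of_clade(node: dendropy.Node) -> str | None:
    doms = {lf.taxon.label.split("_")[0] for lf in node.leaf_iter()}
    return doms.pop() if len(doms) == 1 else None


def _clade_label(node: dendropy.Node) -> str:
    leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
    return "|".join(leaves)


def _suppress_unifurcation(node: dendropy.Node) -> None:
    """Merge a single-child internal node into its child edge."""
    while node is not None and node.parent_node is not None \
            and len(node.child_nodes()) == 1:
        child = node.child_nodes()[0]
        parent = node.parent_node
        child.edge.length = (child.edge.length or 0.0) + (node.edge.length or 0.0)
        parent.remove_child(node)
        parent.add_child(child)
        node = parent


def simulate_gene_tree(species_tree: dendropy.Tree,
                       config: SimulationConfig) -> tuple[dendropy.Tree, EventLog]:
    """Apply ``n_transfers`` depth-preserving SPR events to the species tree.

    For ``inter_domain`` mode the pruned clade and the regraft edge are
    drawn uniformly from opposite domains; the attachment point is
    uniform along the recipient edge and the transferred clade's stem
    is reset so every leaf keeps its original root-to-tip depth.  The
    seed is taken from ``config.seed`` offset by 1 so the gene tree's
    randomness is distinct from the species tree's.
    """
    rng = np.random.default_rng(config.seed + 1)
    tree = species_tree.clone(depth=1)
    log = EventLog()
    for _ in range(config.n_transfers):
        mode = config.transfer_mode
        if mode == "mixed":
            mode = "inter_domain" if rng.random() < 0.5 else "intra_domain"
        _transfer_once(tree, rng, mode, log)
    return tree, log


def _transfer_once(tree: dendropy.Tree, rng: np.random.Generator,
                   mode: str, log: EventLog) -> None:
    for _attempt in range(100):
        _depths(tree)
        domain_counts = {"A": 0, "B": 0}
        for lf in tree.leaf_node_iter():
            domain_counts[lf.taxon.label.split("_")[0]] += 1
        # candidate donor clades: single-domain proper clades whose removal
        # leaves >= 2 leaves of that domain elsewhere in the tree
        donors = []
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            dom = _domain_of_clade(node)
            if dom is None:
                continue
            n_clade = sum(1 for _ in node.leaf_iter())
            if domain_counts[dom] - n_clade >= 2:
                donors.append((node, dom))
        if not donors:
            raise SimulationError("no feasible donor clade for transfer")
        node, dom = donors[int(rng.integers(len(donors)))]
        want = ({"A": "B", "B": "A"}[dom]) if mode == "inter_domain" else dom
        clade_leaves = {lf.taxon.label for lf in node.leaf_iter()}
        # disjoint leaf sets exclude both ancestors and descendants of the
        # clade; a recipient spanning its whole domain is also excluded,
        # since regrafting above a domain's root leaves monophyly intact
        recipients = []
        for r in tree.preorder_node_iter():
            if r.parent_node is None or r is node:
                continue
            if _domain_of_clade(r) != want:
                continue
            r_leaves = {lf.taxon.label for lf in r.leaf_iter()}
            if r_leaves & clade_leaves:
                continue
            if mode == "inter_domain" and len(r_leaves) >= domain_counts[want]:
                continue
            recipients.append(r)
        if not recipients:
            continue
        rec = recipients[int(rng.integers(len(recipients)))]
        u = rng.random()
        attach_depth = rec.parent_node.depth + u * (rec.edge.length or 0.0)
        if attach_depth > node.depth:
            continue  # cannot preserve depth; resample
        donor_label = _clade_label(node)
        rec_label = _clade_label(rec)
        # prune
        parent = node.parent_node
        parent.remove_child(node)
        _suppress_unifurcation(parent)
        # regraft, splitting the recipient edge at the attachment point
        _depths(tree)
        gp = rec.parent_node
        x = attach_depth - gp.depth
        mid = dendropy.Node()
        gp.remove_child(rec)
        gp.add_child(mid)
        mid.edge.length = x
        mid.add_child(rec)
        rec.edge.length = max((rec.edge.length or 0.0) - x, 0.0)
        mid.add_child(node)
        node.edge.length = node.depth - attach_depth
        log.add("transfer", donor_label, rec_label, sorted(clade_leaves))
        return
    raise SimulationError("transfer resampling exceeded 100 attempts")


# ---------------------------------------------------------------------------
# hidden paralogy
# ---------------------------------------------------------------------------

def merge_paralogs(tree1: dendropy.Tree, tree2: dendropy.Tree,
                   fraction: float, seed: int) -> tuple[dendropy.Tree, EventLog]:
    """Mix two paralogous copies of a family into one apparent family.

    The two gene trees (over the same taxa) are grafted at their roots
    with a connecting edge of twice the tree height — the paralogs
    diverged before the root — and for each taxon one of the two
    copies is retained (copy 2 with probability ``fraction``).  The
    event log records which taxa derive from copy 2.
    """
    if not 0.0 <= fraction <= 1.0:
        raise SimulationError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    taxa1 = sorted(lf.taxon.label for lf in tree1.leaf_node_iter())
    taxa2 = sorted(lf.taxon.label for lf in tree2.leaf_node_iter())
    if taxa1 != taxa2:
        raise SimulationError("paralog trees must cover the same taxa")
    height = max(lf.distance_from_root() for lf in tree1.leaf_node_iter())
    from_copy2 = [t for t in taxa1 if rng.random() < fraction]

    tns = dendropy.TaxonNamespace()
    merged = dendropy.Tree(taxon_namespace=tns)
    for copy_idx, src in ((1, tree1), (2, tree2)):
        sub = src.clone(depth=1)
        for lf in sub.leaf_node_iter():
            lf.taxon = tns.require_taxon(label=f"{lf.taxon.label}.{copy_idx}")
        sub_root = sub.seed_node
        merged.seed_node.add_child(sub_root)
        sub_root.edge.length = height  # 2*height total between copy roots
    merged.is_rooted = True
    keep = [f"{t}.2" if t in from_copy2 else f"{t}.1" for t in taxa1]
    merged.retain_taxa_with_labels(keep)
    for lf in merged.leaf_node_iter():
        lf.taxon.label = lf.taxon.label.rsplit(".", 1)[0]
    log = EventLog()
    log.add("duplication_merge", "copy1", "copy2", sorted(from_copy2))
    return merged, log


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def simulate_alignment(tree, config: SimulationConfig,
                       model: SubstitutionModel,
                       seed: int | None = None) -> Alignment:
    """Evolve a gapless alignment along a rooted tree under the model.

    Each site draws a frequency profile by its mixture weight and a
    gamma rate category uniformly; the root state comes from the
    site's profile and states then evolve edge by edge with transition
    matrices P(rate x length x branch_scale).  Draw order: profiles,
    categories, root states, then edges in preorder.
    """
    if config.alignment_length < 1:
        raise SimulationError("zero-length alignment")
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    L = config.alignment_length
    M, K = model.n_profiles, model.K

    site_profile = rng.choice(M, size=L, p=model.weights)
    site_cat = rng.integers(K, size=L)
    comp = site_profile * K + site_cat          # engine component index

    freqs = model.freqs
    states = np.empty(L, dtype=np.int64)
    for m in range(M):
        mask = site_profile == m
        if mask.any():
            states[mask] = rng.choice(20, size=int(mask.sum()), p=freqs[m])

    if not isinstance(tree, dendropy.Tree):
        raise SimulationError("simulate_alignment expects a rooted dendropy tree")
    node_states = {tree.seed_node: states}
    taxa, rows = [], []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = (node.edge.length or 0.0) * config.branch_scale
        P = model.transition_matrices(t)        # (M*K, 20, 20)
        cum = P.cumsum(axis=2)
        parent_states = node_states[node.parent_node]
        u = rng.random(L)
        child = np.empty(L, dtype=np.int64)
        for c in np.unique(comp):
            mask = comp == c
            rowcum = cum[c][parent_states[mask]]
            child[mask] = (u[mask, None] > rowcum).sum(axis=1)
        np.clip(child, 0, 19, out=child)
        node_states[node] = child
        if node.is_leaf():
            taxa.append(node.taxon.label)
            rows.append(child)
    aa = np.array(list(AMINO_ACIDS))
    data = aa[np.vstack(rows)]
    return Alignment(taxa, data, source_name="simulated")


# ---------------------------------------------------------------------------
# convenience: one full family
# ---------------------------------------------------------------------------

def simulate_family(config: SimulationConfig, model: SubstitutionModel,
                    species_tree: dendropy.Tree | None = None):
    """Species tree → gene tree (+ events) → alignment, in one call."""
    if species_tree is None:
        species_tree = simulate_species_tree(config)
    gene_tree, log = simulate_gene_tree(species_tree, config)
    if config.paralog_merge:
        cfg2 = SimulationConfig(**{**config.__dict__, "seed": config.seed + 7001})
        gene_tree2, _ = simulate_gene_tree(species_tree, cfg2)
        gene_tree, mlog = merge_paralogs(gene_tree, gene_tree2,
                                         config.paralog_fraction,
                                         config.seed + 11)
        log.records.extend(mlog.records)
    alignment = simulate_alignment(gene_tree, config, model)
    return species_tree, gene_tree, alignment, log
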