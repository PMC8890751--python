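"""Newick tree I/O and the taxon → domain/lineage map.

Trees are ``dendropy.Tree`` objects kept in a canonical unrooted form: a
trifurcating "virtual root" node, unique leaf labels, non-negative edge
lengths in expected substitutions/site, optional support strings on
internal nodes.  Multi-tree files (bootstrap distributions) hold one
Newick string per line.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import pandas as pd

DOMAINS = ("A", "B")


class TreeError(ValueError):
    """Raised for malformed trees or taxon maps."""


def _validate(tree: dendropy.Tree) -> dendropy.Tree:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise TreeError("duplicate leaf labels")
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
        elif edge.length < 0:
            raise TreeError(f"negative edge length {edge.length}")
    return tree


def canonical_unrooted(tree: dendropy.Tree) -> dendropy.Tree:
    """Deroot in place to the trifurcating virtual-root convention."""
    tree.is_rooted = False
    if len(tree.seed_node.child_nodes()) == 2 and len(tree.leaf_nodes()) > 2:
        tree.deroot()
    return _validate(tree)


def parse_newick(newick: str, rooted: bool = False) -> dendropy.Tree:
    """Parse a single Newick string (quoted labels, internal supports ok)."""
    tree = dendropy.Tree.get(
        data=newick, schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    if rooted:
        tree.is_rooted = True
        return _validate(tree)
    return canonical_unrooted(tree)


def read_newick(path_or_string):
    """Read Newick tree(s): a ``Tree`` for one, a list for multi-tree files.

    Accepts a path or a raw Newick string.  Files with several
    semicolon-terminated trees (one per line, the bootstrap dialect)
    return a list.
    """
    text = path_or_string
    if not str(path_or_string).lstrip().startswith("("):
        text = Path(path_or_string).read_text(encoding="utf-8")
    chunks = [c.strip() for c in text.split(";") if c.strip()]
    if not chunks:
        raise TreeError("no trees found")
    trees = [parse_newick(c + ";") for c in chunks]
    return trees[0] if len(trees) == 1 else trees


def tree_to_newick(tree: dendropy.Tree) -> str:
    """Newick string: 10 significant digits, supports as internal labels."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".10g",
    ).strip()
    return s


def write_newick(trees, path) -> None:
    """Write one tree or a list of trees (one Newick per line)."""
    if isinstance(trees, dendropy.Tree):
        trees = [trees]
    with open(path, "w", encoding="utf-8") as fh:
        for t in trees:
            fh.write(tree_to_newick(t) + "\n")


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def n_edges(tree: dendropy.Tree) -> int:
    """Count real edges (excludes the zero-length edge above the root)."""
    return sum(1 for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node)


@dataclass
class TaxonMap:
    """taxon id → (domain in {A, B}, cluster labels keyed by rank name)."""

    domains: dict[str, str]
    clusters: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        for t, d in self.domains.items():
            if d not in DOMAINS:
                raise TreeError(f"taxon '{t}' has domain '{d}', expected A or B")

    @property
    def ranks(self) -> list[str]:
        for labels in self.clusters.values():
            return list(labels)
        return []

    def domain_of(self, taxon: str) -> str:
        try:
            return self.domains[taxon]
        except KeyError:
            raise TreeError(f"taxon '{taxon}' missing from taxon map") from None

    def cluster_of(self, taxon: str, rank: str) -> str:
        label = self.clusters.get(taxon, {}).get(rank, "")
        if not label:
            raise TreeError(f"taxon '{taxon}' has no '{rank}' label")
        return label

    def taxa_in_domain(self, domain: str) -> list[str]:
        return [t for t, d in self.domains.items() if d == domain]

    def check_tree(self, tree: dendropy.Tree) -> None:
        for label in leaf_labels(tree):
            self.domain_of(label)


def read_taxon_map(path) -> TaxonMap:
    """Read the TSV taxon map (columns: taxon, domain, then rank columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    cols = list(df.columns)
    if cols[:2] != ["taxon", "domain"]:
        raise TreeError("taxon map must start with columns 'taxon', 'domain'")
    ranks = cols[2:]
    domains, clusters = {}, {}
    for _, row in df.iterrows():
        domains[row["taxon"]] = row["domain"]
        clusters[row["taxon"]] = {r: row[r] for r in ranks}
    return TaxonMap(domains, clusters)


def write_taxon_map(tmap: TaxonMap, path) -> None:
    ranks = tmap.ranks
    rows = [
        {"taxon": t, "domain": d, **{r: tmap.clusters.get(t, {}).get(r, "") for r in ranks}}
        for t, d in tmap.domains.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def domain_map_from_prefixes(taxa, ranks: dict[str, str] | None = None) -> TaxonMap:
    """Build a TaxonMap from ``A_``/``B_`` leaf-name prefixes (simulations)."""
    domains, clusters = {}, {}
    for t in taxa:
        dom = t.split("_", 1)[0]
        if dom not in DOMAINS:
            raise TreeError(f"cannot infer domain from taxon name '{t}'")
        domains[t] = dom
        clusters[t] = dict(ranks.get(t, {})) if isinstance(ranks, dict) else {}
    return TaxonMap(domains, clusters)
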