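"""Marker-family orchestration: scoring, ranking, concatenation experiments.

Ties the per-family machinery together the way a verticality study
uses it: score each gene family (ΔLL against domain monophyly, split
scores over bootstrap trees, AB stem from free and constrained trees,
relative AB distance, MAD root-to-tip rate), rank families, build
supermatrices, and run the incremental-concatenation, fast/slow-site
and ribosomal-vs-non-ribosomal comparisons.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import Alignment, GAP
from .likelihood import LikelihoodEngine, as_graph, optimize_branch_lengths
from .metrics import (SplitScoreResult, StemResult, ab_stem_length,
                      bootstrap_trees, check_reciprocal_monophyly, mad_root,
                      relative_ab_distance, root_to_tip_stats, split_score)
from .model import SubstitutionModel
from .search import (constrained_nj, free_and_constrained_search,
                     neighbor_joining, nni_search)
from .toptests import delta_ll, pearson_correlation, wilcoxon_rank_sum
from .treeio import TaxonMap

STEM_EPSILON = 1e-5   # stems below this are "effectively zero" in reports


class PipelineError(ValueError):
    pass


@dataclass
class MarkerRecord:
    """Per-family bundle of data and verticality scores."""

    gene_id: str
    alignment: Alignment
    functional_class: str = "unknown"      # ribosomal | non_ribosomal | unknown
    gene_tree: object = None               # free-search ML tree
    constrained_tree: object = None        # best domain-monophyletic tree
    bootstrap: list = field(default_factory=list)
    ll_free: float | None = None
    ll_constrained: float | None = None
    delta_ll: float | None = None
    split_between: SplitScoreResult | None = None
    split_within: SplitScoreResult | None = None
    stem_free: StemResult | None = None
    stem_constrained: StemResult | None = None
    relative_ab_distance: float | None = None
    root_to_tip_mean: float | None = None

    def score_value(self, key: str) -> float:
        if key == "delta_ll":
            v = self.delta_ll
        elif key == "split_between":
            v = self.split_between.normalized_score if self.split_between else None
        elif key == "split_within":
            v = self.split_within.normalized_score if self.split_within else None
        else:
            raise PipelineError(f"unknown ranking key '{key}'")
        if v is None:
            raise PipelineError(f"gene '{self.gene_id}' missing score '{key}'")
        return float(v)


@dataclass
class ConcatResult:
    marker_ids: list[str]
    supermatrix: Alignment
    partitions: dict[str, tuple[int, int]]   # gene -> 1-based inclusive cols
    tree: object = None
    ab_branch_length: float | None = None
    total_tree_length: float | None = None
    model_name: str = ""

    @property
    def ab_proportion(self) -> float | None:
        if self.ab_branch_length is None or not self.total_tree_length:
            return None
        return self.ab_branch_length / self.total_tree_length


# ---------------------------------------------------------------------------
# scoring one family
# ---------------------------------------------------------------------------

def domain_split_for(alignment: Alignment, taxon_map: TaxonMap) -> frozenset[str]:
    return frozenset(t for t in alignment.taxa if taxon_map.domain_of(t) == "A")


def score_marker(gene_id: str, alignment: Alignment, model: SubstitutionModel,
                 taxon_map: TaxonMap, n_bootstrap: int = 25,
                 within_ranks: dict[str, str] | None = None,
                 functional_class: str = "unknown",
                 seed: int = 0) -> MarkerRecord:
    """Compute the full verticality score bundle for one gene family.

    Runs the free and constrained topology searches, ΔLL, bootstrap
    split scores, AB stem lengths (from the free tree when the domains
    are monophyletic, always from the constrained tree), relative AB
    distance and the MAD-rooted mean root-to-tip distance.
    """
    rec = MarkerRecord(gene_id=gene_id, alignment=alignment,
                       functional_class=functional_class)
    split = domain_split_for(alignment, taxon_map)

    free_tree, free_res, cons_tree, cons_res = free_and_constrained_search(
        alignment, model, split)
    rec.gene_tree, rec.constrained_tree = free_tree, cons_tree
    rec.ll_free, rec.ll_constrained = free_res.total, cons_res.total
    rec.delta_ll = delta_ll(free_res.total, cons_res.total)

    rec.stem_constrained = ab_stem_length(cons_tree, taxon_map, gene_id)
    if check_reciprocal_monophyly(free_tree, taxon_map):
        rec.stem_free = ab_stem_length(free_tree, taxon_map, gene_id)

    rec.bootstrap = bootstrap_trees(alignment, model,
                                    n_replicates=n_bootstrap, seed=seed)
    rec.split_between = split_score(rec.bootstrap, taxon_map,
                                    level="between_domain", gene_id=gene_id)
    if within_ranks is not None:
        rec.split_within = split_score(rec.bootstrap, taxon_map,
                                       level="within_domain",
                                       ranks=within_ranks, gene_id=gene_id)
    rec.relative_ab_distance = relative_ab_distance(free_tree, taxon_map)
    rooted, _ = mad_root(free_tree)
    rec.root_to_tip_mean = root_to_tip_stats(rooted)[0]
    return rec


# ---------------------------------------------------------------------------
# concatenation
# ---------------------------------------------------------------------------

def build_concatenate(markers, taxon_set: list[str] | None = None) -> ConcatResult:
    """Append per-gene alignments column-wise over the taxon union.

    ``markers`` is a list of MarkerRecords or ``(gene_id, Alignment)``
    pairs; taxa missing a gene are padded with gaps.  A taxon named in
    ``taxon_set`` but present in no marker is dropped with a warning.
    """
    pairs = [(m.gene_id, m.alignment) if isinstance(m, MarkerRecord) else m
             for m in markers]
    if not pairs:
        raise PipelineError("no markers to concatenate")
    seen: list[str] = []
    for _, aln in pairs:
        for t in aln.taxa:
            if t not in seen:
                seen.append(t)
    if taxon_set is not None:
        missing = [t for t in taxon_set if t not in seen]
        if missing:
            warnings.warn(f"taxa present in no marker dropped: {missing}")
        taxa = [t for t in taxon_set if t in seen]
    else:
        taxa = seen
    blocks, partitions = [], {}
    col = 1
    for gid, aln in pairs:
        block = np.full((len(taxa), aln.n_sites), GAP, dtype="<U1")
        for i, t in enumerate(taxa):
            if t in aln.taxa:
                block[i] = aln.data[aln.taxa.index(t)]
        blocks.append(block)
        partitions[gid] = (col, col + aln.n_sites - 1)
        col += aln.n_sites
    supermatrix = Alignment(taxa, np.hstack(blocks), source_name="concatenate")
    return ConcatResult([g for g, _ in pairs], supermatrix, partitions)


def fit_concatenate(concat: ConcatResult, model: SubstitutionModel,
                    taxon_map: TaxonMap, tree=None,
                    constrain_monophyly: bool = True) -> ConcatResult:
    """Estimate the concatenate tree and its AB stem.

    With ``tree`` given, only branch lengths are optimised on that
    fixed topology; otherwise a constrained (or free) NNI search runs
    from a domain-aware NJ start.
    """
    aln = concat.supermatrix
    split = domain_split_for(aln, taxon_map)
    if tree is not None:
        g = as_graph(tree).copy()
        engine = LikelihoodEngine(g, aln, model)
        engine.optimize_all_edges()
        fitted = g
    else:
        constraint = split if constrain_monophyly else None
        start = constrained_nj(aln, model, split) if constrain_monophyly \
            else neighbor_joining(aln, model)
        fitted, _ = nni_search(aln, model, start_tree=start,
                               constraint=constraint)
    stem = ab_stem_length(fitted, taxon_map)
    concat.tree = fitted
    concat.ab_branch_length = stem.ab_branch_length
    concat.total_tree_length = stem.total_tree_length
    concat.model_name = model.name
    return concat


# ---------------------------------------------------------------------------
# ranking and experiments
# ---------------------------------------------------------------------------

def rank_markers(records: list[MarkerRecord], key: str = "delta_ll") -> list[MarkerRecord]:
    """Most-vertical-first ordering (ascending score, ties by gene id)."""
    missing = []
    for r in records:
        try:
            r.score_value(key)
        except PipelineError:
            missing.append(r.gene_id)
    if missing:
        raise PipelineError(f"markers missing '{key}' scores: {missing}")
    return sorted(records, key=lambda r: (r.score_value(key), r.gene_id))


def incremental_concatenation(records: list[MarkerRecord],
                              model: SubstitutionModel, taxon_map: TaxonMap,
                              start: int = 20, step: int = 5, stop: int = 100,
                              fixed_tree=None) -> pd.DataFrame:
    """AB stem length as progressively less vertical markers are added.

    ``records`` must already be ranked (most vertical first).  For each
    prefix size the supermatrix is rebuilt and the constrained tree
    re-estimated (or branch lengths refitted on ``fixed_tree``).
    """
    if len(records) < start:
        warnings.warn(
            f"only {len(records)} markers; truncating incremental experiment")
        start = len(records)
    sizes = [n for n in range(start, stop + 1, step) if n <= len(records)]
    rows = []
    for n in sizes:
        concat = build_concatenate(records[:n])
        concat = fit_concatenate(concat, model, taxon_map, tree=fixed_tree,
                                 constrain_monophyly=True)
        rows.append({
            "n_markers": n,
            "n_sites": concat.supermatrix.n_sites,
            "ab_branch_length": concat.ab_branch_length,
            "total_tree_length": concat.total_tree_length,
            "ab_proportion": concat.ab_proportion,
        })
    return pd.DataFrame(rows)


def rate_partition_experiment(concat: ConcatResult, model: SubstitutionModel,
                              taxon_map: TaxonMap) -> pd.DataFrame:
    """Fixed-topology branch lengths from fastest- vs slowest-site sets.

    Sites are assigned to their maximum-posterior gamma category (ties
    to the slower category); the slow partition is category 1, the
    fast partition category K.  Branch lengths are re-optimised on the
    full-concatenate topology for each partition.
    """
    if concat.tree is None:
        raise PipelineError("fit the full concatenate before partitioning")
    aln = concat.supermatrix
    _, res = optimize_branch_lengths(concat.tree, aln, model)
    assignment = np.argmax(res.gamma_posteriors, axis=1)   # ties -> lower cat
    K = model.K
    occupancy = {k: int((assignment == k).sum()) for k in range(K)}
    rows = []
    for name, cats in (("all", list(range(K))), ("slow", [0]), ("fast", [K - 1])):
        idx = np.flatnonzero(np.isin(assignment, cats))
        if idx.size == 0:
            raise PipelineError(
                f"empty '{name}' partition; category occupancies: {occupancy}")
        sub = aln.take_sites(idx) if name != "all" else aln
        g = as_graph(concat.tree).copy()
        engine = LikelihoodEngine(g, sub, model)
        engine.optimize_all_edges()
        stem = ab_stem_length(g, taxon_map)
        rows.append({
            "partition": name,
            "n_sites": sub.n_sites,
            "ab_branch_length": stem.ab_branch_length,
            "total_tree_length": stem.total_tree_length,
            "ab_proportion": stem.ab_proportion,
        })
    return pd.DataFrame(rows)


def ribo_vs_nonribo(records: list[MarkerRecord], model: SubstitutionModel,
                    taxon_map: TaxonMap, fit_concats: bool = True) -> dict:
    """Compare AB stems between ribosomal and non-ribosomal markers.

    Returns per-class stem distributions, the two-sided Wilcoxon
    rank-sum p (``None`` with a note when a class has <2 members) and,
    optionally, per-class fitted concatenates.
    """
    classes = {"ribosomal": [], "non_ribosomal": []}
    for r in records:
        if r.functional_class in classes:
            classes[r.functional_class].append(r)
    stems = {c: [r.stem_constrained.ab_branch_length for r in rs
                 if r.stem_constrained is not None]
             for c, rs in classes.items()}
    out: dict = {"stems": stems, "notes": []}
    if min(len(v) for v in stems.values()) >= 2:
        stat, p = wilcoxon_rank_sum(stems["ribosomal"], stems["non_ribosomal"])
        out["wilcoxon_statistic"], out["wilcoxon_p"] = stat, p
    else:
        out["wilcoxon_p"] = None
        out["notes"].append("a class has <2 members; Wilcoxon skipped")
    if fit_concats:
        out["concatenates"] = {}
        for c, rs in classes.items():
            if not rs:
                continue
            concat = fit_concatenate(build_concatenate(rs), model, taxon_map)
            out["concatenates"][c] = concat
    return out


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

_SCORE_COLUMNS = ["delta_ll", "split_between", "split_within", "ab_stem",
                  "relative_ab_distance", "root_to_tip_mean"]


def scores_table(records: list[MarkerRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        stem = r.stem_constrained.ab_branch_length if r.stem_constrained else np.nan
        rows.append({
            "gene_id": r.gene_id,
            "functional_class": r.functional_class,
            "n_taxa": r.alignment.n_taxa,
            "n_sites": r.alignment.n_sites,
            "ll_free": r.ll_free,
            "ll_constrained": r.ll_constrained,
            "delta_ll": r.delta_ll,
            "split_between": (r.split_between.normalized_score
                              if r.split_between else np.nan),
            "split_within": (r.split_within.normalized_score
                             if r.split_within else np.nan),
            "ab_stem": stem,
            "ab_stem_effectively_zero": bool(stem < STEM_EPSILON)
            if np.isfinite(stem) else True,
            "relative_ab_distance": r.relative_ab_distance,
            "root_to_tip_mean": r.root_to_tip_mean,
        })
    return pd.DataFrame(rows)


def verticality_report(records: list[MarkerRecord]):
    """Score table plus pairwise Pearson correlations among the scores.

    Returns ``(scores, correlations, correlations_filtered)`` where the
    filtered variant drops markers whose constrained AB stem is below
    1e-5 (effectively-zero stems otherwise dominate the correlations).
    Pairs with a constant column get R = NA.
    """
    scores = scores_table(records)
    def corr_frame(df: pd.DataFrame) -> pd.DataFrame:
        rows = []
        cols = [c for c in _SCORE_COLUMNS if c in df.columns]
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                sub = df[[a, b]].dropna()
                if len(sub) < 3:
                    rows.append({"x": a, "y": b, "R": np.nan, "p": np.nan,
                                 "n": len(sub)})
                    continue
                try:
                    R, p = pearson_correlation(sub[a], sub[b])
                except Exception:
                    R, p = np.nan, np.nan
                rows.append({"x": a, "y": b, "R": R, "p": p, "n": len(sub)})
        return pd.DataFrame(rows)

    corr = corr_frame(scores) if len(scores) >= 3 else pd.DataFrame()
    filtered = scores[scores["ab_stem"] >= STEM_EPSILON]
    corr_f = corr_frame(filtered) if len(filtered) >= 3 else pd.DataFrame()
    return scores, corr, corr_f


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: dict, out_dir) -> dict:
    """Simulate a marker bank, score it and emit all reports.

    ``config`` keys (with defaults) are documented in the bundled demo
    configuration; the manifest records the config hash and seed so a
    rerun reproduces every numeric bit-for-bit.
    """
    from . import simulate as sim
    from .model import lg_model
    from .treeio import domain_map_from_prefixes, write_newick

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 1))
    n_per_dom = int(config.get("taxa_per_domain", 6))
    stem = float(config.get("stem_length", 2.0))
    aln_len = int(config.get("alignment_length", 200))
    alpha = float(config.get("gamma_shape", 0.5))
    n_boot = int(config.get("bootstrap_replicates", 20))
    groups = config.get("marker_groups",
                        [{"n": 6, "n_transfers": 0, "class": "ribosomal"},
                         {"n": 6, "n_transfers": 3, "class": "non_ribosomal"}])

    trim_mode = config.get("trim", "none")   # none | gap | entropy
    model = lg_model(alpha=alpha, K=int(config.get("gamma_categories", 4)))
    base_cfg = sim.SimulationConfig(
        n_taxa_A=n_per_dom, n_taxa_B=n_per_dom, stem_length=stem,
        domain_tree_height=float(config.get("domain_tree_height", 1.0)),
        alignment_length=aln_len, gamma_shape=alpha, seed=seed)
    species_tree = sim.simulate_species_tree(base_cfg)
    taxon_map = domain_map_from_prefixes(
        [lf.taxon.label for lf in species_tree.leaf_node_iter()])

    records = []
    gene_idx = 0
    for grp in groups:
        for _ in range(int(grp["n"])):
            gene_idx += 1
            fam_cfg = sim.SimulationConfig(
                **{**base_cfg.__dict__,
                   "n_transfers": int(grp.get("n_transfers", 0)),
                   "paralog_merge": bool(grp.get("paralog_merge", False)),
                   "seed": seed + 1000 * gene_idx})
            _, gene_tree, aln, _ = sim.simulate_family(fam_cfg, model,
                                                       species_tree=species_tree)
            if trim_mode == "gap":
                from .alignment import drop_gappy_sequences, trim_gap_sites
                aln = drop_gappy_sequences(trim_gap_sites(aln))
            elif trim_mode == "entropy":
                from .alignment import trim_entropy
                aln = trim_entropy(aln)
            rec = score_marker(f"g{gene_idx:03d}", aln, model, taxon_map,
                               n_bootstrap=n_boot,
                               functional_class=grp.get("class", "unknown"),
                               seed=seed + 2000 * gene_idx)
            records.append(rec)

    scores, corr, corr_f = verticality_report(records)
    scores.to_csv(out / "marker_scores.tsv", sep="\t", index=False)
    corr.to_csv(out / "score_correlations.tsv", sep="\t", index=False)
    corr_f.to_csv(out / "score_correlations_filtered.tsv", sep="\t", index=False)

    ranked = rank_markers(records, key="delta_ll")
    n_start = min(4, len(ranked))
    inc = incremental_concatenation(ranked, model, taxon_map,
                                    start=n_start, step=max(len(ranked) // 4, 1),
                                    stop=len(ranked))
    inc.to_csv(out / "incremental_concatenation.tsv", sep="\t", index=False)

    concat = fit_concatenate(build_concatenate(ranked[:n_start]), model, taxon_map)
    rates = rate_partition_experiment(concat, model, taxon_map)
    rates.to_csv(out / "rate_partitions.tsv", sep="\t", index=False)

    rvn = ribo_vs_nonribo(records, model, taxon_map, fit_concats=False)

    write_newick([as_graph(r.gene_tree).to_dendropy() for r in records],
                 out / "gene_trees.nwk")
    manifest = {
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()).hexdigest(),
        "config": config,
        "n_markers": len(records),
        "model": model.name,
        "wilcoxon_p_ribo_vs_nonribo": rvn.get("wilcoxon_p"),
        "outputs": ["marker_scores.tsv", "score_correlations.tsv",
                    "score_correlations_filtered.tsv",
                    "incremental_concatenation.tsv", "rate_partitions.tsv",
                    "gene_trees.nwk"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"records": records, "scores": scores, "correlations": corr,
            "incremental": inc, "rate_partitions": rates, "manifest": manifest}
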