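# vertmark

Marker-gene verticality scoring and estimation of the Archaea–Bacteria
(AB) stem length.

Concatenation phylogenomics dates and measures the deepest split in the
tree of life through the length of the **AB stem** — the internal branch
separating all archaeal from all bacterial lineages, in expected
substitutions per site.  That estimate is only as good as the marker
genes behind it: families affected by inter-domain gene transfer, hidden
paralogy or substitutional saturation drag the inferred stem toward
zero.  `vertmark` is a toolkit for researchers who want to quantify
those effects: it scores how vertically each gene family evolves,
estimates the AB stem under site-homogeneous and profile-mixture
substitution models, and ships a synthetic-data generator that lets each
biasing mechanism be switched on in isolation and its effect measured.

## What it computes

For a gene family with alignment `X` and taxon→domain map:

- **ΔLL** = `ln L(T̂_free | X) − ln L(T̂_constrained | X)`, the
  log-likelihood cost of forcing reciprocal domain monophyly (free and
  constrained NNI searches under LG+Γ₄ or LG+C*n*+Γ₄ profile-mixture
  models, Felsenstein pruning over compressed site patterns);
- **split scores**: mean over bootstrap trees of the number of extra
  blocks that predefined taxon clusters (the two domains, or
  within-domain groups at a chosen rank) are broken into — 0 for
  perfect monophyly, normalised by taxon count;
- **AB stem length** and its proportion of total tree length, from the
  free tree when monophyletic and always from the constrained tree;
- **relative AB distance** `(d̄_AB − (d̄_AA + d̄_BB)/2)/d̄_AB` over
  patristic distances, and MAD-rooted mean root-to-tip distance as a
  rate proxy;
- **AU tests** of domain monophyly via multiscale RELL bootstrap, with
  Bonferroni correction across families;
- pipeline experiments: incremental concatenation along a verticality
  ranking, fixed-topology branch lengths from fastest- vs
  slowest-evolving site categories, and ribosomal vs non-ribosomal
  marker comparisons (Wilcoxon rank-sum).

The model layer implements reversible amino-acid substitution models —
LG exchangeabilities (bundled), optional empirical or per-class
frequency profiles with fixed weights, discrete-gamma rates — with
branch-length optimisation, gamma-shape estimation, per-site rate
posteriors and BIC model comparison.  See `docs/methods.md` for the
full model description and the design choices.

## Worked example

Simulate two gene families on the same 10-taxon two-domain species tree
(true stem 2.0 substitutions/site) — one vertical, one hit by four
inter-domain transfers — and score both:

```python
from vertmark import (SimulationConfig, lg_model, simulate_family,
                      ab_stem_length, split_score, bootstrap_trees, delta_ll)
from vertmark.search import free_and_constrained_search
from vertmark.treeio import domain_map_from_prefixes

model = lg_model(alpha=0.5, K=4)
for name, n_transfers in (("vertical", 0), ("transfer-laden", 4)):
    cfg = SimulationConfig(n_taxa_A=5, n_taxa_B=5, stem_length=2.0,
                           alignment_length=300, n_transfers=n_transfers,
                           seed=7)
    _, gene_tree, alignment, events = simulate_family(cfg, model)
    tmap = domain_map_from_prefixes(alignment.taxa)
    split = frozenset(t for t in alignment.taxa if t.startswith("A"))
    _, free, ctree, cons = free_and_constrained_search(alignment, model, split)
    stem = ab_stem_length(ctree, tmap)
    score = split_score(bootstrap_trees(alignment, n_replicates=20, seed=7), tmap)
    print(f"{name}: transfers={len(events.records)} "
          f"dLL={delta_ll(free.total, cons.total):.2f} "
          f"AB_stem={stem.ab_branch_length:.3f} "
          f"ab_proportion={stem.ab_proportion:.3f} "
          f"split_score={score.normalized_score:.3f}")
```

Output:

```
vertical: transfers=0 dLL=0.00 AB_stem=1.694 ab_proportion=0.248 split_score=0.000
transfer-laden: transfers=4 dLL=394.70 AB_stem=0.000 ab_proportion=0.000 split_score=0.565
```

The vertical family accepts domain monophyly at no likelihood cost
(ΔLL = 0), recovers a stem near the simulated 2.0 (1.69 from 300
sites), and never splits a domain across 20 bootstrap trees.  Four
transfers make the constrained topology cost ~395 log-likelihood units,
collapse the constrained stem estimate to zero and break the domains
into multiple blocks in most bootstrap trees — the mechanism by which
unvetted markers shrink the inter-domain branch in concatenations.

## Command line

```sh
vertmark simulate --config sim.yaml --out fam/      # one family + ground truth
vertmark loglik ALN.fasta TREE.nwk --model lg+g4+f  # site lls, alpha, BIC
vertmark splitscore TREES.nwk MAP.tsv --level within --ranks A=class,B=phylum
vertmark autest SITE_LL.tsv --reps 1000 --seed 7
vertmark stem TREE.nwk MAP.tsv
vertmark run --config pipeline.yaml --out results/  # full scoring pipeline
```

Scoring, ranking, concatenation and the rate-partition experiment are
library functions (`vertmark.pipeline`) orchestrated by `vertmark run`;
its manifest records seed and config hash so reruns reproduce every
number bit-for-bit.

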