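# Methods

`vertmark` implements a desk-scale version of a marker-gene verticality
analysis for the deep split between Archaea (A) and Bacteria (B).  The
central quantity is the **AB stem**: the length, in expected
substitutions per site, of the single internal edge separating all
archaeal from all bacterial leaves in a domain-monophyletic unrooted
gene or concatenate tree.  The package quantifies how vertically each
gene family evolves, estimates the AB stem under site-homogeneous and
profile-mixture models, and demonstrates on simulated families how
three factors — inter-domain gene transfer, hidden paralogy and
substitutional saturation — bias the inferred stem downward.

## Model

Sequence evolution is modelled as a reversible continuous-time Markov
chain on the 20 amino acids.  A model couples

- a symmetric exchangeability matrix `S` (the bundled file
  `data/lg.dat` carries the published LG values of Le & Gascuel 2008);
- one or more stationary frequency profiles `π_m` with fixed weights
  `w_m` (one profile gives an LG+G4(+F)-style site-homogeneous model;
  several give a C-series-style profile mixture sharing `S`);
- discrete-gamma rate variation: K equiprobable categories (default
  K = 4) with mean-of-bin rates for shape α, renormalised to mean 1.

Each profile's generator `Q_m` (`q_ij = s_ij π_j`) is normalised to one
expected substitution per unit branch length, and detailed balance
`π_i q_ij = π_j q_ji` holds by construction.  The per-site likelihood
marginalises over profiles and rate categories,

    L(site) = Σ_m w_m (1/K) Σ_k L_{m,k}(site),

computed by Felsenstein pruning over de-duplicated site patterns with
per-pattern log-scaling.  Gap (`-`) and ambiguity (`X`) characters are
missing data (all-ones partial vectors); they differ only in
gap-fraction bookkeeping, where only `-` counts as a gap.

Mixture class weights are fixed when the profile set is loaded and are
not re-optimised per dataset, mirroring how C-series models are used
in practice; an EM reweighting step is deliberately out of scope.

### Optimisation

Branch lengths are optimised one edge at a time by bounded Brent
search on [1e-8, 50] (tolerance 1e-8, configurable), using the
directional-message factorisation `L(t) = Σ_i π_i F_i [P(t) G]_i` so
each likelihood evaluation during the 1-D search costs a single
20×20 contraction per pattern.  Rounds sweep the tree depth-first,
updating messages incrementally so every edge is optimised with exact
partials; sweeps repeat until the total log-likelihood improves by
less than `tol` (default 1e-6).  The gamma shape α is profiled by
Brent search alternated with branch-length optimisation (two outer
rounds) — simpler than joint optimisation and adequate at the scales
the package targets.

Topology estimation is a deliberately lightweight verification tool,
not a production search: neighbor joining (scikit-bio) on pairwise ML
distances provides the start tree, followed by greedy hill-climbing
over all NNI neighbourhoods, re-optimising the five local branch
lengths per candidate move and all branch lengths on accepted moves.
A constrained search restricts moves to topologies containing the A|B
bipartition (a start tree violating it is repaired by per-domain NJ
subtrees joined by a stem).  Because greedy NNI is local, the
constrained search occasionally ends on a better tree than the free
search; `free_and_constrained_search` then restarts the free search
from the constrained tree, guaranteeing ΔLL = ll_free − ll_constrained ≥ 0.

## Verticality scores

- **ΔLL** — log-likelihood difference between the free ML tree and the
  best tree constrained to domain monophyly; larger means the family
  conflicts more strongly with vertical inheritance.
- **Split score** — for a set of predefined taxon clusters (the two
  domains, or within-domain groups at a configured rank), each
  bootstrap tree contributes `Σ_clusters (blocks − 1)` where `blocks`
  is the number of connected components containing cluster members
  after deleting every edge that lies on a path between two
  non-cluster leaves.  This edge-deletion count is root-independent
  and equals the minimal number of pure clades over all rootings
  (property-tested against that oracle).  Scores are averaged over
  bootstrap trees and normalised by the number of taxa mapped into
  scored clusters.  The original split-score script's exact rooting
  behaviour is not reproduced bit-for-bit; the root-free definition is
  the package's fixed, testable choice.
- **Relative AB distance** — `(d̄_AB − (d̄_AA + d̄_BB)/2) / d̄_AB` over
  mean patristic tip-to-tip distances; defined for non-monophyletic
  trees too.  The exact formula used by the original study is not
  printed anywhere we could consult, so this normalised difference is
  the package's documented choice.
- **Root-to-tip rate proxy** — mean root-to-leaf path length after
  minimal-ancestor-deviation (MAD) rooting.  MAD places the root at
  the position minimising the RMS of relative deviations
  `|2 d(ρ,b)/d(b,c) − 1|` over leaf pairs straddling the candidate
  position; the per-edge minimiser is closed-form and ties break on
  the first edge in canonical traversal order.

Bootstrap tree sets use standard nonparametric site resampling with a
tree rebuilt per replicate (default: neighbor joining on
Poisson-corrected distances; NJ on ML distances is available), a
desk-scale stand-in for ultrafast bootstrapping.

## Statistical tests

RELL bootstrap resamples per-site log-likelihood vectors (scale r
resamples `round(r·n)` sites), awarding each replicate to the
highest-scoring topology with exact ties split fractionally.  The AU
test follows the multiscale-bootstrap construction: bootstrap
proportions at scales {0.5, …, 1.4} are transformed through
`z_r = Φ⁻¹(1 − BP_r)`, a weighted least-squares fit of
`z = d√r + c/√r` (binomial-variance weights; clamped proportions keep
inflated variance rather than being dropped) yields
`p_AU = 1 − Φ(d − c)`; BP identically 0 or 1 short-circuits to p = 0
or 1.  Default 1,000 replicates per scale trade precision for speed
and are configurable upward.  Bonferroni correction, the two-sided
Wilcoxon rank-sum test (exact for small tie-free samples, otherwise
normal approximation with midranks, tie-corrected variance and
continuity correction) and Pearson correlation round out the
reporting layer; Bonferroni is the only multiplicity correction,
matching the analysis the package reproduces.

## Alignment filtering

Two protocol rules are implemented exactly: sites with **>90%** gaps
removed, then sequences with **>66%** gaps removed (both strictly
greater-than; 1-based column provenance is tracked through trimming).
The entropy trimmer stands in for BMGE: per column, the excess of the
BLOSUM62-smoothed mixture entropy over the mean per-residue row
entropy, rescaled to [0, 1] so an invariant column scores 0 and a
uniform column 1; columns pass with entropy ≤ 0.5 and gap fraction
≤ 0.2.  BMGE's sliding-window block smoothing is intentionally
omitted and outputs are labelled "simplified"; the pipeline exposes
both filtering routes and leaves the choice to configuration.

## Synthetic data

The generator produces the study's assumed structure, not a fitted
replica of any empirical dataset:

- **Species tree** — two pure-birth (Yule) subtrees, each rescaled to
  an exact ultrametric height (default 1.0), joined by a stem whose
  default length 2.0 substitutions/site matches the order of magnitude
  estimated from curated marker concatenates.  Default 10+10 taxa
  emulate balanced domain sampling in proportion only; clade structure
  is not matched.  Experiments below use 4–5 taxa per domain so a full
  grid of tree searches stays within desk-scale run times; these sizes
  are stated with each experiment.
- **Transfers** — subtree-prune-regraft events whose regraft preserves
  every leaf's root-to-tip depth (the transferred clade's stem is
  shortened to compensate), isolating the topological effect of HGT
  from rate effects.  Inter-domain mode draws donor and recipient from
  opposite domains; infeasible draws are resampled with a hard cap of
  100 attempts.
- **Hidden paralogy** — two independent gene trees are grafted at
  their roots with a connector of twice the tree height (paralogs
  pre-dating the root) and one copy is retained per taxon (copy 2
  with probability `fraction`); the event log records the origins.
- **Alignments** — gapless; per site a profile is drawn by weight and
  a gamma category uniformly, the root state from the site's profile,
  and states evolve with `P(rate × length × branch_scale)`.
  `branch_scale` (default 1) is the saturation knob: it scales all
  edges at simulation time only.  Default α = 0.5 gives strong rate
  heterogeneity so fast/slow-site partitions are informative.

All generators draw from one `numpy` Generator seeded from the config
(sub-streams at documented offsets), so families, event logs and
alignments are bit-reproducible.  What the generator does **not**
emulate: indels and alignment error (gaps enter only via masking),
lineage-specific rate shifts, within-domain compositional trends,
extinction, and gene duplication-loss dynamics.  Passing tests
therefore show that the estimators respond to transfer, paralogy and
saturation as predicted when those are the only violations present —
not that real alignments are free of other confounders.

## Experiments the pipeline automates

- **Incremental concatenation** — markers ranked by ΔLL (ascending,
  ties lexicographic); prefixes of increasing size are concatenated
  (unpartitioned, one model across genes), the constrained tree
  re-estimated per prefix by default (a fixed topology is available
  for speed), and the AB stem recorded.
- **Rate partitions** — sites are assigned to their maximum-posterior
  gamma category (ties to the slower category); branch lengths are
  refitted on the fixed full-concatenate topology for the slowest- and
  fastest-category site sets, and stems compared.
- **Functional classes** — AB stem distributions of ribosomal vs
  non-ribosomal markers (labels from configuration, never from
  database lookups) compared by Wilcoxon rank-sum, plus per-class
  concatenate fits.
- **Score report** — the full per-marker table plus pairwise Pearson
  correlations among ΔLL, split scores, AB stem, relative AB distance
  and root-to-tip mean, with a filtered variant excluding stems below
  1e-5 (flagged "effectively zero" in reports).

## Numerical choices and degenerate inputs

Branch lengths live in [1e-8, 50]; ML pairwise distances are capped at
10.  Transition matrices come from the symmetric eigendecomposition of
the π-similarity-transformed generator, clamped to [0, 1].  Likelihood
results expand pattern-compressed vectors back to original columns, so
per-site outputs align with the input alignment.  Site-likelihood
floors at 1e-300 guard log-of-zero on pathological inputs.  Degenerate
cases raise informative errors rather than returning silently: empty
alignments after trimming, fewer than 4 sequences, single-domain
trees, non-monophyletic trees passed to `ab_stem_length` (the message
points to constrained estimation), all-zero-length trees passed to
MAD rooting, and constrained searches whose split would leave a domain
empty.

## Known limitations

NNI hill-climbing finds local optima; it is adequate for the ≤ 12-taxon
verification experiments shipped here but is no substitute for a
production ML search at hundreds of taxa.  The AU implementation uses
its own scale grid and replicate defaults; equivalence with any
external tool's output is not claimed.  Free-rate models, invariant-
sites categories, codon/nucleotide alphabets and Bayesian dating are
out of scope.  Branch-length recovery at a few thousand sites carries
4–6% per-edge sampling error under LG+G4 — experiments that compare
stems therefore use replicated simulations and sign tests rather than
single-run point estimates.
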