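# Methods

## Model

The package treats a gene network as an unweighted, undirected simple graph
`G = (V, E)` over upper-cased gene symbols.  With adjacency `A` (binary,
symmetric, zero diagonal) and degree matrix `D`, the combinatorial Laplacian
is `L = D − A`.  Information flow is modelled as a continuous-time lazy
random walk whose transition operator after "time" α is the heat kernel

    W = exp(−α L),   α ≥ 0.

Because `L` is symmetric positive semidefinite with `L·1 = 0`, `W` is
symmetric, entrywise in [0, 1] and doubly stochastic — each row/column sums
to one.  Seeding the network with a relevance vector `S` (log2 fold change
on filtered signature genes, 0 elsewhere) gives per-gene diffusion scores
`P = W·S`; `ΣP = ΣS` exactly, so propagation redistributes signature mass
rather than creating or destroying it.  A gene's score mixes its own seed
value with contributions from network neighbours at all distances, weighted
by diffusion proximity — which is what lets withheld (dropout) genes with
many seeded neighbours outrank seeded but poorly connected noise genes.

## Numerical choices

* **Kernel computation.** `W` is computed per connected component by
  symmetric eigendecomposition, `W_c = Q exp(−αΛ) Qᵀ`.  This exploits
  symmetry, keeps cross-component entries *exactly* zero (no numerical
  leakage between components), and leaves a genuinely independent oracle —
  scaling-and-squaring `expm` — available for cross-checking in the tests.
  α = 0 short-circuits to the exact identity.  Entries within 1e−10 below
  zero are clipped to 0; larger negatives would indicate a defect and are
  deliberately not masked.  Dense eigendecomposition targets networks up to
  a few thousand nodes; larger networks would need a chunked or Krylov
  treatment, which is out of scope here.
* **Ranking.** Ranks are descending in `P` with ties broken
  lexicographically by gene symbol, so output ordering is deterministic.
  Input-signature genes stay eligible for the top-N (they visibly persist
  at the top of real propagation results); a flag marks them in all outputs.
* **Scaling.** "Scaled" diffusion scores are z-scores (population SD) by
  default; min–max scaling is available behind a flag.  Both are affine
  monotone and cannot change ranks.  Constant score vectors scale to all
  zeros with a warning.
* **Thresholds.** Edge filters read "superior to" as strict inequality:
  combined score > 300 (with a positive experimental-evidence channel
  required by default) for STRING-like tables, confidence > 0.25 for
  RNAinter-like tables.  The signature filter is log2FC strictly > 0 and
  adjusted p strictly < 0.05.  The enrichment count filter "count > 2" is
  k ≥ 3.
* **Identifiers.** Symbols are upper-cased, whitespace-trimmed, matched
  exactly; no alias resolution (that would import a database dependency).
  RNA–protein links are ordinary gene–gene edges, all annotated at gene
  level.  All graph components are kept (no largest-component restriction);
  component sizes are reported in the manifest.

## Marker-test stand-in

Hurdle-model single-cell DE (MAST) is out of scope; the built-in marker test
is a per-gene two-sided Mann-Whitney rank-sum test (asymptotic, tie-
corrected) on counts-per-10k-normalised values, with
log2FC = log2((mean₁+1)/(mean₂+1)) on normalised group means (explicit
pseudocount 1, stable at zero) and Bonferroni adjustment (p·n_genes capped
at 1).  Constant genes get p = 1 and log2FC = 0.  Under the null generator
the empirical type-I error sits at the nominal 5% (measured at ≈0.050 over
4,000 tests by the acceptance script).

## Enrichment

Over-representation uses the one-sided Fisher exact test: p = P(X ≥ k) for
the hypergeometric overlap of a size-n query with a size-K pathway in a
size-N universe (default universe: all network genes, since diffusion scores
are defined there; configurable).  Gene ratio is k/K — the
"overlap over pathway size" convention — with k/n available behind a flag.
Odds ratios are the cross-product ratio of the 2×2 table with the
Haldane–Anscombe 0.5 correction when any cell is zero.  Multiple testing is
Benjamini–Hochberg by default (the behaviour class of common enrichment
services), Bonferroni optionally.  A two-sided test exists behind a flag but
is off by default.

Concordance between a before- and an after-propagation enrichment pairs
pathways by name.  A pathway is *represented* when k ≥ 1 and *significant*
when additionally adjusted p < 0.05.  Pathways represented in only one state
are reported as missing, never imputed as ratio 0 — conflating absence with
zero would distort the bisector tallies.  Bisector tallies (above/on/below
the identity line, for gene ratios and odds ratios) count paired pathways
significant in at least one state; "highly represented" has no canonical
numeric definition, so full tallies are emitted and qualitative judgment is
left to the user.  Rounded composition percentages use the largest-remainder
rule (ties by category order) so splits always sum to 100.

## Gene-exclusion patterns

The immunoglobulin / ribosomal-protein / TCR exclusion regexes
(`^IGK|^IGH|^IGL|^IGJ|^IGS|^IGD|IGFN1`, `^RP([0-9]+-|[LS])`,
`^TRA|^TRB|^TRG`) are applied as printed in their source convention — the
ribosomal digit range is implemented as ASCII `[0-9]` (the printed form uses
a typographic en-dash), and `^TRA` knowingly also catches TRAF-family
symbols.  The step is exposed but OFF by default in the pipeline: upstream
it belongs to variable-gene selection, not to signature construction.

## Synthetic benchmark

The generators emulate the *structure* of the real analysis inputs, not real
single-cell data:

* **Network** — stochastic block model (planted partition): `n_genes` split
  as evenly as possible into `n_modules`, within-module edge probability
  `p_in` > between-module `p_out`.  Standard fixture: 500 genes, 5 modules,
  p_in 0.2, p_out 0.01 — dense enough that module membership is recoverable,
  sparse enough that degree alone is uninformative.  Isolated nodes are
  retained to exercise the disconnected-graph contract.
* **Signature** — a fraction `observe_frac` (default 0.6) of the phenotype
  module is observed with log2FC drawn log-normally (location 0, scale 0.5
  on the log scale → median fold change 2¹ ≈ 2, always positive, matching
  the positive-log2FC filter); the withheld genes are the simulated
  dropouts.  20 off-module background genes receive log2FC from the same
  distribution at half scale — enough noise to make ranking nontrivial
  without overwhelming the planted signal.  Adjusted p-values are drawn
  below 0.05 so generated tables pass the signature filter unchanged.
* **Pathways** — one exact set per planted module plus random decoys
  (default 20, sizes uniform in [5, 50]); names (`MODULE_k` / `RANDOM_j`)
  record provenance.
* **Counts** — negative binomial (base mean 5, dispersion 0.3 — mid-range
  for UMI data), group-1 means of phenotype-module genes multiplied by
  2^effect, independent zero-inflation (default rate 0.1) for dropouts.

Every generator is a pure function of its arguments including one integer
seed; no hidden global state.  What passing tests do **not** show: the
generators have no library-size variation, batch effects, gene–gene
correlation beyond module topology, or realistic degree distributions
(real PPI networks are heavy-tailed; SBM modules are near-regular).
Recovery results on this benchmark demonstrate the machinery is correct and
that propagation can surface withheld genes under modular connectivity —
not that it will do so at any particular rate on real atlases.

## Problem sizes and reproducibility

Tests and the acceptance script use 500-gene networks (10 seeds), 100-gene
property graphs, and 200-gene × 200-cell count matrices (20 seeds) — sizes
at which the dense kernel is exact and the whole suite runs in seconds.
The pipeline writes a JSON manifest (config echo, seeds, version, per-stage
row counts) with no timestamps, so identical config + seed reproduce
byte-identical artifacts; wall times go to the log only.

## Known limitations

* Dense O(|V|³) eigendecomposition bounds practical network size.
* No restart-based propagation (random walk with restart), weighted-edge
  kernels, or approximate sparse exponentials.
* No ranked-list GSEA or permutation enrichment; Fisher tests ignore
  expression level by design.
* Exact-match symbol namespace; no isoform or alias handling.
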