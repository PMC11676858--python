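# netprop-sig

Single-cell RNA-seq marker signatures are noisy and sparse: dropout events
(false zeros from low mRNA capture) leave genuinely relevant genes out of
differential-expression signatures.  `netprop-sig` refines such signatures by
propagating them through a protein-interaction network: genes are rescored by
their diffusion-weighted connectivity to the weighted input signature, so
well-connected dropouts resurface while poorly connected noise genes sink.
It targets immuno-oncology use cases — e.g. tumor-infiltrating regulatory
T-cell (FOXP3+ Treg) and exhausted CD8+ T-cell (Tex) signatures — but works
for any gene list over any undirected gene network.

## Method

Given an undirected network `G = (V, E)` with adjacency matrix `A` and degree
matrix `D`, the graph Laplacian is `L = D − A` and the diffusion kernel is the
heat kernel

```
W = exp(−αL),    α = 0.1 by default
```

`W` is symmetric, entrywise nonnegative and doubly stochastic.  Each gene
carries a *biological relevance score*: its log2 fold change if it belongs to
the filtered up-regulated signature (log2FC > 0 and Bonferroni-adjusted
p < 0.05), 0 otherwise.  Stacking these into the seed vector `S`, the
*diffusion score* of gene *g* is

```
P = W · S,    P_g = Σ_k w_gk · S_k
```

Total mass is conserved (`ΣP = ΣS`).  Genes are ranked by `P` (z-scaled for
inspection of the score decay) and the top 200 form the propagated signature.
Refinement is quantified by Fisher-exact over-representation against GMT
pathway collections before vs. after propagation — gene ratios (overlap /
pathway size), odds ratios, BH-adjusted p-values — plus Venn overlaps and
per-pathway concordance tallies.

A synthetic module provides fully seeded benchmarks with known ground truth:
stochastic-block-model networks with planted modules, signatures drawn from
one module with a fraction of genes withheld (simulated dropouts), module-
aligned pathway collections with random decoys, and zero-inflated
negative-binomial count matrices for the built-in rank-sum marker test.

## Worked example

```python
from netprop_sig import *

network, truth = make_sbm_network(n_genes=500, n_modules=5, p_in=0.2, p_out=0.01, seed=7)
signature, truth = make_signature(truth, network, observe_frac=0.6, seed=8)
kernel = heat_kernel(laplacian(network), alpha=0.1)
result = diffuse(kernel, relevance_vector(filter_signature(signature), network))
top = top_n(scale_scores(result), n=200)

recovered = sum(g in set(top.gene) for g in truth.hidden_genes)
print(f"hidden genes recovered in top 200: {recovered}/{len(truth.hidden_genes)}")

collection = make_pathway_collection(truth, n_random=20, seed=9)
after = fisher_enrichment(list(top.gene), collection, list(network.nodes))
print(filter_and_rank(after, top=3)[["pathway", "k", "K", "gene_ratio", "odds_ratio", "p_adj"]])
```

prints

```
hidden genes recovered in top 200: 40/40
 pathway    k    K  gene_ratio  odds_ratio        p_adj
MODULE_0  100  100         1.0       601.0 1.108742e-47
```

The 500-gene network (5,921 edges at seed 7) carries an 80-gene signature:
60 observed genes of the 100-gene planted module plus 20 background noise
genes; the other 40 module genes were withheld as simulated dropouts.
Propagation recovers all 40 in the top 200, and the planted-module pathway
dominates the post-propagation enrichment (all 100 module genes present,
adjusted p ≈ 10⁻⁴⁷).

The same pipeline runs end to end from the shell:

```
netprop-sig run --outdir my_run --seed 7
netprop-sig simulate --n-genes 500 --n-modules 5 --seed 7 --outdir sim/
netprop-sig diffuse --network sim/network.tsv --signature sim/signature.tsv --top 200 -o ranked.tsv
```

`run` writes every intermediate (network TSV, signature TSV, GMT, ranked
scores, both enrichment tables, concordance report) plus a manifest; reruns
with the same config are byte-identical.  Real edge tables are ingested with
`netprop-sig build-network` (STRING-like tables filtered at combined score
> 300 with experimental evidence required, RNAinter-like at confidence
> 0.25).

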