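"""Seeded synthetic inputs with known ground truth.

The generators emulate the shape of the real analysis inputs without any
external download: a modular undirected gene network (stochastic block
model, the planted-partition benchmark), an up-regulated signature drawn
from one planted module with a fraction of module genes withheld (simulated
scRNA-seq dropouts), pathway collections aligned to modules plus random
decoys, and zero-inflated negative-binomial counts for the marker-test
stand-in.  Every generator is a pure function of its arguments including the
seed; all distributional choices are synthetic stand-ins, labelled as such
in output provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd

from .netio import GeneNetwork, PathwayCollection

__all__ = [
    "SyntheticTruth",
    "make_sbm_network",
    "make_signature",
    "make_pathway_collection",
    "make_counts",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one synthetic scenario.

    ``hidden_genes`` are planted phenotype-module genes withheld from the
    observed signature — the simulated dropouts that propagation should
    surface.  They are always a subset of the phenotype module.
    """

    module_assignment: dict[str, int]
    phenotype_module: int
    seed: int
    hidden_genes: frozenset[str] = frozenset()
    observed_genes: frozenset[str] = frozenset()
    background_genes: frozenset[str] = frozenset()

    def module_genes(self, module: int) -> list[str]:
        return sorted(g for g, m in self.module_assignment.items() if m == module)


def _gene_symbols(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"G{i + 1:0{width}d}" for i in range(n_genes)]


def make_sbm_network(
    n_genes: int,
    n_modules: int,
    p_in: float,
    p_out: float,
    seed: int,
) -> tuple[GeneNetwork, SyntheticTruth]:
    """Sample a planted-partition (stochastic block model) gene network.

    Module sizes split ``n_genes`` as evenly as possible; within-module edge
    probability ``p_in`` must strictly exceed between-module ``p_out``.
    Isolated nodes are retained — the diffusion kernel treats them as
    singleton components.
    """
    if not (0 <= p_out < p_in <= 1):
        raise ValueError(f"require 0 <= p_out < p_in <= 1, got p_in={p_in}, p_out={p_out}")
    if n_modules < 1 or n_modules > n_genes:
        raise ValueError(f"n_modules must be in [1, n_genes], got {n_modules}")
    base, extra = divmod(n_genes, n_modules)
    sizes = [base + (1 if i < extra else 0) for i in range(n_modules)]
    probs = [
        [p_in if i == j else p_out for j in range(n_modules)] for i in range(n_modules)
    ]
    g = nx.stochastic_block_model(sizes, probs, seed=int(seed))
    symbols = _gene_symbols(n_genes)
    g = nx.relabel_nodes(g, dict(enumerate(symbols)))
    assignment: dict[str, int] = {}
    pos = 0
    for module, size in enumerate(sizes):
        for sym in symbols[pos : pos + size]:
            assignment[sym] = module
        pos += size
    clean = nx.Graph()
    clean.add_nodes_from(symbols)
    clean.add_edges_from(g.edges())
    truth = SyntheticTruth(module_assignment=assignment, phenotype_module=0, seed=int(seed))
    return GeneNetwork(clean), truth


def make_signature(
    truth: SyntheticTruth,
    network: GeneNetwork,
    observe_frac: float = 0.6,
    lfc_mean: float = 0.0,
    lfc_sd: float = 0.5,
    n_background: int = 20,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw an up-regulated signature from the phenotype module with dropouts.

    A ``round(observe_frac * |module|)``-sized random subset of phenotype-module
    genes is observed with positive log2 fold change drawn log-normally
    (location ``lfc_mean``, scale ``lfc_sd`` on the log scale); the withheld
    genes become ``hidden_genes``.  ``n_background`` off-module genes receive
    positive log2FC from the same distribution scaled by 0.5 (noise that makes
    ranking nontrivial).  All emitted rows carry adjusted p < 0.05, so the
    table passes the signature filter unchanged.
    """
    if not (0 < observe_frac <= 1):
        raise ValueError(f"observe_frac must be in (0, 1], got {observe_frac}")
    module_genes = truth.module_genes(truth.phenotype_module)
    if len(module_genes) < 2:
        raise ValueError("phenotype module must contain at least 2 genes")
    rng = np.random.default_rng(seed)
    n_obs = int(round(observe_frac * len(module_genes)))
    observed = sorted(rng.choice(module_genes, size=n_obs, replace=False))
    hidden = sorted(set(module_genes) - set(observed))

    off_module = sorted(
        g for g in network.nodes if truth.module_assignment.get(g) != truth.phenotype_module
    )
    if n_background > len(off_module):
        raise ValueError("n_background exceeds the number of off-module genes")
    background = sorted(rng.choice(off_module, size=n_background, replace=False))

    genes = observed + background
    lfc = rng.lognormal(mean=lfc_mean, sigma=lfc_sd, size=len(genes))
    lfc[len(observed):] *= 0.5  # background noise at half scale
    p_adj = rng.uniform(1e-8, 0.05, size=len(genes))
    p = p_adj * rng.uniform(1e-3, 1.0, size=len(genes))

    table = (
        pd.DataFrame(
            {
                "gene": genes,
                "log2fc": lfc,
                "p": p,
                "p_adj": p_adj,
                "provenance": f"synthetic_module_{truth.phenotype_module}",
            }
        )
        .sort_values("gene")
        .reset_index(drop=True)
    )
    updated = replace(
        truth,
        hidden_genes=frozenset(hidden),
        observed_genes=frozenset(observed),
        background_genes=frozenset(background),
    )
    return table, updated


def make_pathway_collection(
    truth: SyntheticTruth,
    n_random: int = 20,
    size_range: tuple[int, int] = (5, 50),
    seed: int = 0,
) -> PathwayCollection:
    """One exact pathway per planted module plus ``n_random`` random decoys.

    Names record provenance: ``MODULE_k`` for planted modules, ``RANDOM_j``
    for decoys of uniform random size within ``size_range``.
    """
    genes = sorted(truth.module_assignment)
    lo, hi = size_range
    if not (2 <= lo <= hi <= len(genes)):
        raise ValueError(f"size_range must lie within [2, {len(genes)}], got {size_range}")
    rng = np.random.default_rng(seed)
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    modules = sorted(set(truth.module_assignment.values()))
    for k in modules:
        sets[f"MODULE_{k}"] = set(truth.module_genes(k))
        desc[f"MODULE_{k}"] = f"synthetic planted module {k}"
    for j in range(n_random):
        size = int(rng.integers(lo, hi + 1))
        sets[f"RANDOM_{j}"] = set(rng.choice(genes, size=size, replace=False))
        desc[f"RANDOM_{j}"] = "synthetic random decoy"
    return PathwayCollection(sets, desc)


def make_counts(
    truth: SyntheticTruth,
    cells_per_group: int = 100,
    base_mean: float = 5.0,
    dispersion: float = 0.3,
    effect_log2fc: float = 1.0,
    dropout_rate: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Zero-inflated negative-binomial counts for the marker-test stand-in.

    Genes x cells; phenotype-module genes have their group-1 mean multiplied
    by ``2**effect_log2fc``; every entry is independently zeroed with
    probability ``dropout_rate``.  Returns the matrix and the per-cell group
    labels (``group1``/``group2``).
    """
    if cells_per_group < 2:
        raise ValueError("cells_per_group must be >= 2")
    for name, val in (
        ("base_mean", base_mean),
        ("dispersion", dispersion),
        ("dropout_rate", dropout_rate),
    ):
        if val < 0:
            raise ValueError(f"{name} must be >= 0, got {val}")
    if dispersion == 0:
        raise ValueError("dispersion must be > 0 (negative-binomial shape)")
    if dropout_rate > 1:
        raise ValueError("dropout_rate is a probability")

    rng = np.random.default_rng(seed)
    genes = sorted(truth.module_assignment)
    n_genes, n_cells = len(genes), 2 * cells_per_group
    in_module = np.array(
        [truth.module_assignment[g] == truth.phenotype_module for g in genes]
    )
    mu = np.full((n_genes, n_cells), base_mean, dtype=float)
    mu[np.ix_(in_module, np.arange(cells_per_group))] *= 2.0 ** effect_log2fc

    r = 1.0 / dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    if dropout_rate > 0:
        counts = np.where(rng.random(counts.shape) < dropout_rate, 0, counts)

    labels = np.array(["group1"] * cells_per_group + ["group2"] * cells_per_group)
    cols = [f"{lab}_c{i % cells_per_group:04d}" for i, lab in enumerate(labels)]
    return pd.DataFrame(counts, index=genes, columns=cols), labels
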