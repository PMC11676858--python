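"""Gene signatures: marker testing, filtering and the relevance vector.

A signature table holds per-gene differential-expression statistics
(gene, log2fc, p, p_adj, provenance).  The up-regulated signature keeps rows
with strictly positive log2 fold change and Bonferroni-adjusted p strictly
below 0.05.  The filtered signature is then mapped onto the network as the
biological-relevance vector S: the log2 fold change for signature genes
present in the network, 0 for every other node.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .netio import GeneNetwork

logger = logging.getLogger(__name__)

SIGNATURE_COLUMNS = ("gene", "log2fc", "p", "p_adj")

# Immunoglobulin / ribosomal-protein / T-cell-receptor exclusion patterns.
# The ribosomal pattern is printed upstream with a typographic en-dash in the
# digit range; it is applied here as the ASCII range [0-9].
DEFAULT_EXCLUDE_PATTERNS = (
    r"^IGK|^IGH|^IGL|^IGJ|^IGS|^IGD|IGFN1",
    r"^RP([0-9]+-|[LS])",
    r"^TRA|^TRB|^TRG",
)


@dataclass(frozen=True)
class RelevanceVector:
    """Per-node seed scores S aligned to a network's canonical node order.

    ``n_mapped`` / ``unmapped`` form the coverage report: signature genes
    absent from the network are counted and listed, never silently dropped.
    """

    scores: np.ndarray
    nodes: tuple[str, ...]
    n_mapped: int
    unmapped: tuple[str, ...]


def rank_sum_markers(
    counts: pd.DataFrame,
    labels,
    provenance: str | None = None,
) -> pd.DataFrame:
    """Two-group marker test: per-gene two-sided rank-sum (Mann-Whitney) p.

    Counts are genes x cells; ``labels`` assigns each cell (column) to one of
    exactly two groups, each with at least 2 cells.  Cells are depth-normalised
    to counts-per-10k before testing.  log2fc = log2((mean1 + 1)/(mean2 + 1))
    on normalised means (pseudocount 1, stable at zero); p_adj is Bonferroni
    (p * n_genes, capped at 1).  Constant genes get p = 1 and log2fc = 0.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != counts.shape[1]:
        raise ValueError("labels must align with count-matrix columns (cells)")
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {len(groups)}")
    g1, g2 = groups
    if (labels == g1).sum() < 2 or (labels == g2).sum() < 2:
        raise ValueError("each group needs at least 2 cells")

    mat = counts.to_numpy(dtype=float)
    depth = mat.sum(axis=0)
    safe = np.where(depth > 0, depth, 1.0)
    norm = mat / safe * 1e4

    x = norm[:, labels == g1]
    y = norm[:, labels == g2]
    n_genes = mat.shape[0]

    pvals = np.ones(n_genes)
    row_min = norm.min(axis=1)
    row_max = norm.max(axis=1)
    varying = row_max > row_min
    if varying.any():
        res = scipy.stats.mannwhitneyu(
            x[varying], y[varying], axis=1, alternative="two-sided", method="asymptotic"
        )
        pvals[varying] = np.nan_to_num(res.pvalue, nan=1.0)

    m1 = x.mean(axis=1)
    m2 = y.mean(axis=1)
    log2fc = np.log2((m1 + 1.0) / (m2 + 1.0))
    p_adj = np.minimum(pvals * n_genes, 1.0)

    return pd.DataFrame(
        {
            "gene": counts.index.astype(str),
            "log2fc": log2fc,
            "p": pvals,
            "p_adj": p_adj,
            "provenance": provenance or f"{g1}_vs_{g2}",
        }
    ).reset_index(drop=True)


def filter_signature(
    table: pd.DataFrame,
    min_log2fc: float = 0.0,
    max_p_adj: float = 0.05,
) -> pd.DataFrame:
    """Keep rows with log2fc strictly above ``min_log2fc`` AND adjusted p
    strictly below ``max_p_adj`` (both boundaries exclusive)."""
    if table.empty:
        raise ValueError("filter_signature requires a nonempty table")
    kept = table[(table["log2fc"] > min_log2fc) & (table["p_adj"] < max_p_adj)]
    if kept.empty:
        logger.warning("no genes survived the signature filter")
    return kept.reset_index(drop=True)


def exclude_gene_patterns(
    genes, patterns: tuple[str, ...] = DEFAULT_EXCLUDE_PATTERNS
) -> list[str]:
    """Drop symbols matching any immunoglobulin/ribosomal/TCR pattern.

    Patterns are applied as printed; the TCR anchor ^TRA intentionally also
    catches TRAF-family symbols.
    """
    compiled = [re.compile(p) for p in patterns]
    return [g for g in genes if not any(rx.search(g) for rx in compiled)]


def relevance_vector(signature: pd.DataFrame, network: GeneNetwork) -> RelevanceVector:
    """Map a filtered signature onto the network node order.

    S_g is the gene's log2 fold change for signature genes present in the
    network and 0 everywhere else.  Raises if no signature gene maps.
    """
    genes = signature["gene"].astype(str)
    if genes.duplicated().any():
        dupes = sorted(genes[genes.duplicated()].unique())
        raise ValueError(f"duplicate genes in signature: {dupes[:5]}")
    lookup = dict(zip(genes, signature["log2fc"].astype(float)))
    node_set = set(network.nodes)
    unmapped = tuple(sorted(g for g in lookup if g not in node_set))
    n_mapped = len(lookup) - len(unmapped)
    if n_mapped == 0:
        raise ValueError("no signature gene maps onto the network")
    if unmapped:
        logger.info(
            "%d/%d signature genes absent from the network", len(unmapped), len(lookup)
        )
    scores = np.array([lookup.get(n, 0.0) for n in network.nodes], dtype=float)
    return RelevanceVector(scores, network.nodes, n_mapped, unmapped)
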