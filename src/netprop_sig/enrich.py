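"""Gene-set over-representation by Fisher exact test.

For a query gene list of size n drawn from a universe of size N, and a
pathway of size K (both intersected with the universe), the overlap k is
tested against the hypergeometric null.  The one-sided (enrichment
direction) p-value is the upper tail P(X >= k).  Reported alongside:

* gene ratio  — k / K, the "6 out of 11 genes" convention (a ``query``
  convention k / n is available behind a flag);
* odds ratio  — cross-product ratio of the 2x2 table
  (k, n-k; K-k, N-K-n+k), with the Haldane–Anscombe 0.5 added to every cell
  when any cell is zero;
* adjusted p  — Benjamini–Hochberg across the collection (configurable to
  Bonferroni).

Filtering follows the upstream convention: adjusted p strictly below 0.05
and overlap count of at least 3 ("count > 2"), then decreasing gene ratio.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .netio import PathwayCollection

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = (
    "pathway", "k", "K", "n", "N", "gene_ratio", "odds_ratio", "p", "p_adj", "genes",
)


def fisher_pvalue(k: int, K: int, n: int, N: int, alternative: str = "greater") -> float:
    """Fisher exact p for overlap k of a size-n query with a size-K set in a
    size-N universe.  ``greater`` is the hypergeometric upper tail P(X >= k)."""
    if alternative == "greater":
        return float(scipy.stats.hypergeom.sf(k - 1, N, K, n))
    if alternative == "two-sided":
        table = [[k, n - k], [K - k, N - K - n + k]]
        return float(scipy.stats.fisher_exact(table, alternative="two-sided")[1])
    raise ValueError(f"unknown alternative {alternative!r}")


def odds_ratio(k: int, K: int, n: int, N: int) -> float:
    """Cross-product ratio of the enrichment 2x2 table; Haldane–Anscombe 0.5
    added to all cells when any cell is zero."""
    a, b, c, d = k, n - k, K - k, N - K - n + k
    if min(a, b, c, d) < 0:
        raise ValueError(f"invalid 2x2 table for k={k}, K={K}, n={n}, N={N}")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_enrichment(
    query,
    collection: PathwayCollection,
    universe,
    alternative: str = "greater",
    gene_ratio_convention: str = "pathway",
    adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """Per-pathway Fisher exact over-representation of ``query`` in ``universe``.

    Query genes outside the universe are dropped with a logged count;
    pathways are intersected with the universe (those left empty are dropped
    with a logged count).  Raises on an empty universe or an empty
    post-intersection query.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    query_all = list(dict.fromkeys(query))
    query_set = set(query_all) & universe_set
    dropped = len(query_all) - len(query_set)
    if dropped:
        logger.info("%d query gene(s) outside the universe dropped", dropped)
    if not query_set:
        raise ValueError("query is empty after intersection with the universe")
    if gene_ratio_convention not in ("pathway", "query"):
        raise ValueError(f"unknown gene_ratio_convention {gene_ratio_convention!r}")

    n = len(query_set)
    N = len(universe_set)
    rows = []
    n_empty = 0
    for name in sorted(collection):
        members = collection[name] & universe_set
        if not members:
            n_empty += 1
            continue
        K = len(members)
        overlap = sorted(members & query_set)
        k = len(overlap)
        denom = K if gene_ratio_convention == "pathway" else n
        rows.append(
            {
                "pathway": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "gene_ratio": k / denom,
                "odds_ratio": odds_ratio(k, K, n, N),
                "p": fisher_pvalue(k, K, n, N, alternative),
                "genes": ";".join(overlap),
            }
        )
    if n_empty:
        logger.info("%d pathway(s) empty after universe intersection dropped", n_empty)
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no pathway overlaps the universe")
    if adjust == "fdr_bh":
        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    elif adjust == "bonferroni":
        table["p_adj"] = np.minimum(table["p"] * len(table), 1.0)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return table[list(ENRICHMENT_COLUMNS)]


def filter_and_rank(
    table: pd.DataFrame,
    max_p_adj: float = 0.05,
    min_count: int = 3,
    top: int = 10,
) -> pd.DataFrame:
    """Keep rows with adjusted p strictly below ``max_p_adj`` and overlap
    k >= ``min_count``; order by decreasing gene ratio (ties: adjusted p
    ascending, then name) and truncate to ``top``."""
    kept = table[(table["p_adj"] < max_p_adj) & (table["k"] >= min_count)]
    kept = kept.sort_values(
        ["gene_ratio", "p_adj", "pathway"], ascending=[False, True, True]
    )
    return kept.head(top).reset_index(drop=True)
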