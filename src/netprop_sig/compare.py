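"""Before/after comparison of signatures and their enrichments.

Quantifies how network propagation refines a signature: Venn overlaps of
gene sets, top-list overlap fractions, represented-pathway counts before and
after propagation, per-pathway paired gene ratios and odds ratios with
above/below-bisector tallies, and the small cell-composition arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .errors import OrderMismatchError

SIGNIFICANCE_P_ADJ = 0.05


@dataclass(frozen=True)
class VennCounts:
    size_a: int
    size_b: int
    shared: int
    exclusive_a: int
    exclusive_b: int


@dataclass
class ComparisonReport:
    """Pairing of a before-propagation and an after-propagation enrichment.

    A pathway is *represented* when at least one query gene overlaps it
    (k >= 1) and *significant* when additionally adjusted p < 0.05.
    ``paired`` holds pathways represented in both states; pathways
    represented in only one state are listed as missing, never imputed as
    zero on the absent side.  Bisector tallies count paired pathways,
    significant in at least one state, whose after-value lies above / on /
    below the before-value.
    """

    represented_before: int
    represented_after: int
    significant_before: int
    significant_after: int
    paired: pd.DataFrame
    missing_after: list[str] = field(default_factory=list)
    missing_before: list[str] = field(default_factory=list)
    gene_ratio_tally: dict[str, int] = field(default_factory=dict)
    odds_ratio_tally: dict[str, int] = field(default_factory=dict)

    @property
    def represented_fold_change(self) -> float:
        """before / after represented-pathway count (e.g. 2.0 = 2-fold decrease)."""
        if self.represented_after == 0:
            return float("inf")
        return self.represented_before / self.represented_after

    def to_dict(self) -> dict:
        return {
            "represented_before": self.represented_before,
            "represented_after": self.represented_after,
            "significant_before": self.significant_before,
            "significant_after": self.significant_after,
            "represented_fold_change": self.represented_fold_change,
            "missing_after": self.missing_after,
            "missing_before": self.missing_before,
            "gene_ratio_tally": self.gene_ratio_tally,
            "odds_ratio_tally": self.odds_ratio_tally,
        }


def venn(set_a, set_b) -> VennCounts:
    """Exact two-set overlap arithmetic."""
    a, b = set(set_a), set(set_b)
    shared = len(a & b)
    return VennCounts(len(a), len(b), shared, len(a) - shared, len(b) - shared)


def overlap_fraction(top_a, top_b) -> float:
    """|intersection| / list length for two equally sized ranked lists."""
    top_a, top_b = list(top_a), list(top_b)
    if len(top_a) != len(top_b):
        raise ValueError(f"length mismatch: {len(top_a)} vs {len(top_b)}")
    if not top_a:
        raise ValueError("empty lists")
    return len(set(top_a) & set(top_b)) / len(top_a)


def _tally(before: np.ndarray, after: np.ndarray, significant: np.ndarray) -> dict[str, int]:
    b, a = before[significant], after[significant]
    return {
        "above": int((a > b).sum()),
        "on": int((a == b).sum()),
        "below": int((a < b).sum()),
    }


def pathway_concordance(before: pd.DataFrame, after: pd.DataFrame) -> ComparisonReport:
    """Pair the two enrichment tables by pathway name.

    Both tables must come from the same collection and universe (same pathway
    rows and N); a mismatch is a hard error.  Pairing is lossless: every
    pathway represented in either state appears exactly once, in ``paired``
    or in one missing list.
    """
    names_b, names_a = set(before["pathway"]), set(after["pathway"])
    if names_b != names_a or set(before["N"]) != set(after["N"]):
        raise OrderMismatchError(
            "enrichment tables disagree on pathway collection or universe"
        )
    b = before.set_index("pathway")
    a = after.set_index("pathway")
    rep_b = set(b.index[b["k"] >= 1])
    rep_a = set(a.index[a["k"] >= 1])
    both = sorted(rep_b & rep_a)

    paired = pd.DataFrame(
        {
            "pathway": both,
            "gene_ratio_before": b.loc[both, "gene_ratio"].to_numpy(),
            "gene_ratio_after": a.loc[both, "gene_ratio"].to_numpy(),
            "odds_ratio_before": b.loc[both, "odds_ratio"].to_numpy(),
            "odds_ratio_after": a.loc[both, "odds_ratio"].to_numpy(),
            "p_adj_before": b.loc[both, "p_adj"].to_numpy(),
            "p_adj_after": a.loc[both, "p_adj"].to_numpy(),
        }
    )
    significant = (
        (paired["p_adj_before"] < SIGNIFICANCE_P_ADJ)
        | (paired["p_adj_after"] < SIGNIFICANCE_P_ADJ)
    ).to_numpy()
    return ComparisonReport(
        represented_before=len(rep_b),
        represented_after=len(rep_a),
        significant_before=int(((b["k"] >= 1) & (b["p_adj"] < SIGNIFICANCE_P_ADJ)).sum()),
        significant_after=int(((a["k"] >= 1) & (a["p_adj"] < SIGNIFICANCE_P_ADJ)).sum()),
        paired=paired,
        missing_after=sorted(rep_b - rep_a),
        missing_before=sorted(rep_a - rep_b),
        gene_ratio_tally=_tally(
            paired["gene_ratio_before"].to_numpy(),
            paired["gene_ratio_after"].to_numpy(),
            significant,
        ),
        odds_ratio_tally=_tally(
            paired["odds_ratio_before"].to_numpy(),
            paired["odds_ratio_after"].to_numpy(),
            significant,
        ),
    )


def composition_ratio(counts) -> tuple[list[float], list[int]]:
    """Per-category proportions and a rounded percentage split summing to 100.

    Rounding uses the largest-remainder rule (ties broken by category order),
    so e.g. cell counts (129977, 117731) give the 52:48 split.
    """
    counts = [int(c) for c in counts]
    if any(c < 0 for c in counts):
        raise ValueError("counts must be nonnegative")
    total = sum(counts)
    if total == 0:
        raise ValueError("total count is zero")
    proportions = [c / total for c in counts]
    raw = [100.0 * p for p in proportions]
    floors = [int(np.floor(r)) for r in raw]
    shortfall = 100 - sum(floors)
    remainders = sorted(
        range(len(raw)), key=lambda i: (-(raw[i] - floors[i]), i)
    )
    percents = list(floors)
    for i in remainders[:shortfall]:
        percents[i] += 1
    return proportions, percents


def ranking_auroc(scores, labels) -> float:
    """Rank-based AUROC of ``scores`` for binary ``labels`` (1 = positive).

    Computed from the Mann-Whitney U statistic with midranks for ties:
    AUROC = (R_pos - n_pos(n_pos+1)/2) / (n_pos * n_neg).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both positive and negative labels")
    ranks = scipy.stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))
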