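import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netprop_sig.compare import (
    composition_ratio,
    overlap_fraction,
    pathway_concordance,
    ranking_auroc,
    venn,
)
from netprop_sig.errors import OrderMismatchError


def test_venn_reproduces_signature_overlap_arithmetic():
    """571- and 240-gene signatures sharing 190 genes leave 381 and 50 exclusives."""
    a = {f"A{i}" for i in range(381)} | {f"S{i}" for i in range(190)}
    b = {f"B{i}" for i in range(50)} | {f"S{i}" for i in range(190)}
    vc = venn(a, b)
    assert (vc.size_a, vc.size_b, vc.shared) == (571, 240, 190)
    assert (vc.exclusive_a, vc.exclusive_b) == (381, 50)


def test_venn_disjoint_and_identical():
    assert venn({"A"}, {"B"}).shared == 0
    vc = venn({"A", "B"}, {"A", "B"})
    assert vc.shared == 2 and vc.exclusive_a == vc.exclusive_b == 0


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    a=st.sets(st.integers(0, 50), max_size=30),
    b=st.sets(st.integers(0, 50), max_size=30),
)
def test_venn_is_symmetric_with_labels_swapped(a, b):
    ab, ba = venn(a, b), venn(b, a)
    assert ab.shared == ba.shared
    assert ab.exclusive_a == ba.exclusive_b
    assert ab.exclusive_a + ab.shared + ab.exclusive_b == len(a | b)


def test_overlap_fraction_cases():
    assert overlap_fraction(list("abc"), list("abc")) == 1.0
    assert overlap_fraction(list("abc"), list("xyz")) == 0.0
    a = [f"g{i}" for i in range(200)]
    b = a[:180] + [f"h{i}" for i in range(20)]
    assert overlap_fraction(a, b) == pytest.approx(0.90)
    with pytest.raises(ValueError):
        overlap_fraction(list("ab"), list("abc"))


def enrichment_table(rows):
    return pd.DataFrame(
        rows,
        columns=["pathway", "k", "K", "n", "N", "gene_ratio", "odds_ratio", "p", "p_adj", "genes"],
    )


def base_table():
    return enrichment_table(
        [
            ("P1", 5, 10, 20, 100, 0.5, 8.0, 1e-4, 1e-3, ""),
            ("P2", 2, 10, 20, 100, 0.2, 1.5, 0.2, 0.4, ""),
            ("P3", 1, 5, 20, 100, 0.2, 1.0, 0.5, 0.6, ""),
            ("P4", 0, 8, 20, 100, 0.0, 0.1, 1.0, 1.0, ""),
        ]
    )


def test_identical_tables_sit_on_the_bisector():
    rep = pathway_concordance(base_table(), base_table())
    assert rep.represented_before == rep.represented_after == 3
    assert rep.missing_after == [] and rep.missing_before == []
    assert rep.odds_ratio_tally == {"above": 0, "on": 1, "below": 0}  # only P1 significant
    assert rep.gene_ratio_tally["on"] == 1


def test_represented_pathway_count_decrease_is_reported_as_fold_change():
    before = base_table()
    after = base_table()
    after.loc[after["pathway"] == "P3", ["k", "gene_ratio"]] = 0
    rep = pathway_concordance(before, after)  # 3 represented -> 2
    assert rep.represented_before == 3 and rep.represented_after == 2
    assert rep.represented_fold_change == pytest.approx(1.5)

    after.loc[after["pathway"] == "P2", ["k", "gene_ratio"]] = 0
    rep = pathway_concordance(before, after)  # 3 represented -> 1
    assert rep.represented_fold_change == pytest.approx(3.0)
    assert rep.missing_after == ["P2", "P3"]


def test_pairing_is_lossless_and_missing_never_imputed():
    before = base_table()
    after = base_table()
    after.loc[after["pathway"] == "P3", ["k", "gene_ratio"]] = 0
    rep = pathway_concordance(before, after)
    listed = set(rep.paired["pathway"]) | set(rep.missing_after) | set(rep.missing_before)
    assert listed == {"P1", "P2", "P3"}
    assert "P3" in rep.missing_after
    assert "P3" not in set(rep.paired["pathway"])


def test_collection_mismatch_is_hard_error():
    other = base_table().replace({"P4": "P9"})
    with pytest.raises(OrderMismatchError):
        pathway_concordance(base_table(), other)


def test_greater_after_odds_ratios_tally_above():
    before = base_table()
    after = base_table()
    after.loc[after["pathway"] == "P1", "odds_ratio"] = 20.0
    rep = pathway_concordance(before, after)
    assert rep.odds_ratio_tally == {"above": 1, "on": 0, "below": 0}


@pytest.mark.parametrize(
    "counts, expected",
    [
        ((129977, 117731), [52, 48]),  # CD4+ vs CD8+ T-cell split
        ((50, 50), [50, 50]),
        ((1, 0), [100, 0]),
        ((1, 1, 1), [34, 33, 33]),  # largest remainder, ties by order
    ],
)
def test_composition_rounded_split(counts, expected):
    proportions, percents = composition_ratio(counts)
    assert percents == expected
    assert sum(proportions) == pytest.approx(1.0)


def test_composition_rejects_degenerate_input():
    with pytest.raises(ValueError):
        composition_ratio([0, 0])
    with pytest.raises(ValueError):
        composition_ratio([-1, 2])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 10_000), min_size=1, max_size=8).filter(lambda c: sum(c) > 0))
def test_composition_percentages_always_sum_to_100(counts):
    _, percents = composition_ratio(counts)
    assert sum(percents) == 100
    assert all(p >= 0 for p in percents)


def test_ranking_auroc_matches_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(0)
    scores = np.round(rng.normal(size=200), 1)  # rounding forces ties
    labels = rng.random(200) < 0.3
    assert ranking_auroc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))
    with pytest.raises(ValueError):
        ranking_auroc([1.0, 2.0], [1, 1])
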