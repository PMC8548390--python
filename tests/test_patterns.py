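import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from heteroprot import (
    HeteroprotError,
    LABELS,
    PatternParams,
    PatternSummary,
    classify_all,
    classify_protein,
    percentage,
    summarize_patterns,
)
from conftest import make_matrix

positive = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)
LITERAL = PatternParams(mode="literal")
RECONSTRUCTED = PatternParams(mode="reconstructed")


@pytest.mark.parametrize(
    "count, total, decimals, expected",
    [
        (697, 4395, 2, 15.86),
        (254, 4395, 2, 5.78),
        (291, 4395, 2, 6.62),
        (155, 4395, 2, 3.53),
        (195, 299, 1, 65.2),
        (270, 299, 1, 90.3),
        (75, 270, 1, 27.8),
        (150, 195, 1, 76.9),
        (0, 10, 2, 0.0),
        (1, 8, 0, 13.0),  # 12.5 rounds half-away-from-zero, not to-even
        (113, 4395, 2, 2.57),  # arithmetic, not the tabulated misprint 2.58
        (112, 4395, 2, 2.55),
    ],
)
def test_percentage_half_away_from_zero(count, total, decimals, expected):
    assert percentage(count, total, decimals) == expected


def test_percentage_rejects_bad_denominators():
    with pytest.raises(HeteroprotError):
        percentage(1, 0, 2)
    with pytest.raises(HeteroprotError):
        percentage(5, 4, 2)


def means_for(r_hp, r_mp):
    """Build (f1, p1, p2) with the requested f1/HP and f1/MP ratios.

    HP is pinned at 1.0 so f1/HP equals r_hp bit-exactly (boundary cases
    must not drift through float division)."""
    f1 = r_hp
    p2 = 2 * r_hp / r_mp - 1.0
    assert p2 <= 1.0 + 1e-12
    return f1, 1.0, p2


@pytest.mark.parametrize(
    "r_hp, r_mp, mode, expected",
    [
        (2.0, 2.4, "literal", "over_dominant_up"),
        (1.55, 1.86, "literal", "high_parent"),
        (0.58, 0.61, "literal", "under_dominant"),
        (1.5 * (1 + 0.10), 1.9, "literal", "over_dominant_up"),  # closed at U(1+b)
        (1.5, 1.8, "literal", "high_parent"),                    # closed at U
        (2.0, 2.4, "reconstructed", "over_dominant_up"),
    ],
)
def test_rule_table_band_examples(r_hp, r_mp, mode, expected):
    f1, p1, p2 = means_for(r_hp, r_mp)
    call = classify_protein(f1, p1, p2, PatternParams(mode=mode))
    assert call.label == expected


def test_mid_parent_ratio_one_is_additive():
    call = classify_protein(1.0, 1.2, 0.8, LITERAL)
    assert call.label == "additive" and call.direction == "none"


def test_reconstructed_low_parent_band_references_the_low_parent():
    # hybrid at 0.636 x LP with 2-fold diverged parents
    call = classify_protein(0.636, 1.0, 2.0, RECONSTRUCTED)
    assert call.label == "low_parent" and call.direction == "down"
    # the literal reading sends the same protein to under_dominant (vs HP)
    assert classify_protein(0.636, 1.0, 2.0, LITERAL).label == "under_dominant"


def test_partial_nonadditive_catches_the_unbanded_gap():
    call = classify_protein(1.6, 1.2, 1.0, LITERAL)  # r_mp=1.4545 -> additive
    assert call.label == "additive"
    call = classify_protein(1.8, 1.3, 1.0, LITERAL)  # r_mp=1.565 but r_hp=1.3846
    assert call.label == "partial_nonadditive" and call.direction == "up"


def test_non_positive_means_rejected():
    with pytest.raises(HeteroprotError, match="positive"):
        classify_protein(1.0, 0.0, 1.0)


@pytest.mark.parametrize("params", [LITERAL, RECONSTRUCTED])
@given(f1=positive, p1=positive, p2=positive, c=positive)
def test_partition_symmetry_and_scale_invariance(params, f1, p1, p2, c):
    call = classify_protein(f1, p1, p2, params)
    assert call.label in LABELS  # exactly one rule fires, always
    assert classify_protein(f1, p2, p1, params).label == call.label
    assert classify_protein(c * f1, c * p1, c * p2, params).label == call.label


@pytest.mark.parametrize("params", [LITERAL, RECONSTRUCTED])
def test_label_sweep_is_monotone_in_f1(params):
    rank = {"under_dominant": 0, "low_parent": 1, "partial_nonadditive": 2,
            "additive": 2, "high_parent": 3, "over_dominant_up": 4}
    for p1, p2 in [(1.0, 1.0), (1.0, 1.3), (1.0, 2.0), (1.0, 5.0)]:
        labels = [classify_protein(f1, p1, p2, params).label
                  for f1 in np.geomspace(0.05, 50.0, 800)]
        ranks = [rank[label] for label in labels]
        assert ranks == sorted(ranks)


def test_band_zero_collapses_the_dominant_classes():
    for mode in ("literal", "reconstructed"):
        params = PatternParams(band=0.0, mode=mode)
        labels = {
            classify_protein(f1, 1.0, 1.5, params).label
            for f1 in np.geomspace(0.05, 50.0, 2000)
        }
        assert "high_parent" not in labels and "low_parent" not in labels


def test_summarize_patterns_reproduces_study_percentages():
    summary = PatternSummary.from_counts(
        n_additive=29, n_overdominant_up=150, n_overdominant_down=45,
        n_dominant_high=51, n_dominant_low=24,
    )
    assert summary.n_nonadditive == 270
    assert summary.pct_nonadditive_of_classified == 90.3
    assert summary.pct_overdominant_of_nonadditive == 72.2
    assert summary.pct_dominant_of_nonadditive == 27.8
    assert summary.pct_overdominant_of_classified == 65.2
    assert summary.pct_up_of_overdominant == 76.9


def test_summarize_patterns_degenerate_compositions():
    all_additive = PatternSummary.from_counts(5, 0, 0, 0, 0)
    assert all_additive.pct_nonadditive_of_classified == 0.0
    assert all_additive.pct_overdominant_of_nonadditive is None
    lone = PatternSummary.from_counts(0, 1, 0, 0, 0)
    assert lone.pct_overdominant_of_classified == 100.0
    with pytest.raises(HeteroprotError):
        summarize_patterns([])


def test_classify_all_uses_replicate_means_and_validates_ids():
    matrix = make_matrix({
        "od": ([90, 100, 110], [190, 200, 210], [790, 800, 810]),
        "add": ([100, 100, 100], [200, 200, 200], [150, 150, 150]),
    })
    calls = classify_all(matrix, ["od", "add"])
    labels = {c.protein_id: c.label for c in calls}
    assert labels == {"od": "over_dominant_up", "add": "additive"}
    assert classify_all(matrix, []) == []
    with pytest.raises(HeteroprotError, match="ghost"):
        classify_all(matrix, ["ghost"])
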