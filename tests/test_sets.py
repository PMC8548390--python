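import numpy as np
import pandas as pd
import pytest

from heteroprot import (
    HeteroprotError,
    VennPartition,
    cluster_rows,
    enrich_terms,
    shared_fraction,
    venn_partition,
)
from oracles import hypergeom_upper_tail, upgma_merge_heights


def test_venn_partition_trivial_configurations():
    part = venn_partition({"x"}, {"x"}, {"x"})
    assert part.abc == 1
    assert (part.only_a, part.only_b, part.only_c, part.ab, part.ac, part.bc) == (0,) * 6
    disjoint = venn_partition({1, 2}, {3, 4, 5}, {6, 7, 8, 9})
    assert (disjoint.only_a, disjoint.only_b, disjoint.only_c) == (2, 3, 4)


def test_venn_regions_reconstruct_set_sizes_against_membership_oracle():
    rng = np.random.default_rng(17)
    ids = [f"P{i}" for i in range(100)]
    for _ in range(10):
        a, b, c = (set(rng.choice(ids, size=rng.integers(0, 60), replace=False))
                   for _ in range(3))
        part = venn_partition(a, b, c)
        assert part.size("a") == len(a)
        assert part.size("b") == len(b)
        assert part.size("c") == len(c)
        total = (part.only_a + part.only_b + part.only_c
                 + part.ab + part.ac + part.bc + part.abc)
        assert total == len(a | b | c)
        # region counts by brute-force membership testing
        brute_abc = sum(1 for x in ids if x in a and x in b and x in c)
        assert part.abc == brute_abc


def test_shared_fraction_worked_example_and_edges():
    part = VennPartition(only_a=227, only_b=0, only_c=0, ab=0, ac=23, bc=0, abc=4)
    assert part.size("a") == 254
    assert shared_fraction(part, ("a", "c"), "a") == 10.63
    empty_pair = VennPartition(only_a=5, only_b=1, only_c=1, ab=0, ac=0, bc=0, abc=0)
    assert shared_fraction(empty_pair, ("a", "c"), "a") == 0.0
    all_triple = VennPartition(only_a=0, only_b=0, only_c=0, ab=0, ac=0, bc=0, abc=9)
    assert shared_fraction(all_triple, ("a", "b"), "a") == 100.0
    nothing = VennPartition(0, 1, 1, 0, 0, 0, 0)
    with pytest.raises(HeteroprotError, match="empty"):
        shared_fraction(nothing, ("a", "b"), "a")


def test_enrichment_exact_tail_and_boundaries():
    background = [f"P{i}" for i in range(8)]
    terms = pd.DataFrame({
        "protein_id": background[:4] + background,
        "term_id": ["T1"] * 4 + ["ALL"] * 8,
    })
    de = background[:3] + [background[7]]  # k=3 of K=4, n=4, N=8
    result = enrich_terms(de, background, terms).set_index("term_id")
    assert result.loc["T1", "p_raw"] == pytest.approx(17 / 70, abs=1e-12)
    assert result.loc["ALL", "p_raw"] == pytest.approx(1.0)  # term in everything
    absent = pd.DataFrame({"protein_id": background[4:7], "term_id": ["T0"] * 3})
    r0 = enrich_terms(background[:3], background, absent)  # k=0
    assert r0["p_raw"].iloc[0] == pytest.approx(1.0)
    with pytest.raises(HeteroprotError, match="absent"):
        enrich_terms(["ghost"], background, terms)


def test_enrichment_matches_exhaustive_enumeration_and_is_label_invariant():
    rng = np.random.default_rng(23)
    for _ in range(20):
        big_n = int(rng.integers(4, 25))
        background = [f"P{i}" for i in range(big_n)]
        n = int(rng.integers(1, big_n + 1))
        big_k = int(rng.integers(1, big_n + 1))
        de = list(rng.choice(background, size=n, replace=False))
        with_term = list(rng.choice(background, size=big_k, replace=False))
        terms = pd.DataFrame({"protein_id": with_term, "term_id": "T"})
        got = enrich_terms(de, background, terms)["p_raw"].iloc[0]
        k = len(set(de) & set(with_term))
        assert got == pytest.approx(float(hypergeom_upper_tail(k, big_n, big_k, n)), abs=1e-10)


def test_upgma_hand_computed_example():
    rows = pd.DataFrame([[0.0], [1.0], [5.0]], index=["a", "b", "c"])
    dendro = cluster_rows(rows)
    np.testing.assert_allclose(sorted(dendro.heights), [1.0, 4.5], atol=1e-12)
    twins = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
    assert cluster_rows(twins).heights[0] == 0.0


def test_upgma_matches_brute_force_oracle():
    rng = np.random.default_rng(31)
    for n in (3, 5, 8):
        x = rng.normal(size=(n, 4))
        frame = pd.DataFrame(x, index=[f"r{i}" for i in range(n)])
        dendro = cluster_rows(frame)
        np.testing.assert_allclose(
            sorted(dendro.heights), upgma_merge_heights(x), atol=1e-10
        )
        # average linkage on a metric is monotone
        assert (np.diff(dendro.heights) >= -1e-12).all()


def test_upgma_heights_are_permutation_invariant():
    rng = np.random.default_rng(41)
    x = rng.normal(size=(7, 3))
    frame = pd.DataFrame(x, index=[f"r{i}" for i in range(7)])
    shuffled = frame.iloc[rng.permutation(7)]
    np.testing.assert_allclose(
        sorted(cluster_rows(frame).heights),
        sorted(cluster_rows(shuffled).heights),
        atol=1e-10,
    )


def test_cluster_rejects_missing_values_and_tiny_input():
    frame = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]], index=["a", "b"])
    with pytest.raises(HeteroprotError, match="missing"):
        cluster_rows(frame)
    with pytest.raises(HeteroprotError, match="at least 2"):
        cluster_rows(pd.DataFrame([[1.0, 2.0]], index=["a"]))


def test_newick_export_contains_all_leaves_and_parses():
    rng = np.random.default_rng(43)
    frame = pd.DataFrame(rng.normal(size=(6, 3)), index=[f"leaf{i}" for i in range(6)])
    newick = cluster_rows(frame).to_newick()
    assert newick.endswith(";")
    assert newick.count("(") == newick.count(")") == 5  # n-1 internal nodes
    for leaf in frame.index:
        assert leaf in newick
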