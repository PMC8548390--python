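"""Set-level summaries of DEP lists: Venn partition, term over-representation,
and average-linkage hierarchical clustering of expression profiles."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .errors import HeteroprotError
from .io import QuantMatrix
from .patterns import percentage


@dataclass(frozen=True)
class VennPartition:
    """Counts of the seven regions of a three-set Venn diagram.

    By pipeline convention A is the parent-vs-parent DEP set, B the
    hybrid-vs-female set and C the hybrid-vs-male set, but the partition is
    pure set algebra.
    """

    only_a: int
    only_b: int
    only_c: int
    ab: int   # in A and B only
    ac: int   # in A and C only
    bc: int   # in B and C only
    abc: int  # in all three

    def size(self, which: str) -> int:
        which = which.lower()
        if which == "a":
            return self.only_a + self.ab + self.ac + self.abc
        if which == "b":
            return self.only_b + self.ab + self.bc + self.abc
        if which == "c":
            return self.only_c + self.ac + self.bc + self.abc
        raise HeteroprotError(f"unknown set {which!r}; expected 'a', 'b' or 'c'")

    def pair_region(self, pair: tuple[str, str]) -> int:
        key = "".join(sorted(p.lower() for p in pair))
        regions = {"ab": self.ab, "ac": self.ac, "bc": self.bc}
        if key not in regions:
            raise HeteroprotError(f"unknown pair {pair!r}")
        return regions[key]


def venn_partition(set_a: Iterable, set_b: Iterable, set_c: Iterable) -> VennPartition:
    a, b, c = set(set_a), set(set_b), set(set_c)
    abc = a & b & c
    return VennPartition(
        only_a=len(a - b - c),
        only_b=len(b - a - c),
        only_c=len(c - a - b),
        ab=len((a & b) - abc),
        ac=len((a & c) - abc),
        bc=len((b & c) - abc),
        abc=len(abc),
    )


def shared_fraction(
    partition: VennPartition, pair: tuple[str, str], denominator_set: str
) -> float:
    """Percent of one set shared by a given pair (pair-exclusive region + triple)."""
    denom = partition.size(denominator_set)
    if denom == 0:
        raise HeteroprotError("denominator set is empty")
    shared = partition.pair_region(pair) + partition.abc
    return percentage(shared, denom, 2)


def enrich_terms(
    de_ids: Iterable[str],
    background_ids: Iterable[str],
    term_map: pd.DataFrame | Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per annotation term.

    ``term_map`` is either a DataFrame with columns protein_id/term_id or a
    mapping protein -> terms.  p-values are the upper hypergeometric tail
    P(X >= k) (Fisher's exact test for over-representation) and are BH
    adjusted across terms.
    """
    de = set(de_ids)
    background = set(background_ids)
    stray = sorted(de - background)
    if stray:
        raise HeteroprotError(f"DE proteins absent from the background: {stray}")
    if isinstance(term_map, pd.DataFrame):
        pairs = term_map[["protein_id", "term_id"]].itertuples(index=False)
    else:
        pairs = ((p, t) for p, terms in term_map.items() for t in terms)
    members: dict[str, set[str]] = {}
    for protein, term in pairs:
        if protein in background:
            members.setdefault(term, set()).add(protein)

    n, big_n = len(de), len(background)
    rows = []
    for term in sorted(members):
        big_k = len(members[term])
        k = len(members[term] & de)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append({"term_id": term, "k": k, "K": big_k, "n": n, "N": big_n,
                     "p_raw": min(p, 1.0)})
    frame = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "p_raw"])
    if len(frame):
        from .deps import bh_adjust

        frame["p_adj"] = bh_adjust(frame["p_raw"].to_numpy())
        frame = frame.sort_values(["p_raw", "term_id"]).reset_index(drop=True)
    else:
        frame["p_adj"] = []
    return frame


@dataclass(frozen=True)
class Dendrogram:
    """Result of UPGMA clustering: scipy linkage matrix plus the row ids."""

    ids: tuple[str, ...]
    linkage: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.ids[i] for i in hierarchy.leaves_list(self.linkage)]

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.linkage, columns=["cluster_i", "cluster_j", "height", "size"])

    def to_newick(self) -> str:
        """Serialize as Newick with branch lengths from merge-height differences."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.ids[node.id]}:{length:.10g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        root = f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"
        return root


def cluster_rows(data: QuantMatrix | pd.DataFrame, standardize: bool = False) -> Dendrogram:
    """UPGMA (average-linkage) clustering of rows on Euclidean distances.

    ``standardize`` z-scores each row first (common for expression heat maps).
    Rows with missing values are rejected; filter them before clustering.
    """
    frame = data.values if isinstance(data, QuantMatrix) else data
    x = frame.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise HeteroprotError("clustering needs at least 2 rows")
    if np.isnan(x).any():
        raise HeteroprotError(
            "matrix contains missing values; filter to complete rows before clustering"
        )
    if standardize:
        sd = x.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=1, keepdims=True)) / sd
    linkage = hierarchy.linkage(x, method="average", metric="euclidean")
    return Dendrogram(ids=tuple(map(str, frame.index)), linkage=linkage)
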