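"""Trait heterosis indices for a two-parent / F1-hybrid trio.

For a trait with hybrid mean F1 and parental means HP (high parent), MP
(mid-parent, the parental average) and LP (low parent):

    OPH (%) = (F1 - HP) / HP x 100      over-high-parent heterosis
    MPH (%) = (F1 - MP) / MP x 100      mid-parent heterosis
    BPH (%) = (F1 - LP) / LP x 100      below-low-parent heterosis

All three are scale-invariant and symmetric in the parents.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .deps import two_sample_test
from .errors import HeteroprotError, UndefinedIndexError


@dataclass(frozen=True)
class HeterosisResult:
    f1_mean: float
    hp: float
    lp: float
    mp: float
    oph_pct: float
    mph_pct: float
    bph_pct: float


def mid_parent(p1_mean: float, p2_mean: float) -> float:
    """Arithmetic mean of the two parental trait means."""
    if not (np.isfinite(p1_mean) and np.isfinite(p2_mean)):
        raise HeteroprotError("parent means must be finite")
    return (p1_mean + p2_mean) / 2.0


def heterosis_indices(f1_mean: float, p1_mean: float, p2_mean: float) -> HeterosisResult:
    """Compute OPH/MPH/BPH percentages from trio trait means."""
    hp = max(p1_mean, p2_mean)
    lp = min(p1_mean, p2_mean)
    mp = mid_parent(p1_mean, p2_mean)
    for name, denom in (("OPH", hp), ("MPH", mp), ("BPH", lp)):
        if denom == 0:
            raise UndefinedIndexError(f"{name} is undefined: its denominator is zero")
    return HeterosisResult(
        f1_mean=f1_mean,
        hp=hp,
        lp=lp,
        mp=mp,
        oph_pct=(f1_mean - hp) / hp * 100.0,
        mph_pct=(f1_mean - mp) / mp * 100.0,
        bph_pct=(f1_mean - lp) / lp * 100.0,
    )


def heterosis_from_table(
    traits: pd.DataFrame, female: str, male: str, hybrid: str
) -> HeterosisResult:
    """Aggregate a (genotype, replicate, value) table and compute the indices."""
    means = traits.groupby("genotype")["value"].mean()
    missing = [g for g in (female, male, hybrid) if g not in means.index]
    if missing:
        raise HeteroprotError(f"genotypes absent from trait table: {missing}")
    return heterosis_indices(means[hybrid], means[female], means[male])


def trait_significance(traits: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise two-sided pooled t-tests between all genotypes of a trait table.

    Returns one row per genotype pair with the t statistic, degrees of
    freedom, p-value and a significance flag at ``alpha``.
    """
    groups = {g: sub["value"].to_numpy(dtype=float) for g, sub in traits.groupby("genotype")}
    thin = [g for g, v in groups.items() if v.size < 2]
    if thin:
        raise HeteroprotError(f"genotypes with fewer than 2 replicates: {thin}")
    rows = []
    for a, b in combinations(sorted(groups), 2):
        t, df, p = two_sample_test(groups[a], groups[b])
        rows.append({"genotype_a": a, "genotype_b": b, "t_stat": t, "df": df,
                     "p_value": p, "significant": bool(p <= alpha)})
    return pd.DataFrame(rows)
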