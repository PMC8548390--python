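"""Inheritance-pattern classification of hybrid protein expression.

Each differentially expressed protein is labelled by where the hybrid's mean
abundance F1 sits relative to its parents' means: near the mid-parent value
MP (additive), near one parent (dominant: high- or low-parent), or outside
the parental range (over-/under-dominant).  The rules are fold-change
thresholds with a +/-10% band around them:

* additive            L < F1/MP < U                        (defaults L=0.67, U=1.5)
* over_dominant_up    F1/R_up  >= U*(1+b)                  (>= 1.65 by default)
* high_parent         U <= F1/R_up < U*(1+b)               ([1.5, 1.65))
* under_dominant      F1/R_dn  <= L*(1-b)                  (<= 0.603)
* low_parent          L*(1-b) < F1/R_dn <= L               ((0.603, 0.67])
* partial_nonadditive anything else (past the additive gate but in no band)

evaluated top to bottom.  In ``mode="literal"`` both band ratios are taken
against the high parent (R_up = R_dn = HP); ``mode="reconstructed"``
references the down-side bands to the low parent (R_dn = LP), the
biologically conventional reading in which "low-parent expression" means the
hybrid sits at the low parent's level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import pandas as pd

from .errors import HeteroprotError
from .io import QuantMatrix

LABELS = (
    "additive",
    "over_dominant_up",
    "high_parent",
    "under_dominant",
    "low_parent",
    "partial_nonadditive",
)

MODES = ("literal", "reconstructed")


def percentage(count: int, total: int, decimals: int = 2) -> float:
    """count/total x 100, rounded half-away-from-zero to ``decimals`` places."""
    if total <= 0:
        raise HeteroprotError("percentage denominator must be positive")
    if not 0 <= count <= total:
        raise HeteroprotError("count must lie in [0, total]")
    value = Decimal(count) * 100 / Decimal(total)
    return float(value.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PatternParams:
    """Thresholds of the rule table (fold-change cut points and band width)."""

    upper_threshold: float = 1.5
    lower_threshold: float = 0.67
    band: float = 0.10
    mode: str = "literal"

    def __post_init__(self) -> None:
        if not 0 < self.lower_threshold < 1 < self.upper_threshold:
            raise HeteroprotError("need 0 < lower_threshold < 1 < upper_threshold")
        if not 0 <= self.band < 1:
            raise HeteroprotError("band must lie in [0, 1)")
        if self.mode not in MODES:
            raise HeteroprotError(f"mode must be one of {MODES}")


@dataclass(frozen=True)
class PatternCall:
    protein_id: str
    r_mp: float
    r_hp: float
    r_lp: float
    label: str
    direction: str


@dataclass(frozen=True)
class PatternSummary:
    """Counts and rounded percentages per inheritance-pattern class.

    ``over_dominant`` aggregates the up- and down-regulated outside-parental
    classes (rule labels over_dominant_up and under_dominant); ``dominant``
    aggregates the high- and low-parent classes.  Ratio percentages are
    ``None`` when their denominator is zero.
    """

    n_additive: int
    n_overdominant_up: int
    n_overdominant_down: int
    n_dominant_high: int
    n_dominant_low: int
    n_partial: int
    n_nonadditive: int
    pct_nonadditive_of_classified: float | None
    pct_overdominant_of_nonadditive: float | None
    pct_dominant_of_nonadditive: float | None
    pct_overdominant_of_classified: float | None
    pct_up_of_overdominant: float | None

    @classmethod
    def from_counts(
        cls,
        n_additive: int,
        n_overdominant_up: int,
        n_overdominant_down: int,
        n_dominant_high: int,
        n_dominant_low: int,
        n_partial: int = 0,
    ) -> "PatternSummary":
        n_od = n_overdominant_up + n_overdominant_down
        n_dom = n_dominant_high + n_dominant_low
        n_nonadd = n_od + n_dom + n_partial
        n_classified = n_additive + n_nonadd

        def pct(count: int, total: int) -> float | None:
            return percentage(count, total, 1) if total > 0 else None

        return cls(
            n_additive=n_additive,
            n_overdominant_up=n_overdominant_up,
            n_overdominant_down=n_overdominant_down,
            n_dominant_high=n_dominant_high,
            n_dominant_low=n_dominant_low,
            n_partial=n_partial,
            n_nonadditive=n_nonadd,
            pct_nonadditive_of_classified=pct(n_nonadd, n_classified),
            pct_overdominant_of_nonadditive=pct(n_od, n_nonadd),
            pct_dominant_of_nonadditive=pct(n_dom, n_nonadd),
            pct_overdominant_of_classified=pct(n_od, n_classified),
            pct_up_of_overdominant=pct(n_overdominant_up, n_od),
        )


_DEFAULT_PARAMS = PatternParams()


def classify_protein(
    f1_mean: float,
    p1_mean: float,
    p2_mean: float,
    params: PatternParams = _DEFAULT_PARAMS,
    protein_id: str = "",
) -> PatternCall:
    """Label one protein from its hybrid and parent mean abundances.

    The rules are exhaustive and mutually exclusive for any positive input:
    exactly one label is returned.
    """
    if not (f1_mean > 0 and p1_mean > 0 and p2_mean > 0):
        raise HeteroprotError("all means must be strictly positive")
    hp = max(p1_mean, p2_mean)
    lp = min(p1_mean, p2_mean)
    mp = (p1_mean + p2_mean) / 2.0
    r_mp = f1_mean / mp
    r_hp = f1_mean / hp
    r_lp = f1_mean / lp
    upper = params.upper_threshold
    lower = params.lower_threshold
    up_cut = upper * (1.0 + params.band)
    dn_cut = lower * (1.0 - params.band)
    r_up = r_hp
    r_dn = r_hp if params.mode == "literal" else r_lp

    if lower < r_mp < upper:
        label, direction = "additive", "none"
    elif r_up >= up_cut:
        label, direction = "over_dominant_up", "up"
    elif upper <= r_up < up_cut:
        label, direction = "high_parent", "up"
    elif r_dn <= dn_cut:
        label, direction = "under_dominant", "down"
    elif dn_cut < r_dn <= lower:
        label, direction = "low_parent", "down"
    else:
        label = "partial_nonadditive"
        direction = "up" if r_mp >= upper else "down"
    return PatternCall(protein_id, r_mp, r_hp, r_lp, label, direction)


def classify_all(
    matrix: QuantMatrix,
    dep_ids: Iterable[str],
    params: PatternParams = _DEFAULT_PARAMS,
) -> list[PatternCall]:
    """Classify every listed DEP from its per-genotype replicate means."""
    dep_ids = list(dep_ids)
    known = set(matrix.protein_ids)
    missing = sorted(set(dep_ids) - known)
    if missing:
        raise HeteroprotError(f"protein ids not in the matrix: {missing}")
    means = matrix.role_means()
    calls = []
    for pid in dep_ids:
        row = means.loc[pid]
        calls.append(
            classify_protein(
                row["hybrid"], row["female_parent"], row["male_parent"],
                params=params, protein_id=pid,
            )
        )
    return calls


def summarize_patterns(calls: Sequence[PatternCall]) -> PatternSummary:
    """Tally pattern labels and the headline percentages of the classification."""
    if not calls:
        raise HeteroprotError("cannot summarize an empty classification")
    counts = {label: 0 for label in LABELS}
    for call in calls:
        counts[call.label] += 1
    return PatternSummary.from_counts(
        n_additive=counts["additive"],
        n_overdominant_up=counts["over_dominant_up"],
        n_overdominant_down=counts["under_dominant"],
        n_dominant_high=counts["high_parent"],
        n_dominant_low=counts["low_parent"],
        n_partial=counts["partial_nonadditive"],
    )


def calls_to_frame(calls: Sequence[PatternCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": c.protein_id,
                "r_mp": c.r_mp,
                "r_hp": c.r_hp,
                "r_lp": c.r_lp,
                "label": c.label,
                "direction": c.direction,
            }
            for c in calls
        ]
    )
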