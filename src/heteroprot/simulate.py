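"""Synthetic trio proteomics data with planted inheritance patterns.

The generator emulates the downstream shape of a DIA-style quantification
experiment on a female parent, a male parent and their F1 hybrid, each with a
small number of biological replicates.  For every protein it draws a base
abundance, decides whether the parents diverge (by ``parent_fold``), plants a
hybrid inheritance pattern, and multiplies every replicate observation by
lognormal noise ``exp(Normal(0, sigma))`` with ``sigma = sqrt(ln(1+cv^2))``,
so planted means are log-scale medians and ``cv`` is the per-replicate
coefficient of variation.

Planted hybrid levels, per pattern (HP/LP/MP are the parental medians):

* ``additive``        F1 = MP
* ``over_dominant``   F1 = 2.0  x HP   (upregulated, outside the parental range)
* ``high_parent``     F1 = 1.57 x HP   (dominant toward the high parent)
* ``under_dominant``  F1 = 0.45 x LP   (downregulated, outside the range)
* ``low_parent``      F1 = 0.636 x LP  (dominant toward the low parent)
* ``null``            parents equal, F1 = parents (no signal at all)

Down-side patterns are referenced to the low parent, the conventional
genetic reading (classification ``mode="reconstructed"`` recovers them; see
:mod:`heteroprot.patterns`).  Each protein gets its own counter-derived
random substream, so enlarging ``n_proteins`` never reshuffles earlier
proteins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import QuantMatrix, SampleDesign

PATTERNS = ("additive", "high_parent", "low_parent", "over_dominant", "under_dominant", "null")

#: Hybrid multipliers relative to the reference parent (HP for up-side patterns,
#: LP for down-side patterns, MP for additive).  Band patterns sit mid-interval
#: of their defining rule so classification is unambiguous at low noise.
DEFAULT_MULTIPLIERS: Mapping[str, float] = {
    "additive": 1.0,
    "over_dominant": 2.0,
    "high_parent": 1.57,
    "low_parent": 0.636,
    "under_dominant": 0.45,
    "null": 1.0,
}

#: Default planted-pattern proportions.  Over-dominant patterns dominate the
#: non-additive signal (as in heterotic crosses); the two dominant classes are
#: kept a modest fraction because their defining fold-change bands are only
#: ~10% wide, which bounds how sharply any classifier can separate them from
#: their neighbours once replicate noise is present.
DEFAULT_PATTERN_MIX: Mapping[str, float] = {
    "null": 0.30,
    "additive": 0.14,
    "over_dominant": 0.32,
    "under_dominant": 0.14,
    "high_parent": 0.07,
    "low_parent": 0.03,
}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated trio experiment."""

    n_proteins: int = 2000
    n_replicates: int = 3
    parent_fold: float = 2.0
    pattern_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PATTERN_MIX))
    cv: float = 0.10
    seed: int = 0
    base_median: float = 1000.0
    base_log_sd: float = 1.0
    multipliers: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MULTIPLIERS))

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.n_replicates < 1:
            raise ConfigError("n_proteins and n_replicates must be positive")
        if self.parent_fold <= 1:
            raise ConfigError("parent_fold must exceed 1")
        if self.cv < 0:
            raise ConfigError("cv must be non-negative")
        unknown = sorted(set(self.pattern_mix) - set(PATTERNS))
        if unknown:
            raise ConfigError(f"unknown patterns in mix: {unknown}")
        total = sum(self.pattern_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"pattern_mix must sum to 1 (got {total!r})")


def _noise_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def _protein_rng(seed: int, index: int) -> np.random.Generator:
    # counter-derived substream: stable per protein index for a given seed
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, index]))


def _trio_design(n_replicates: int) -> SampleDesign:
    rows = []
    for genotype, role in (("P1", "female_parent"), ("P2", "male_parent"), ("F1", "hybrid")):
        for rep in range(1, n_replicates + 1):
            rows.append({"sample_id": f"{genotype}_r{rep}", "genotype": genotype,
                         "role": role, "replicate": rep})
    return SampleDesign(pd.DataFrame(rows))


def simulate_quant(config: SimConfig) -> tuple[QuantMatrix, pd.DataFrame]:
    """Simulate a quantification matrix and the truth table of planted patterns.

    Returns the matrix plus a DataFrame with columns ``protein_id``,
    ``true_pattern`` and the exact planted median ratios ``f1_over_mp``,
    ``f1_over_hp`` and ``f1_over_lp``.
    """
    design = _trio_design(config.n_replicates)
    sigma = _noise_sigma(config.cv)
    labels = list(config.pattern_mix)
    probs = np.array([config.pattern_mix[k] for k in labels], dtype=float)
    cum = np.cumsum(probs)

    ids, truth_rows, values = [], [], []
    width = max(6, len(str(config.n_proteins)))
    for i in range(config.n_proteins):
        rng = _protein_rng(config.seed, i)
        pattern = labels[int(np.searchsorted(cum, rng.random(), side="right").clip(0, len(labels) - 1))]
        base = config.base_median * math.exp(config.base_log_sd * rng.standard_normal())
        if pattern == "null":
            p1 = p2 = base
        else:
            high_is_female = rng.random() < 0.5
            lo, hi = base, base * config.parent_fold
            p1, p2 = (hi, lo) if high_is_female else (lo, hi)
        hp, lp, mp = max(p1, p2), min(p1, p2), (p1 + p2) / 2.0
        mult = config.multipliers[pattern]
        if pattern in ("additive", "null"):
            f1 = mult * mp
        elif pattern in ("over_dominant", "high_parent"):
            f1 = mult * hp
        else:
            f1 = mult * lp

        medians = np.repeat([p1, p2, f1], config.n_replicates)
        noise = np.exp(sigma * rng.standard_normal(medians.size)) if sigma > 0 else 1.0
        values.append(medians * noise)
        pid = f"P{i:0{width}d}"
        ids.append(pid)
        truth_rows.append({
            "protein_id": pid,
            "true_pattern": pattern,
            "f1_over_mp": f1 / mp,
            "f1_over_hp": f1 / hp,
            "f1_over_lp": f1 / lp,
        })

    columns = design.sample_ids  # P1 reps, P2 reps, F1 reps — matches np.repeat order
    matrix = QuantMatrix(pd.DataFrame(np.asarray(values), index=ids, columns=columns), design)
    return matrix, pd.DataFrame(truth_rows)


def simulate_trait(
    genotype_means: Mapping[str, float],
    cv: float,
    n_replicates: int,
    seed: int,
) -> pd.DataFrame:
    """Simulate a trait table (genotype, replicate, value) with lognormal noise."""
    if n_replicates < 1:
        raise ConfigError("n_replicates must be positive")
    if cv < 0:
        raise ConfigError("cv must be non-negative")
    for genotype, mean in genotype_means.items():
        if not mean > 0:
            raise ConfigError(f"trait mean for {genotype!r} must be positive")
    sigma = _noise_sigma(cv)
    rng = np.random.default_rng(seed)
    rows = []
    for genotype, mean in genotype_means.items():
        noise = np.exp(sigma * rng.standard_normal(n_replicates)) if sigma > 0 else np.ones(n_replicates)
        for rep in range(1, n_replicates + 1):
            rows.append({"genotype": genotype, "replicate": rep, "value": mean * noise[rep - 1]})
    return pd.DataFrame(rows)
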