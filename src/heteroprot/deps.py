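"""Differential-protein calling between genotype roles of the trio.

Each protein is tested with a two-sided pooled-variance Student t-test on
log2 abundances (the transform is standard for intensity data and makes the
lognormal noise model exactly normal); fold changes are always reported on
the raw scale.  Raw p-values are Benjamini-Hochberg adjusted across the
tested proteins of a comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DesignError, HeteroprotError
from .io import ROLES, QuantMatrix
from .patterns import percentage

logger = logging.getLogger(__name__)

DEP_COLUMNS = [
    "protein_id", "comparison", "fc", "log2fc", "t_stat", "df",
    "p_raw", "p_adj", "direction", "significant",
]


@dataclass(frozen=True)
class ComparisonSummary:
    """Up/down/total DEP counts of one comparison, as fractions of the quantified set."""

    comparison: str
    n_up: int
    n_down: int
    n_total: int
    n_quantified: int
    pct_up: float
    pct_down: float
    pct_total: float

    @classmethod
    def from_counts(cls, comparison: str, n_up: int, n_down: int, n_quantified: int) -> "ComparisonSummary":
        n_total = n_up + n_down
        return cls(
            comparison=comparison,
            n_up=n_up,
            n_down=n_down,
            n_total=n_total,
            n_quantified=n_quantified,
            pct_up=percentage(n_up, n_quantified, 2),
            pct_down=percentage(n_down, n_quantified, 2),
            pct_total=percentage(n_total, n_quantified, 2),
        )


def _pooled_t(ma, mb, va, vb, na, nb):
    """Vectorized pooled-variance two-sample t with zero-variance handling."""
    df = na + nb - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        t = (ma - mb) / se
        diff = ma - mb
        zero_se = se == 0
        t = np.where(zero_se & (diff == 0), 0.0, t)
        t = np.where(zero_se & (diff != 0), np.sign(diff) * np.inf, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    return t, df, np.clip(p, 0.0, 1.0)


def two_sample_test(a, b) -> tuple[float, int, float]:
    """Two-sided pooled-variance Student t-test; returns (t, df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise HeteroprotError("each group needs at least 2 finite values")
    t, df, p = _pooled_t(a.mean(), b.mean(), a.var(ddof=1), b.var(ddof=1), a.size, b.size)
    return float(t), int(df), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise HeteroprotError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_deps(
    matrix: QuantMatrix,
    comparison: tuple[str, str],
    alpha: float = 0.05,
    use_fdr: bool = True,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Test every protein between two genotype roles.

    ``comparison`` is an ordered (test, reference) pair of roles; "up" means
    higher in the test role.  Proteins with fewer than two observed
    replicates in either group are skipped (and logged), not errors.
    Returns a DataFrame with one row per testable protein
    (columns :data:`DEP_COLUMNS`).
    """
    test_role, ref_role = comparison
    for role in comparison:
        if role not in ROLES:
            raise DesignError(f"unknown role {role!r}; expected one of {ROLES}")
    label = f"{matrix.design.genotype_of(test_role)}-VS-{matrix.design.genotype_of(ref_role)}"

    raw_a = matrix.role_values(test_role).to_numpy(dtype=float)
    raw_b = matrix.role_values(ref_role).to_numpy(dtype=float)
    na = np.sum(np.isfinite(raw_a), axis=1)
    nb = np.sum(np.isfinite(raw_b), axis=1)
    testable = (na >= 2) & (nb >= 2)
    skipped = np.asarray(matrix.protein_ids)[~testable]
    if skipped.size:
        logger.info(
            "%s: skipped %d protein(s) with <2 observed replicates in a group: %s",
            label, skipped.size, ", ".join(skipped[:10]) + ("..." if skipped.size > 10 else ""),
        )

    ids = np.asarray(matrix.protein_ids)[testable]
    raw_a, raw_b = raw_a[testable], raw_b[testable]
    na, nb = na[testable], nb[testable]
    ta = np.log2(raw_a) if log_transform else raw_a
    tb = np.log2(raw_b) if log_transform else raw_b
    ma, mb = np.nanmean(ta, axis=1), np.nanmean(tb, axis=1)
    va, vb = np.nanvar(ta, axis=1, ddof=1), np.nanvar(tb, axis=1, ddof=1)
    t, df, p_raw = _pooled_t(ma, mb, va, vb, na, nb)
    p_adj = bh_adjust(p_raw) if p_raw.size else p_raw

    fc = np.nanmean(raw_a, axis=1) / np.nanmean(raw_b, axis=1)  # raw scale always
    chosen = p_adj if use_fdr else p_raw
    return pd.DataFrame({
        "protein_id": ids,
        "comparison": label,
        "fc": fc,
        "log2fc": np.log2(fc),
        "t_stat": t,
        "df": df,
        "p_raw": p_raw,
        "p_adj": p_adj,
        "direction": np.where(fc > 1, "up", "down"),
        "significant": chosen <= alpha,
    })


def significant_ids(records: pd.DataFrame) -> set[str]:
    return set(records.loc[records["significant"], "protein_id"])


def summarize_comparison(records: pd.DataFrame, n_quantified: int) -> ComparisonSummary:
    """Tally significant up/down calls of one comparison against the quantified total."""
    if n_quantified <= 0:
        raise HeteroprotError("n_quantified must be positive")
    labels = records["comparison"].unique() if len(records) else np.array(["?"])
    if len(labels) > 1:
        raise HeteroprotError("records mix multiple comparisons")
    sig = records[records["significant"]] if len(records) else records
    n_up = int((sig["direction"] == "up").sum()) if len(sig) else 0
    n_down = int((sig["direction"] == "down").sum()) if len(sig) else 0
    return ComparisonSummary.from_counts(str(labels[0]), n_up, n_down, n_quantified)
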