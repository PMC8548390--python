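"""Relative expression from qPCR cycle thresholds by the Livak 2^-ddCt method.

Per genotype, dCt = mean(Ct_target) - mean(Ct_reference) over replicates
(averaging on the Ct scale before exponentiation); ddCt subtracts the
calibrator's dCt, which may be a named genotype or the mid-parent value
(the mean of the two parents' dCt).  Relative expression is 2^-ddCt, so the
calibrator itself always maps to exactly 1.0.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .errors import HeteroprotError

MID_PARENT = "mid_parent"


def ddct_relative_expression(
    ct: pd.DataFrame,
    gene: str,
    organ: str,
    calibrator: str = MID_PARENT,
    parents: tuple[str, str] | None = None,
) -> dict[str, float]:
    """2^-ddCt relative expression per genotype for one gene in one organ.

    ``calibrator`` is either a genotype name present in the table or
    ``"mid_parent"``, in which case ``parents`` must name the two parental
    genotypes.
    """
    sub = ct[(ct["gene"] == gene) & (ct["organ"] == organ)]
    if sub.empty:
        raise HeteroprotError(f"no Ct rows for gene {gene!r} in organ {organ!r}")
    means = sub.groupby("genotype")[["ct_target", "ct_reference"]].mean()
    dct = (means["ct_target"] - means["ct_reference"]).to_dict()
    if calibrator == MID_PARENT:
        if parents is None:
            raise HeteroprotError("calibrator='mid_parent' requires the parents argument")
        missing = [p for p in parents if p not in dct]
        if missing:
            raise HeteroprotError(f"parent genotypes absent from Ct table: {missing}")
        cal_dct = (dct[parents[0]] + dct[parents[1]]) / 2.0
    else:
        if calibrator not in dct:
            raise HeteroprotError(f"calibrator genotype {calibrator!r} absent from Ct table")
        cal_dct = dct[calibrator]
    return {genotype: 2.0 ** -(value - cal_dct) for genotype, value in dct.items()}
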