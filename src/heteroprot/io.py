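"""Reading, validation and writing of the pipeline's tabular inputs and outputs.

The pipeline starts from a quantified protein matrix (proteins x samples,
positive intensities, missing allowed) plus a sample map assigning every
sample column to one genotype of a trio design: a female parent, a male
parent and their F1 hybrid, each with replicate numbers.  Everything here is
plain delimited text; the delimiter is taken from the file extension
(``.tsv`` -> tab, ``.csv`` -> comma, anything else -> tab).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError, HeteroprotError

ROLES = ("female_parent", "male_parent", "hybrid")

_DESIGN_COLUMNS = ["sample_id", "genotype", "role", "replicate"]


def _delimiter(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


@dataclass(frozen=True)
class SampleDesign:
    """Assignment of each sample to a genotype role of the trio design.

    ``table`` has columns ``sample_id``, ``genotype``, ``role`` (one of
    :data:`ROLES`) and ``replicate`` (positive integer).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in _DESIGN_COLUMNS if c not in t.columns]
        if missing:
            raise FormatError(f"sample map is missing columns: {missing}")
        bad_roles = sorted(set(t["role"]) - set(ROLES))
        if bad_roles:
            raise DesignError(f"unknown roles in sample map: {bad_roles}")
        absent = sorted(set(ROLES) - set(t["role"]))
        if absent:
            raise DesignError(f"trio design requires all roles; missing: {absent}")
        if t["sample_id"].duplicated().any():
            raise DesignError("duplicate sample_id in sample map")
        if t.duplicated(subset=["genotype", "replicate"]).any():
            raise DesignError("(genotype, replicate) pairs must be unique")
        for role, group in t.groupby("role"):
            if group["genotype"].nunique() != 1:
                raise DesignError(f"role {role!r} maps to more than one genotype")
        if (t["replicate"].astype(int) < 1).any():
            raise DesignError("replicate indices must be positive integers")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def genotype_of(self, role: str) -> str:
        self._check_role(role)
        return str(self.table.loc[self.table["role"] == role, "genotype"].iloc[0])

    def samples_for(self, role: str) -> list[str]:
        self._check_role(role)
        sub = self.table[self.table["role"] == role]
        return list(sub.sort_values("replicate")["sample_id"])

    def _check_role(self, role: str) -> None:
        if role not in ROLES:
            raise DesignError(f"unknown role {role!r}; expected one of {ROLES}")


@dataclass(frozen=True)
class QuantMatrix:
    """Protein abundance matrix with the trio design attached.

    ``values`` is indexed by protein id with one column per sample; observed
    entries are strictly positive, missing entries are NaN.
    """

    values: pd.DataFrame
    design: SampleDesign

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = sorted(set(self.values.index[self.values.index.duplicated()]))
            raise FormatError(f"duplicate protein ids: {dup}")
        design_samples = set(self.design.sample_ids)
        matrix_samples = set(map(str, self.values.columns))
        extra = sorted(matrix_samples - design_samples)
        if extra:
            raise DesignError(f"sample columns absent from the sample map: {extra}")
        absent = sorted(design_samples - matrix_samples)
        if absent:
            raise DesignError(f"sample map rows without a matrix column: {absent}")
        vals = self.values.to_numpy(dtype=float)
        observed = ~np.isnan(vals)
        if not (vals[observed] > 0).all():
            raise HeteroprotError("observed abundances must be strictly positive")

    @property
    def protein_ids(self) -> list[str]:
        return list(map(str, self.values.index))

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    def role_values(self, role: str) -> pd.DataFrame:
        """Replicate columns for one genotype role, in replicate order."""
        return self.values[self.design.samples_for(role)]

    def role_means(self) -> pd.DataFrame:
        """Per-protein arithmetic mean of observed replicates, one column per role."""
        return pd.DataFrame(
            {role: self.role_values(role).mean(axis=1, skipna=True) for role in ROLES}
        )

    def complete_cases(self) -> "QuantMatrix":
        """Restrict to proteins observed in every sample (the jointly quantified set)."""
        keep = self.values.notna().all(axis=1)
        return QuantMatrix(self.values.loc[keep], self.design)

    def canonical(self) -> "QuantMatrix":
        """Sort rows by protein id and columns by sample id (order-free comparisons)."""
        vals = self.values.sort_index()
        vals = vals[sorted(vals.columns)]
        design = SampleDesign(
            self.design.table.sort_values("sample_id").reset_index(drop=True)
        )
        return QuantMatrix(vals, design)


def read_sample_map(path: str | Path) -> SampleDesign:
    table = pd.read_csv(path, sep=_delimiter(path), dtype={"sample_id": str, "genotype": str, "role": str})
    return SampleDesign(table)


def read_quant_table(path: str | Path, design_path: str | Path) -> QuantMatrix:
    """Read a protein x sample abundance table plus its sample map.

    The quant file's header row holds sample ids and its first column holds
    protein ids.  Empty cells and ``NA`` are kept as missing values.  The
    result is in canonical order (rows sorted by protein id, columns by
    sample id) so that row/column permutations of the file are equivalent.
    """
    design = read_sample_map(design_path)
    table = pd.read_csv(
        path, sep=_delimiter(path), index_col=0, na_values=["NA", ""], keep_default_na=True
    )
    table.index = table.index.astype(str)
    table.index.name = None
    table.columns = table.columns.astype(str)
    return QuantMatrix(table.astype(float), design).canonical()


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read a trait measurement table with columns genotype, replicate, value."""
    table = pd.read_csv(path, sep=_delimiter(path))
    required = ["genotype", "replicate", "value"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"trait table is missing columns: {missing}")
    if not np.isfinite(table["value"].to_numpy(dtype=float)).all():
        raise HeteroprotError("trait values must be finite")
    return table[required]


def read_term_map(path: str | Path) -> pd.DataFrame:
    """Read a two-column protein -> term annotation table."""
    table = pd.read_csv(path, sep=_delimiter(path), dtype=str)
    if table.shape[1] < 2:
        raise FormatError("term map needs two columns: protein_id, term_id")
    table = table.iloc[:, :2]
    table.columns = ["protein_id", "term_id"]
    return table


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR Ct table: gene, genotype, organ, replicate, ct_target, ct_reference."""
    table = pd.read_csv(path, sep=_delimiter(path))
    required = ["gene", "genotype", "organ", "replicate", "ct_target", "ct_reference"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"Ct table is missing columns: {missing}")
    cts = table[["ct_target", "ct_reference"]].to_numpy(dtype=float)
    if not (np.isfinite(cts).all() and (cts > 0).all()):
        raise HeteroprotError("Ct values must be positive and finite")
    return table[required]


def _as_dataframe(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    records = list(records)
    if records and dataclasses.is_dataclass(records[0]):
        return pd.DataFrame([dataclasses.asdict(r) for r in records])
    return pd.DataFrame(records)


def write_records(records, path: str | Path, format: str = "tsv") -> None:
    """Write any tabular result (DataFrame or dataclass list) as TSV or JSON.

    Numeric fields survive a read-back via :func:`read_records` to full float
    precision (pandas writes shortest round-trip representations).
    """
    frame = _as_dataframe(records)
    path = Path(path)
    if format == "tsv":
        frame.to_csv(path, sep="\t", index=False)
    elif format == "json":
        path.write_text(json.dumps(frame.to_dict(orient="records"), indent=1) + "\n")
    else:
        raise FormatError(f"unknown output format {format!r}; use 'tsv' or 'json'")


def read_records(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read back a table produced by :func:`write_records`."""
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        return pd.DataFrame(json.loads(Path(path).read_text()))
    raise FormatError(f"unknown input format {format!r}; use 'tsv' or 'json'")


def write_quant_table(matrix: QuantMatrix, quant_path: str | Path, design_path: str | Path) -> None:
    """Write a QuantMatrix as the pair of files ``read_quant_table`` consumes."""
    matrix.values.to_csv(quant_path, sep=_delimiter(quant_path), index_label="protein_id")
    matrix.design.table.to_csv(design_path, sep=_delimiter(design_path), index=False)
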