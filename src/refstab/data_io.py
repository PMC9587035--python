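"""Data model and I/O for RT-qPCR Cq tables.

The central container is :class:`CqTable`: a genes x samples matrix of
quantification-cycle (Cq) values together with per-sample metadata
(postnatal day, developmental stage, sex, FiO2, RNA integrity number and
PCR plate).  Non-detects are represented as missing values (``NaN``),
never as an imputed ceiling Cq.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "EmptySelectionError",
    "CqTable",
    "GroupDesign",
    "read_cq_table",
    "write_cq_table",
    "filter_samples",
    "drop_undetected_genes",
]

#: strings in a Cq export that denote a non-detect / missing measurement
SENTINELS = {"", "na", "nan", "n/a", "undetermined", "undet", "no cq", "-"}

#: recognised per-sample metadata fields and their dtypes
META_FIELDS = {
    "pnd": float,
    "stage": str,
    "sex": str,
    "fio2": float,
    "rin": float,
    "plate": str,
}

CQ_MIN, CQ_MAX = 0.0, 45.0


class ValidationError(ValueError):
    """Raised when a table violates the data-model invariants."""


class EmptySelectionError(ValueError):
    """Raised when a sample filter matches nothing (analyses need n >= 2)."""


@dataclass
class CqTable:
    """Genes x samples Cq matrix plus per-sample metadata.

    Parameters
    ----------
    cq
        DataFrame indexed by gene symbol with sample IDs as columns.
        Missing entries (``NaN``) are non-detects.
    meta
        DataFrame indexed by sample ID with (a subset of) the columns
        ``pnd, stage, sex, fio2, rin, plate``.  ``plate`` is mandatory.
    """

    cq: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.cq = self.cq.astype(float)
        if self.cq.index.duplicated().any():
            dup = self.cq.index[self.cq.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene IDs: {dup}")
        if self.cq.columns.duplicated().any():
            dup = self.cq.columns[self.cq.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dup}")
        if "plate" not in self.meta.columns:
            raise ValidationError("metadata is missing the required column 'plate'")
        missing_meta = [s for s in self.cq.columns if s not in self.meta.index]
        if missing_meta:
            raise ValidationError(f"samples without metadata: {missing_meta}")
        self.meta = self.meta.loc[list(self.cq.columns)]
        if self.meta["plate"].isna().any():
            bad = self.meta.index[self.meta["plate"].isna()].tolist()
            raise ValidationError(f"samples without a plate ID: {bad}")
        vals = self.cq.to_numpy(float)
        observed = ~np.isnan(vals)
        if np.any(~np.isfinite(vals) & observed):
            raise ValidationError("non-finite Cq values present")
        if np.any((vals[observed] <= CQ_MIN) | (vals[observed] >= CQ_MAX)):
            raise ValidationError(
                f"Cq values outside ({CQ_MIN}, {CQ_MAX}) present"
            )

    # -- convenience -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.cq.index)

    @property
    def samples(self) -> list[str]:
        return list(self.cq.columns)

    @property
    def n_missing(self) -> int:
        return int(self.cq.isna().sum().sum())

    def subset_samples(self, samples: Sequence[str]) -> "CqTable":
        samples = list(samples)
        unknown = [s for s in samples if s not in self.cq.columns]
        if unknown:
            raise ValidationError(f"unknown samples: {unknown}")
        return CqTable(self.cq[samples].copy(), self.meta.loc[samples].copy())

    def subset_genes(self, genes: Sequence[str]) -> "CqTable":
        genes = list(genes)
        unknown = [g for g in genes if g not in self.cq.index]
        if unknown:
            raise ValidationError(f"unknown genes: {unknown}")
        return CqTable(self.cq.loc[genes].copy(), self.meta.copy())


@dataclass
class GroupDesign:
    """Named assignment of samples to disjoint groups.

    Every group needs at least two samples because the grouped stability
    analyses estimate a within-group variance.
    """

    name: str
    groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = list(self.groups)
        if len(set(labels)) != len(labels):
            raise ValidationError("group labels must be unique")
        seen: dict[str, str] = {}
        for label, members in self.groups.items():
            if len(members) < 2:
                raise ValidationError(
                    f"group {label!r} has {len(members)} sample(s); need >= 2"
                )
            for s in members:
                if s in seen:
                    raise ValidationError(
                        f"sample {s!r} appears in groups {seen[s]!r} and {label!r}"
                    )
                seen[s] = label

    @property
    def labels(self) -> list[str]:
        return list(self.groups)

    @property
    def sizes(self) -> dict[str, int]:
        return {g: len(m) for g, m in self.groups.items()}

    @property
    def all_samples(self) -> list[str]:
        return [s for members in self.groups.values() for s in members]

    @classmethod
    def from_metadata(
        cls, table: CqTable, column: str, name: str | None = None
    ) -> "GroupDesign":
        """Build a design from a categorical metadata column."""
        if column not in table.meta.columns:
            raise ValidationError(f"unknown metadata column {column!r}")
        groups = {
            str(level): list(idx)
            for level, idx in table.meta.groupby(column, sort=True).groups.items()
        }
        return cls(name or column, groups)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _to_float(x) -> float:
    if isinstance(x, str) and x.strip().lower() in SENTINELS:
        return np.nan
    try:
        return float(x)
    except (TypeError, ValueError):
        return np.nan


def read_cq_table(
    path: str | Path,
    *,
    meta: str | Path | pd.DataFrame | None = None,
    orientation: str = "genes_by_samples",
    sep: str | None = None,
) -> CqTable:
    """Read a Cq table from CSV/TSV.

    ``orientation`` is ``"genes_by_samples"`` (genes as rows, the common
    qPCR export layout) or ``"samples_by_genes"`` for the transpose.
    Sample metadata may be embedded as extra columns of a
    samples-by-genes file or supplied as a sidecar CSV (``meta``) keyed
    by sample ID.  Sentinel cells ("Undetermined", "NA", empty, any
    non-numeric text) become missing.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if orientation == "samples_by_genes":
        meta_cols = [c for c in raw.columns if c.lower() in META_FIELDS]
        embedded = raw[meta_cols].rename(columns=str.lower) if meta_cols else None
        raw = raw.drop(columns=meta_cols).T
    elif orientation == "genes_by_samples":
        embedded = None
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    cq = raw.map(_to_float)
    cq.index = cq.index.astype(str)
    cq.columns = cq.columns.astype(str)

    if isinstance(meta, (str, Path)):
        meta = pd.read_csv(meta, index_col=0)
        meta.index = meta.index.astype(str)
        meta.columns = [c.lower() for c in meta.columns]
    if meta is None:
        if embedded is None:
            raise ValidationError(
                "no sample metadata: supply a sidecar file via meta= "
                "(a 'plate' column is required)"
            )
        meta = embedded
    meta = meta.copy()
    for col, typ in META_FIELDS.items():
        if col in meta.columns and typ is float:
            meta[col] = pd.to_numeric(meta[col], errors="coerce")
    return CqTable(cq, meta)


def write_cq_table(
    table: CqTable, path: str | Path, meta_path: str | Path | None = None
) -> None:
    """Write a CqTable as CSV (genes x samples) plus a metadata sidecar."""
    path = Path(path)
    table.cq.to_csv(path, index_label="gene")
    if meta_path is None:
        meta_path = path.with_name(path.stem + ".meta.csv")
    table.meta.to_csv(meta_path, index_label="sample")


def write_run_manifest(path: str | Path, **entries) -> None:
    """Serialize run parameters/outputs as a small JSON manifest."""
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True, default=str)


# ---------------------------------------------------------------------------
# sample / gene filtering
# ---------------------------------------------------------------------------

_OPS = {
    ">": lambda s, v: s > v,
    ">=": lambda s, v: s >= v,
    "<": lambda s, v: s < v,
    "<=": lambda s, v: s <= v,
    "==": lambda s, v: s == v,
    "!=": lambda s, v: s != v,
    "in": lambda s, v: s.isin(v),
    "between": lambda s, v: (s >= v[0]) & (s <= v[1]),
}


def filter_samples(table: CqTable, predicate: Mapping[str, object]) -> CqTable:
    """Select samples whose metadata satisfies *all* conditions.

    ``predicate`` maps a metadata field to either a scalar (equality),
    a ``(op, value)`` tuple with op in ``> >= < <= == != in between``,
    or a list of such tuples (conjunction).  Example::

        filter_samples(t, {"fio2": 0.21, "rin": (">", 5),
                           "pnd": ("between", (2.5, 28.5))})
    """
    mask = pd.Series(True, index=table.meta.index)
    for field_name, cond in predicate.items():
        if field_name not in table.meta.columns:
            raise ValidationError(f"unknown metadata field {field_name!r}")
        col = table.meta[field_name]
        conds = cond if isinstance(cond, list) else [cond]
        for c in conds:
            if isinstance(c, tuple):
                op, value = c
                if op not in _OPS:
                    raise ValidationError(f"unknown operator {op!r}")
                mask &= _OPS[op](col, value)
            else:
                mask &= col == c
    selected = list(table.meta.index[mask])
    if not selected:
        raise EmptySelectionError(f"predicate {predicate!r} matches no sample")
    return table.subset_samples(selected)


def drop_undetected_genes(
    table: CqTable, max_missing: int = 0
) -> tuple[CqTable, pd.DataFrame]:
    """Remove genes whose non-detect count exceeds ``max_missing``.

    Mirrors the exclusion of a candidate that produced no measurable Cq
    in several samples.  Returns the reduced table and a report listing
    each removed gene with its missing count, e.g. ``"6/60"``.
    """
    if max_missing < 0:
        raise ValueError("max_missing must be >= 0")
    n_samples = len(table.samples)
    n_missing = table.cq.isna().sum(axis=1)
    removed = n_missing[n_missing > max_missing]
    report = pd.DataFrame(
        {
            "gene": removed.index,
            "n_missing": removed.to_numpy(int),
            "n_samples": n_samples,
            "fraction": [f"{int(m)}/{n_samples}" for m in removed],
        }
    ).reset_index(drop=True)
    kept = [g for g in table.genes if g not in set(removed.index)]
    out = CqTable(table.cq.loc[kept].copy(), table.meta.copy())
    return out, report
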