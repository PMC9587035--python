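"""Microarray expression-matrix preparation.

Prepares an intra-slide-normalized intensity matrix (probes x arrays)
for downstream candidate confirmation: quality filtering, replicate
averaging, sequential KNN imputation of remaining holes, quantile
normalization and log2 transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "qc_filter",
    "average_replicates",
    "seq_knn_impute",
    "quantile_normalize",
    "log2_transform",
]


@dataclass
class ExpressionMatrix:
    """Probes/genes x arrays intensity matrix.

    ``flags`` marks probes failing vendor quality flags, ``is_control``
    marks control probes; both are optional boolean Series indexed like
    ``values``.  ``is_log2`` records whether values are log2 scale.
    """

    values: pd.DataFrame
    flags: pd.Series | None = None
    is_control: pd.Series | None = None
    is_log2: bool = False

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        for name in ("flags", "is_control"):
            s = getattr(self, name)
            if s is not None:
                setattr(self, name, s.reindex(self.values.index).fillna(False).astype(bool))

    @property
    def missing_fraction(self) -> pd.Series:
        return self.values.isna().mean(axis=1)

    def subset(self, probes) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[probes].copy(),
            None if self.flags is None else self.flags.loc[probes],
            None if self.is_control is None else self.is_control.loc[probes],
            self.is_log2,
        )


def qc_filter(
    m: ExpressionMatrix, max_missing_frac: float = 0.5
) -> tuple[ExpressionMatrix, dict]:
    """Remove control probes, quality-flagged probes and probes with a
    missing-value fraction >= ``max_missing_frac``.

    Returns the filtered matrix and a report counting removals per
    category (a probe is counted once, in the first category it hits).
    """
    report = {"control": 0, "flagged": 0, "high_missing": 0, "kept": 0}
    if m.flags is None:
        report["warning"] = "no quality flags supplied; flag filter skipped"
    keep = []
    miss = m.missing_fraction
    for probe in m.values.index:
        if m.is_control is not None and bool(m.is_control.loc[probe]):
            report["control"] += 1
        elif m.flags is not None and bool(m.flags.loc[probe]):
            report["flagged"] += 1
        elif miss.loc[probe] >= max_missing_frac:
            report["high_missing"] += 1
        else:
            keep.append(probe)
    report["kept"] = len(keep)
    return m.subset(keep), report


def average_replicates(
    m: ExpressionMatrix, replicate_map: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse replicate probes to their per-array mean, ignoring
    missing values (a collapsed cell is missing only if all replicates
    are missing).  ``replicate_map`` maps probe ID -> group label;
    unmapped probes keep their own ID as the group."""
    unknown = [p for p in replicate_map if p not in m.values.index]
    if unknown:
        raise KeyError(f"replicate map names unknown probes: {unknown}")
    groups = [replicate_map.get(p, p) for p in m.values.index]
    collapsed = m.values.groupby(pd.Index(groups, name=m.values.index.name)).mean()
    return ExpressionMatrix(collapsed, None, None, m.is_log2)


def seq_knn_impute(m: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Sequential KNN imputation.

    Probes are imputed in order of ascending missingness.  Each missing
    entry becomes the Euclidean-distance-weighted mean (weights 1/d over
    the mutually observed arrays, distances scaled to per-column terms)
    of the k nearest probes that are already complete; an imputed probe
    immediately joins the donor pool — the "sequential" rule.  A donor
    at distance zero is copied exactly.
    """
    vals = m.values.to_numpy(float).copy()
    n_probes, n_arrays = vals.shape
    missing = np.isnan(vals)
    complete = ~missing.any(axis=1)
    if not complete.any() and missing.any():
        raise ValueError("sequential KNN needs at least one complete probe")
    n_miss = missing.sum(axis=1)
    order = [i for i in np.argsort(n_miss, kind="stable") if n_miss[i] > 0]
    donor = list(np.flatnonzero(complete))
    for i in order:
        obs = ~missing[i]
        donors = np.array(donor, dtype=int)
        if donors.size == 0:
            raise ValueError("no donor probes available")
        diff = vals[donors][:, obs] - vals[i, obs]
        # mean squared difference over mutually observed arrays keeps
        # distances comparable across probes with different missingness
        d = np.sqrt(np.mean(diff**2, axis=1))
        kk = min(k, donors.size)
        nearest = np.argsort(d, kind="stable")[:kk]
        nd = d[nearest]
        ndon = donors[nearest]
        if np.any(nd == 0):
            w = (nd == 0).astype(float)
        else:
            w = 1.0 / nd
        w = w / w.sum()
        fill = w @ vals[ndon]
        vals[i, missing[i]] = fill[missing[i]]
        missing[i] = False
        donor.append(i)
    out = pd.DataFrame(vals, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(out, m.flags, m.is_control, m.is_log2)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile normalization: every array's sorted values are replaced
    by the across-array mean of sorted values.  Ties within an array
    receive the mean of their target quantile values (average ranks with
    linear interpolation, the limma convention)."""
    vals = m.values.to_numpy(float)
    if np.isnan(vals).any():
        raise ValueError("matrix contains missing values; impute first")
    n = vals.shape[0]
    mean_sorted = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    positions = np.arange(1, n + 1, dtype=float)
    from scipy.stats import rankdata

    for j in range(vals.shape[1]):
        ranks = rankdata(vals[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, mean_sorted)
    df = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(df, m.flags, m.is_control, m.is_log2)


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Element-wise log2; requires strictly positive intensities."""
    vals = m.values.to_numpy(float)
    bad = np.asarray(~np.isnan(vals) & (vals <= 0)).nonzero()
    if bad[0].size:
        probe = m.values.index[bad[0][0]]
        array = m.values.columns[bad[1][0]]
        raise ValueError(
            f"non-positive intensity at probe {probe!r}, array {array!r}"
        )
    df = pd.DataFrame(
        np.log2(vals), index=m.values.index, columns=m.values.columns
    )
    return ExpressionMatrix(df, m.flags, m.is_control, is_log2=True)
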