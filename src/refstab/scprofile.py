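"""Single-cell expression summaries for the candidate panel.

Works on an :class:`anndata.AnnData` of cells x genes (sparse or dense
counts / normalized expression) with per-cell ``cell_type`` and
``timepoint`` labels.  Produces dot-plot statistics (fraction of cells
expressing above the detection limit, mean expression) per cell type
and timepoint, a per-gene variability ranking (SD across all cells
pooled), and cell-type mean matrices pooled over timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

__all__ = [
    "SCProfile",
    "dotplot_summary",
    "gene_sd_ranking",
    "celltype_mean_heatmap",
]


@dataclass
class SCProfile:
    """Tidy dot-plot summary plus bookkeeping of absent genes."""

    summary: pd.DataFrame  # gene, cell_type, timepoint, fraction, mean, n_cells
    not_found: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _gene_matrix(adata: AnnData, genes: list[str]):
    present = [g for g in genes if g in adata.var_names]
    absent = [g for g in genes if g not in adata.var_names]
    X = adata[:, present].X
    return X, present, absent


def _col_stats(X, detection_limit: float = 0.0):
    """(fraction expressing, mean) per column; sparse-exact."""
    n = X.shape[0]
    if n == 0:
        return None, None
    if sparse.issparse(X):
        X = X.tocsc()
        mean = np.asarray(X.mean(axis=0)).ravel()
        if detection_limit == 0.0:
            frac = np.diff(X.indptr) / n
            # explicit zeros would inflate the count; remove them
            if X.nnz and (X.data == 0).any():
                X = X.copy()
                X.eliminate_zeros()
                frac = np.diff(X.indptr) / n
        else:
            frac = np.asarray((X > detection_limit).sum(axis=0)).ravel() / n
    else:
        X = np.asarray(X)
        mean = X.mean(axis=0)
        frac = (X > detection_limit).mean(axis=0)
    return frac, mean


def dotplot_summary(
    adata: AnnData,
    genes: list[str],
    cell_type_key: str = "cell_type",
    timepoint_key: str = "timepoint",
    detection_limit: float = 0.0,
) -> SCProfile:
    """Per (gene, cell type, timepoint): fraction of cells expressing
    above ``detection_limit`` and the mean expression over *all* cells
    of the stratum.  Genes absent from the matrix are reported, not
    errored; empty strata yield missing statistics with a warning."""
    X, present, absent = _gene_matrix(adata, genes)
    obs = adata.obs
    rows, warnings = [], []
    types = obs[cell_type_key].astype(str)
    tps = obs[timepoint_key].astype(str)
    for ct in sorted(types.unique()):
        for tp in sorted(tps.unique()):
            mask = ((types == ct) & (tps == tp)).to_numpy()
            n = int(mask.sum())
            if n == 0:
                warnings.append(f"empty stratum ({ct}, {tp})")
                for g in present:
                    rows.append((g, ct, tp, np.nan, np.nan, 0))
                continue
            frac, mean = _col_stats(X[mask], detection_limit)
            for j, g in enumerate(present):
                rows.append((g, ct, tp, float(frac[j]), float(mean[j]), n))
    summary = pd.DataFrame(
        rows,
        columns=["gene", "cell_type", "timepoint", "fraction", "mean", "n_cells"],
    )
    return SCProfile(summary, not_found=absent, warnings=warnings)


def gene_sd_ranking(
    adata: AnnData, genes: list[str] | None = None
) -> pd.DataFrame:
    """Per-gene SD across all cells (all types and timepoints pooled),
    ranked ascending — the least variable genes first.  Ties share the
    lower rank and sort alphabetically."""
    if adata.n_obs < 2:
        raise ValueError("SD across cells needs >= 2 cells")
    genes = list(genes) if genes is not None else list(adata.var_names)
    X, present, absent = _gene_matrix(adata, genes)
    # two-pass on densified panel columns: exact for constant genes,
    # cheap because the panel is small relative to the atlas
    dense = X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)
    sd = pd.Series(dense.std(axis=0, ddof=1), index=present, name="sd")
    ordered = sorted(present, key=lambda g: (sd[g], g))
    ranks, prev = {}, None
    for i, g in enumerate(ordered):
        ranks[g] = ranks[ordered[i - 1]] if i and sd[g] == prev else i + 1
        prev = sd[g]
    out = pd.DataFrame({"sd": sd.loc[ordered], "rank": [ranks[g] for g in ordered]})
    out.attrs["not_found"] = absent
    out.attrs["least_variable"] = list(out.index[:5])
    return out


def celltype_mean_heatmap(
    adata: AnnData,
    genes: list[str],
    cell_type_key: str = "cell_type",
) -> pd.DataFrame:
    """Gene x cell-type matrix of mean expression pooled over all
    timepoints (rows: genes; columns: cell-type labels, which may be
    fine-grained)."""
    X, present, absent = _gene_matrix(adata, genes)
    labels = adata.obs[cell_type_key].astype(str)
    cols = {}
    for ct in sorted(labels.unique()):
        mask = (labels == ct).to_numpy()
        _, mean = _col_stats(X[mask])
        cols[ct] = mean
    out = pd.DataFrame(cols, index=present)
    out.attrs["not_found"] = absent
    return out
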