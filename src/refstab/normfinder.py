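"""NormFinder model-based expression-stability analysis, from scratch.

The model: gene-centered log2 expression ``z_igj`` (gene i, group g,
sample j) decomposes into a systematic between-group difference
``d_ig`` and within-group noise with variance ``sigma2_ig``.  Because
centering across genes mixes every gene's noise into each z value, the
naive within-group variance is biased; the de-mixing corrections below
(for k genes) undo that::

    v_ig        = sample variance of z_igj over j
    S_g         = (k/(k-1)) * sum_i v_ig          # total noise variance
    sigma2_ig   = max(0, (v_ig - S_g/k**2) * k/(k-2))

With G groups, the between-group variance component is::

    d_ig    = mean_j z_igj - mean_g mean_j z_igj
    gamma2  = max(0, sum_ig d_ig**2 / ((G-1)(k-1))
                     - (1/(G*k)) * sum_ig sigma2_ig / n_g)

and the group differences are shrunk toward zero (empirical Bayes)::

    dtilde_ig = d_ig * gamma2 / (gamma2 + sigma2_ig / n_g)

The stability value combines both sources; lower is more stable::

    single group:  SV_i = sqrt(sigma2_i)
    grouped:       SV_i = (1/G) * sum_g [ |dtilde_ig|
                     + sqrt( (sigma2_ig/n_g) * gamma2 / (gamma2 + sigma2_ig/n_g) ) ]
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .data_io import CqTable, GroupDesign

__all__ = [
    "NormfinderResult",
    "log_and_center",
    "intragroup_variance",
    "intergroup_analysis",
    "stability_values",
    "best_combination",
    "analyze",
]


def log_and_center(
    table: CqTable, genes: list[str] | None = None, efficiency: float = 2.0
) -> pd.DataFrame:
    """Centered log2 expression ``z`` (genes x samples).

    ``y = -log2(E) * Cq`` is log2 expression up to an additive constant;
    centering across genes within each sample removes sample-specific
    effects (template load, cDNA yield).  Samples with any missing Cq
    among the analyzed genes are dropped (listwise deletion).
    """
    cq = table.cq if genes is None else table.cq.loc[genes]
    if cq.shape[0] < 3:
        raise ValueError("gene-centering needs >= 3 genes")
    cq = cq.loc[:, cq.notna().all(axis=0)]
    if cq.shape[1] == 0:
        raise ValueError("listwise deletion removed every sample")
    y = -np.log2(efficiency) * cq
    return y - y.mean(axis=0)


def _group_matrix(z: pd.DataFrame, design: GroupDesign) -> dict[str, pd.DataFrame]:
    out = {}
    for label, members in design.groups.items():
        present = [s for s in members if s in z.columns]
        if len(present) < 2:
            raise ValueError(
                f"group {label!r} has {len(present)} usable sample(s); need >= 2"
            )
        out[label] = z[present]
    return out


def intragroup_variance(z: pd.DataFrame, design: GroupDesign) -> pd.DataFrame:
    """De-mixed within-group variance estimates (genes x groups),
    truncated at zero."""
    k = z.shape[0]
    if k < 3:
        raise ValueError("intragroup variance needs >= 3 genes (k/(k-2) factor)")
    cols = {}
    for label, zg in _group_matrix(z, design).items():
        v = zg.var(axis=1, ddof=1)
        S = (k / (k - 1)) * v.sum()
        cols[label] = np.maximum(0.0, (v - S / k**2) * k / (k - 2))
    return pd.DataFrame(cols)


def intergroup_analysis(
    z: pd.DataFrame, design: GroupDesign, sigma2: pd.DataFrame
) -> tuple[pd.DataFrame, float, pd.DataFrame]:
    """Shrunken between-group differences.

    Returns ``(dtilde, gamma2, dhat)``: the shrunken and raw group
    differences (genes x groups) and the between-group variance
    component.  Within each group the raw differences sum to zero over
    genes (a centering identity).
    """
    G = len(design.groups)
    if G < 2:
        raise ValueError("intergroup analysis needs >= 2 groups; "
                         "use the single-group stability value otherwise")
    k = z.shape[0]
    zbar = pd.DataFrame(
        {label: zg.mean(axis=1) for label, zg in _group_matrix(z, design).items()}
    )
    dhat = zbar.sub(zbar.mean(axis=1), axis=0)
    n_g = pd.Series(design.sizes)[dhat.columns].astype(float)
    var_term = (sigma2[dhat.columns] / n_g).to_numpy()
    gamma2 = max(
        0.0,
        float((dhat.to_numpy() ** 2).sum() / ((G - 1) * (k - 1))
              - var_term.sum() / (G * k)),
    )
    denom = gamma2 + var_term
    with np.errstate(invalid="ignore"):
        shrink = np.where(denom > 0, gamma2 / np.where(denom > 0, denom, 1.0), 0.0)
    dtilde = pd.DataFrame(
        dhat.to_numpy() * shrink, index=dhat.index, columns=dhat.columns
    )
    return dtilde, gamma2, dhat


@dataclass
class NormfinderResult:
    sv: pd.Series
    ranks: pd.Series
    mode: str  # "single" | "grouped"
    sigma2: pd.DataFrame
    dtilde: pd.DataFrame | None = None
    gamma2: float | None = None
    best_gene: str | None = None
    best_pair: tuple[str, str] | None = None
    best_pair_sd: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"SV": self.sv, "rank": self.ranks}).sort_values(
            ["rank", "SV"]
        )


def _rank_ascending(values: pd.Series) -> pd.Series:
    ordered = sorted(values.index, key=lambda g: (values[g], g))
    ranks, prev = {}, None
    for i, g in enumerate(ordered):
        ranks[g] = ranks[ordered[i - 1]] if i and values[g] == prev else i + 1
        prev = values[g]
    return pd.Series(ranks).loc[values.index].astype(int)


def stability_values(
    sigma2: pd.DataFrame,
    dtilde: pd.DataFrame | None,
    design: GroupDesign,
    gamma2: float | None = None,
    mode: str = "grouped",
) -> NormfinderResult:
    """Combine variance components into per-gene stability values."""
    if mode == "single":
        sv = np.sqrt(sigma2.mean(axis=1)) if sigma2.shape[1] > 1 else np.sqrt(
            sigma2.iloc[:, 0]
        )
    elif mode == "grouped":
        if dtilde is None or gamma2 is None:
            raise ValueError("grouped mode needs dtilde and gamma2")
        n_g = pd.Series(design.sizes)[sigma2.columns].astype(float)
        var_term = (sigma2 / n_g).to_numpy()
        denom = gamma2 + var_term
        with np.errstate(invalid="ignore"):
            se2 = np.where(denom > 0, var_term * gamma2 / np.where(denom > 0, denom, 1.0), 0.0)
        per_group = np.abs(dtilde.to_numpy()) + np.sqrt(se2)
        sv = pd.Series(per_group.mean(axis=1), index=sigma2.index)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    sv = pd.Series(sv, name="SV")
    ranks = _rank_ascending(sv)
    best = ranks.index[ranks == 1][0]
    return NormfinderResult(
        sv=sv,
        ranks=ranks,
        mode=mode,
        sigma2=sigma2,
        dtilde=dtilde,
        gamma2=gamma2,
        best_gene=best,
    )


def _grouped_sv_of(z: pd.DataFrame, design: GroupDesign) -> pd.Series:
    sigma2 = intragroup_variance(z, design)
    dtilde, gamma2, _ = intergroup_analysis(z, design, sigma2)
    return stability_values(sigma2, dtilde, design, gamma2, mode="grouped").sv


def best_combination(
    z: pd.DataFrame, design: GroupDesign, candidates: list[str] | None = None
) -> tuple[tuple[str, str], float]:
    """Best two-gene combination and its re-calculated SD.

    For each gene pair the sample-wise mean of the two genes' centered
    log expression acts as a pseudo-gene; the grouped stability value is
    recomputed on the reduced gene set (pair replaced by the
    pseudo-gene) and the pair minimizing the pseudo-gene's stability
    value wins.  Averaging halves independent noise, so a good pair can
    beat the best single gene.

    Recomputing "on the reduced gene set" includes the gene-centering
    step: the reduced matrix is re-centered across its k-1 rows, which
    is exactly what centering the uncentered log expression of the
    reduced set would give (per-sample constants cancel).  Without the
    re-centering the pseudo-gene would keep the original k-gene
    centering and its variance estimate would be model-inconsistent.
    """
    genes = candidates or list(z.index)
    if len(genes) < 2:
        raise ValueError("need >= 2 candidate genes")
    best_pair, best_sd = None, np.inf
    for g1, g2 in combinations(sorted(genes), 2):
        pseudo = f"{g1}+{g2}"
        z2 = z.drop(index=[g1, g2])
        z2.loc[pseudo] = (z.loc[g1] + z.loc[g2]) / 2.0
        z2 = z2 - z2.mean(axis=0)
        sv = _grouped_sv_of(z2, design)[pseudo]
        if sv < best_sd:
            best_pair, best_sd = (g1, g2), float(sv)
    return best_pair, best_sd


def analyze(
    table: CqTable,
    design: GroupDesign | None = None,
    genes: list[str] | None = None,
    efficiency: float = 2.0,
    with_best_pair: bool = False,
) -> NormfinderResult:
    """Full NormFinder run on a CqTable.

    Without a design (or with a single group) all samples form one
    group and SV reduces to the within-group SD.  With >= 2 groups the
    intra/intergroup decomposition is used, and optionally the best
    two-gene combination is searched.
    """
    z = log_and_center(table, genes, efficiency)
    if design is None:
        design = GroupDesign("all", {"all": list(z.columns)})
    single = len(design.groups) < 2
    sigma2 = intragroup_variance(z, design)
    if single:
        result = stability_values(sigma2, None, design, mode="single")
    else:
        dtilde, gamma2, _ = intergroup_analysis(z, design, sigma2)
        result = stability_values(sigma2, dtilde, design, gamma2, mode="grouped")
        if with_best_pair:
            pair, sd = best_combination(z, design)
            result.best_pair, result.best_pair_sd = pair, sd
    return result
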