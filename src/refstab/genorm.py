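"""GeNorm expression-stability analysis, implemented from scratch.

For genes j, k with linear-scale relative quantities ``a`` across
samples, the pairwise variation ``V_jk`` is the sample standard
deviation of ``log2(a_j / a_k)``.  A gene's stability measure ``M_j``
is the mean of ``V_jk`` over all partner genes.  Ranking proceeds by
iterative exclusion: the gene with the highest M is removed and M is
recomputed, until the two most stable genes — indistinguishable by
construction — remain as the final pair.

M is invariant under per-sample multiplicative factors (template-load
artifacts, hence also additive per-sample Cq shifts such as inter-run
calibration) and under per-gene constants; lower M means more stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import CqTable

__all__ = [
    "RelQuantTable",
    "GenormResult",
    "cq_to_relquant",
    "pairwise_variation",
    "m_values",
    "iterative_ranking",
    "pairwise_variation_ladder",
]


@dataclass
class RelQuantTable:
    """Genes x samples matrix of strictly positive relative quantities,
    scaled so each gene's maximum is 1 (the lowest-Cq sample)."""

    values: pd.DataFrame
    efficiency: float = 2.0
    removed_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if (self.values <= 0).any().any() or self.values.isna().any().any():
            raise ValueError("relative quantities must be strictly positive")

    @property
    def log2(self) -> pd.DataFrame:
        return np.log2(self.values)


def cq_to_relquant(
    table: CqTable, efficiency: float = 2.0, genes: list[str] | None = None
) -> RelQuantTable:
    """Convert Cq to linear relative quantities ``a = E**(Cq_min - Cq)``.

    Samples with any missing Cq among the analyzed genes are removed
    (listwise deletion) and reported on the result.
    """
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    cq = table.cq if genes is None else table.cq.loc[genes]
    complete = cq.notna().all(axis=0)
    removed = [s for s, ok in complete.items() if not ok]
    cq = cq.loc[:, complete]
    if cq.shape[1] == 0:
        raise ValueError("listwise deletion removed every sample")
    a = np.power(efficiency, cq.min(axis=1).to_numpy()[:, None] - cq.to_numpy())
    values = pd.DataFrame(a, index=cq.index, columns=cq.columns)
    return RelQuantTable(values, efficiency, removed)


def pairwise_variation(a_j, a_k) -> float:
    """V_jk: sample SD (n-1 denominator) of log2(a_j / a_k)."""
    a_j = np.asarray(a_j, dtype=float)
    a_k = np.asarray(a_k, dtype=float)
    if a_j.shape != a_k.shape:
        raise ValueError("series must have equal length")
    if a_j.size < 2:
        raise ValueError("pairwise variation needs >= 2 samples")
    if np.any(a_j <= 0) or np.any(a_k <= 0):
        raise ValueError("relative quantities must be positive")
    return float(np.std(np.log2(a_j / a_k), ddof=1))


def _m_from_log(L: np.ndarray) -> np.ndarray:
    """M per gene from a genes x samples log2 matrix (vectorized)."""
    k = L.shape[0]
    # V[j, l] = sd over samples of (L_j - L_l)
    diff = L[:, None, :] - L[None, :, :]
    V = diff.std(axis=2, ddof=1)
    return V.sum(axis=1) / (k - 1)


def m_values(rq: RelQuantTable, genes: list[str] | None = None) -> pd.Series:
    """Per-gene GeNorm M: mean pairwise variation against all partners."""
    vals = rq.values if genes is None else rq.values.loc[genes]
    if vals.shape[0] < 3:
        raise ValueError(
            "M-values need >= 3 genes; use pairwise_variation for two"
        )
    if vals.shape[1] < 2:
        raise ValueError("M-values need >= 2 samples")
    L = np.log2(vals.to_numpy(float))
    return pd.Series(_m_from_log(L), index=vals.index, name="M")


@dataclass
class GenormResult:
    """Outcome of iterative GeNorm ranking.

    ``m`` holds each gene's M at the round of its removal (the final
    pair: the last round); ``first_round_m`` the M from the full gene
    set, kept for transparency.  Ranks: the final pair is tied at 1,
    the next gene ranks 3, and so on in reverse exclusion order.
    """

    m: pd.Series
    first_round_m: pd.Series
    ranks: pd.Series
    exclusion_order: list[str]
    final_pair: tuple[str, str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"M": self.m, "rank": self.ranks, "first_round_M": self.first_round_m}
        ).sort_values(["rank", "M"])


def iterative_ranking(rq: RelQuantTable) -> GenormResult:
    """Iteratively exclude the least stable gene (highest M; ties broken
    by removing the alphabetically last symbol first) until two remain."""
    genes = list(rq.values.index)
    if len(genes) < 3:
        raise ValueError("iterative ranking needs >= 3 genes")
    first = m_values(rq)
    removal_m: dict[str, float] = {}
    exclusion: list[str] = []
    remaining = genes[:]
    while len(remaining) > 2:
        m = m_values(rq, remaining)
        worst = sorted(m.index[m == m.max()])[-1]
        removal_m[worst] = float(m.loc[worst])
        exclusion.append(worst)
        remaining.remove(worst)
    # final pair: M of the last round equals V between the two genes
    v = pairwise_variation(
        rq.values.loc[remaining[0]], rq.values.loc[remaining[1]]
    )
    pair = tuple(sorted(remaining))
    for g in pair:
        removal_m[g] = v
    ranks = {}
    for g in pair:
        ranks[g] = 1
    for i, g in enumerate(reversed(exclusion)):
        ranks[g] = 3 + i
    m_series = pd.Series({g: removal_m[g] for g in genes}, name="M").loc[genes]
    rank_series = pd.Series(ranks, name="rank").loc[genes]
    return GenormResult(m_series, first, rank_series, exclusion, pair)


def pairwise_variation_ladder(
    rq: RelQuantTable, result: GenormResult
) -> pd.Series:
    """V(n/n+1) between normalization factors of the top-n and
    top-(n+1) genes (geometric means), for n = 2..k-1.  The classic
    companion output used to decide how many reference genes to use."""
    order = [*result.final_pair, *reversed(result.exclusion_order)]
    L = np.log2(rq.values.loc[order].to_numpy(float))
    out = {}
    for n in range(2, len(order)):
        nf_n = L[:n].mean(axis=0)  # log2 geometric mean
        nf_n1 = L[: n + 1].mean(axis=0)
        out[f"V{n}/{n + 1}"] = float(np.std(nf_n - nf_n1, ddof=1))
    return pd.Series(out, name="V")
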