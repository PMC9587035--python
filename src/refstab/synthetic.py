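"""Synthetic data generators with the statistical structure the
stability analyses assume.

``simulate_cq`` draws a gene x sample Cq table from an additive model
on the Cq (log2-expression) scale::

    Cq_gs = mu_g + stage/sex/hyperoxia offsets + plate shift + eps
    eps ~ Normal(0, sigma_g * (1 + lambda * [RIN < 5]))

i.e. multiplicative log-normal expression noise, the regime in which
GeNorm's M and NormFinder's SV are defined.  Values beyond the
detection cutoff become non-detects.  The default design mirrors the
study that motivates the package: 17 room-air samples of good RNA
quality split over three developmental stages (6 / 7 / 4), 33 room-air
samples with degraded RNA, 36 hyperoxia-exposed samples, a 21 / 20
male / female split among the good-quality room-air + hyperoxia
animals, and four PCR plates.

``simulate_sc`` draws sparse negative-binomial single-cell counts per
cell type x timepoint stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

from .data_io import CqTable
from .fixtures import fixture_tables  # re-exported: packaged reference tables

__all__ = ["GeneSpec", "SimConfig", "simulate_cq", "simulate_sc", "default_config",
           "fixture_tables"]

STAGES = ("PND2.5", "PND5.5", "PND14.5-28.5")
STAGE_PND = {"PND2.5": 2.5, "PND5.5": 5.5, "PND14.5-28.5": 21.0}


@dataclass
class GeneSpec:
    """Per-gene simulation parameters (all on the Cq/cycle scale)."""

    symbol: str
    baseline_cq: float = 22.0
    noise_sd: float = 0.3
    stage_effects: dict[str, float] = field(default_factory=dict)
    sex_effect: float = 0.0  # added to male samples
    hyperoxia_effect: float = 0.0
    rin_offset: float = 0.0  # degradation shift for RIN < 5 samples


@dataclass
class SimConfig:
    """Study design and noise model for :func:`simulate_cq`."""

    genes: list[GeneSpec]
    n_physiologic: dict[str, int] = field(
        default_factory=lambda: {"PND2.5": 6, "PND5.5": 7, "PND14.5-28.5": 4}
    )
    n_low_rin: int = 33
    n_hyperoxia: int = 36
    n_male_good_rin: int = 21  # male count among RIN>5 animals
    n_plates: int = 4
    plate_shift_sd: float = 0.4
    rin_noise_factor: float = 1.0  # lambda: extra noise for RIN < 5
    dropout_cq: float = 35.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(g.noise_sd < 0 for g in self.genes):
            raise ValueError("noise SDs must be >= 0")
        if not 0 < self.dropout_cq < 45:
            raise ValueError("dropout cutoff must lie in (0, 45)")


def default_config(seed: int = 0) -> SimConfig:
    """Eight genes with graded noise, one hyperoxia-regulated gene and
    one near the detection limit; study-sized strata."""
    sds = [0.05, 0.1, 0.15, 0.2, 0.3, 0.4, 0.6, 0.8]
    genes = [
        GeneSpec(f"G{i + 1:02d}", baseline_cq=20.0 + i, noise_sd=s)
        for i, s in enumerate(sds)
    ]
    genes[5].hyperoxia_effect = 1.5  # regulated under oxygen injury
    return SimConfig(genes=genes, seed=seed)


def _build_samples(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    idx = 0

    def add(stage, fio2, rin_high):
        nonlocal idx
        idx += 1
        rin = float(rng.uniform(5.4, 8.1)) if rin_high else float(rng.uniform(1.5, 4.9))
        rows.append(
            {
                "sample": f"S{idx:03d}",
                "pnd": STAGE_PND[stage],
                "stage": stage,
                "fio2": fio2,
                "rin": round(rin, 1),
                "sex": None,
                "plate": f"P{(idx - 1) % cfg.n_plates + 1}",
            }
        )

    for stage, n in cfg.n_physiologic.items():
        for _ in range(n):
            add(stage, 0.21, True)
    n_stage = list(cfg.n_physiologic.values())
    low = np.array_split(np.arange(cfg.n_low_rin), len(STAGES))
    for stage, chunk in zip(STAGES, low):
        for _ in chunk:
            add(stage, 0.21, False)
    hyper = np.array_split(np.arange(cfg.n_hyperoxia), len(STAGES))
    for stage, chunk in zip(STAGES, hyper):
        for _ in chunk:
            add(stage, 0.8, True)
    meta = pd.DataFrame(rows).set_index("sample")
    # sex: fix the male/female split among good-RNA animals, alternate rest
    good = meta.index[meta["rin"] > 5]
    sexes = ["M"] * cfg.n_male_good_rin + ["F"] * (len(good) - cfg.n_male_good_rin)
    perm = rng.permutation(len(good))
    meta.loc[good, "sex"] = [sexes[i] for i in perm]
    rest = meta.index[meta["sex"].isna()]
    meta.loc[rest, "sex"] = ["M" if i % 2 == 0 else "F" for i in range(len(rest))]
    return meta


def simulate_cq(cfg: SimConfig, seed: int | None = None) -> tuple[CqTable, dict]:
    """Draw a Cq table from the additive model; deterministic per seed.

    Returns the table and a truth record holding every parameter the
    recovery tests need (per-gene noise SDs, effects, plate shifts).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    meta = _build_samples(cfg, rng)
    plates = sorted(meta["plate"].unique())
    plate_shift = {p: float(rng.normal(0.0, cfg.plate_shift_sd)) for p in plates}
    n = len(meta)
    cq = {}
    for g in cfg.genes:
        mu = np.full(n, g.baseline_cq, dtype=float)
        mu += meta["stage"].map(lambda s: g.stage_effects.get(s, 0.0)).to_numpy()
        mu += np.where(meta["sex"].to_numpy() == "M", g.sex_effect, 0.0)
        mu += np.where(meta["fio2"].to_numpy() > 0.21, g.hyperoxia_effect, 0.0)
        low_rin = (meta["rin"] < 5).to_numpy()
        mu += np.where(low_rin, g.rin_offset, 0.0)
        mu += meta["plate"].map(plate_shift).to_numpy()
        sd = g.noise_sd * (1.0 + cfg.rin_noise_factor * low_rin)
        vals = mu + rng.normal(0.0, 1.0, size=n) * sd
        vals[vals > cfg.dropout_cq] = np.nan
        cq[g.symbol] = vals
    cq_df = pd.DataFrame(cq, index=meta.index).T
    truth = {
        "noise_sd": {g.symbol: g.noise_sd for g in cfg.genes},
        "baseline_cq": {g.symbol: g.baseline_cq for g in cfg.genes},
        "hyperoxia_effect": {g.symbol: g.hyperoxia_effect for g in cfg.genes},
        "sex_effect": {g.symbol: g.sex_effect for g in cfg.genes},
        "stage_effects": {g.symbol: dict(g.stage_effects) for g in cfg.genes},
        "plate_shift": plate_shift,
        "rin_noise_factor": cfg.rin_noise_factor,
        "dropout_cq": cfg.dropout_cq,
    }
    return CqTable(cq_df, meta), truth


SC_TIMEPOINTS = ("P0", "P3", "P5", "P7", "P14")
SC_CELLTYPES = ("epithelial", "endothelial", "mesenchymal", "other")


def simulate_sc(
    gene_means: pd.DataFrame,
    dispersion: float | pd.DataFrame = 2.0,
    cells_per_stratum: int = 50,
    celltypes: tuple[str, ...] = SC_CELLTYPES,
    timepoints: tuple[str, ...] = SC_TIMEPOINTS,
    seed: int = 0,
) -> AnnData:
    """Sparse negative-binomial single-cell counts.

    ``gene_means``: genes x cell-type matrix of mean counts (applied at
    every timepoint); ``dispersion`` is the NB size parameter (variance
    = mu + mu^2/size; size -> inf approaches Poisson).  Cells carry
    ``cell_type`` and ``timepoint`` labels.
    """
    rng = np.random.default_rng(seed)
    genes = list(gene_means.index)
    blocks, ct_labels, tp_labels = [], [], []
    for ct in celltypes:
        mu = gene_means[ct].to_numpy(float) if ct in gene_means.columns else np.zeros(len(genes))
        for tp in timepoints:
            size = dispersion if np.isscalar(dispersion) else dispersion.loc[:, ct].to_numpy()
            with np.errstate(divide="ignore"):
                p = np.where(mu > 0, size / (size + mu), 1.0)
            counts = np.where(
                mu[None, :] > 0,
                rng.negative_binomial(size, p[None, :], size=(cells_per_stratum, len(genes))),
                0,
            )
            blocks.append(sparse.csr_matrix(counts))
            ct_labels += [ct] * cells_per_stratum
            tp_labels += [tp] * cells_per_stratum
    X = sparse.vstack(blocks).tocsr()
    obs = pd.DataFrame(
        {"cell_type": ct_labels, "timepoint": tp_labels},
        index=[f"cell{i:05d}" for i in range(X.shape[0])],
    )
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    return AnnData(X=X, obs=obs, var=var)
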