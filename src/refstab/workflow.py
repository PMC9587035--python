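"""Comparison protocol for reference-gene evaluation.

Stability columns (GeNorm M or NormFinder SV per condition) are
thresholded — values strictly below 0.5 count as reliable — ranked, and
aggregated across condition groups by mean rank for genes reliable in
every group.  Two-group comparisons additionally run the NormFinder
intra/intergroup analysis with best gene and best two-gene combination.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

from . import genorm as _genorm
from . import normfinder as _normfinder
from .data_io import CqTable, GroupDesign

__all__ = [
    "StabilityColumn",
    "RELIABILITY_THRESHOLD",
    "reliability_filter",
    "mean_rank_across_groups",
    "compare_conditions",
    "preselection_vs_validation",
    "reproduce_published_analysis",
]

#: M/SV below this (strictly) marks a reliable reference gene
RELIABILITY_THRESHOLD = 0.5


@dataclass
class StabilityColumn:
    """One condition's stability values for a shared gene universe."""

    name: str
    algorithm: str  # "genorm" | "normfinder"
    values: pd.Series
    ranks: pd.Series
    n: int | None = None

    def reliable(self, threshold: float = RELIABILITY_THRESHOLD) -> list[str]:
        return reliability_filter(self.values, threshold)

    def to_frame(self, threshold: float = RELIABILITY_THRESHOLD) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "value": self.values,
                "rank": self.ranks,
                "reliable": self.values < threshold,
            }
        )


def reliability_filter(
    values: pd.Series, threshold: float = RELIABILITY_THRESHOLD
) -> list[str]:
    """Genes with stability value strictly below ``threshold``.

    The comparison is strict: a value of exactly 0.5 is not reliable.
    """
    if threshold <= 0:
        return []
    return sorted(values.index[values < threshold])


def mean_rank_across_groups(
    columns: list[StabilityColumn],
    threshold: float = RELIABILITY_THRESHOLD,
) -> pd.DataFrame:
    """Mean-rank aggregation over condition groups.

    Eligible genes are reliable (value < threshold) in *every* column;
    their score is the arithmetic mean of the within-column ranks,
    sorted ascending (ties broken by smaller mean value, then
    alphabetically).  Ineligible genes are listed with
    ``eligible=False`` after the eligible block.
    """
    if not columns:
        raise ValueError("need at least one stability column")
    universe = set(columns[0].values.index)
    for c in columns[1:]:
        if set(c.values.index) != universe:
            raise ValueError("columns must share one gene universe")
    genes = sorted(universe)
    vals = pd.DataFrame({c.name: c.values for c in columns}).loc[genes]
    ranks = pd.DataFrame({c.name: c.ranks for c in columns}).loc[genes]
    eligible = (vals < threshold).all(axis=1)
    out = pd.DataFrame(
        {
            "mean_rank": ranks.mean(axis=1),
            "mean_value": vals.mean(axis=1),
            "eligible": eligible,
        }
    )
    out = out.loc[
        sorted(
            out.index,
            key=lambda g: (
                not out.loc[g, "eligible"],
                out.loc[g, "mean_rank"],
                out.loc[g, "mean_value"],
                g,
            ),
        )
    ]
    return out


def _single_condition_columns(
    table: CqTable,
    design: GroupDesign,
    algorithms: tuple[str, ...],
    efficiency: float,
) -> list[StabilityColumn]:
    cols = []
    for label, members in design.groups.items():
        sub = table.subset_samples(members)
        if "genorm" in algorithms:
            rq = _genorm.cq_to_relquant(sub, efficiency)
            res = _genorm.iterative_ranking(rq)
            cols.append(
                StabilityColumn(
                    f"{design.name}:{label}:genorm", "genorm",
                    res.m, res.ranks, n=len(members),
                )
            )
        if "normfinder" in algorithms:
            res = _normfinder.analyze(sub, design=None, efficiency=efficiency)
            cols.append(
                StabilityColumn(
                    f"{design.name}:{label}:normfinder", "normfinder",
                    res.sv, res.ranks, n=len(members),
                )
            )
    return cols


def compare_conditions(
    table: CqTable,
    designs: list[GroupDesign],
    algorithms: tuple[str, ...] = ("genorm", "normfinder"),
    threshold: float = RELIABILITY_THRESHOLD,
    efficiency: float = 2.0,
    with_best_pair: bool = True,
) -> dict:
    """Run the full comparison protocol.

    For each design, every group is analyzed separately with each
    algorithm; per-algorithm mean-rank aggregation follows, and designs
    with >= 2 groups get a NormFinder intra/intergroup analysis with
    best gene and (optionally) best two-gene combination.  The bundle
    also carries a per-gene summary of where each gene was reliable and
    the union "reliable in >= 1 approach" set.  Deterministic: running
    twice yields identical bundles.
    """
    bundle: dict = {"threshold": threshold, "designs": {}}
    reliable_anywhere: dict[str, list[str]] = {}
    for design in designs:
        try:
            cols = _single_condition_columns(table, design, algorithms, efficiency)
        except Exception as err:  # attach the condition label
            raise type(err)(f"[design {design.name!r}] {err}") from err
        entry: dict = {"columns": {}, "mean_rank": {}}
        for c in cols:
            entry["columns"][c.name] = c.to_frame(threshold)
        for algo in algorithms:
            acols = [c for c in cols if c.algorithm == algo]
            entry["mean_rank"][algo] = mean_rank_across_groups(acols, threshold)
            for c in acols:
                for g in c.reliable(threshold):
                    reliable_anywhere.setdefault(g, []).append(c.name)
        if len(design.groups) >= 2 and "normfinder" in algorithms:
            nf = _normfinder.analyze(
                table.subset_samples(design.all_samples),
                design,
                efficiency=efficiency,
                with_best_pair=with_best_pair,
            )
            entry["intergroup"] = {
                "best_gene": nf.best_gene,
                "best_gene_sd": float(nf.sv.min()),
                "best_pair": nf.best_pair,
                "best_pair_sd": nf.best_pair_sd,
                "gamma2": nf.gamma2,
            }
        bundle["designs"][design.name] = entry
    bundle["reliable_in_any_approach"] = {
        g: sorted(set(names)) for g, names in sorted(reliable_anywhere.items())
    }
    return bundle


def serialize_bundle(bundle: dict, out_dir: str | Path) -> None:
    """Write a comparison bundle as CSV tables plus a JSON summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "threshold": bundle["threshold"],
        "reliable_in_any_approach": bundle["reliable_in_any_approach"],
        "designs": {},
    }
    for dname, entry in bundle["designs"].items():
        safe = dname.replace("/", "_")
        for cname, frame in entry["columns"].items():
            frame.to_csv(out_dir / f"{safe}.{cname.replace(':', '.')}.csv")
        for algo, mr in entry["mean_rank"].items():
            mr.to_csv(out_dir / f"{safe}.mean_rank.{algo}.csv")
        summary["designs"][dname] = entry.get("intergroup", {})
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)


def preselection_vs_validation(
    pre_ranks: pd.Series, post_ranks: pd.Series
) -> tuple[pd.DataFrame, float]:
    """Rank discordance between pre-selection and RT-qPCR validation.

    Positive ``delta`` means the gene did worse in validation than the
    pre-selection promised.  Returns the table sorted by ``|delta|``
    (largest first) and the Spearman rank correlation.
    """
    genes = sorted(set(pre_ranks.index) & set(post_ranks.index))
    if not genes:
        raise ValueError("no shared genes")
    pre = pre_ranks.loc[genes].astype(float)
    post = post_ranks.loc[genes].astype(float)
    delta = post - pre
    table = pd.DataFrame(
        {"pre_rank": pre, "post_rank": post, "delta": delta}
    ).sort_values("delta", key=lambda s: s.abs(), ascending=False)
    if len(genes) < 2 or pre.nunique() == 1 or post.nunique() == 1:
        corr = float("nan")
    else:
        corr = float(stats.spearmanr(pre, post).statistic)
    return table, corr


# ---------------------------------------------------------------------------
# headline reproduction on the study's raw Cq export
# ---------------------------------------------------------------------------

def reproduce_published_analysis(
    cq_path: str | Path,
    meta_path: str | Path | None = None,
    efficiency: float = 2.0,
) -> dict:
    """Recompute the headline stability results from a raw Cq export.

    Expects the study's raw RT-qPCR data (24 genes x 86 samples with
    pnd/sex/fio2/rin/plate metadata; distributed as journal
    supplementary material, not with this package).  Drops genes
    undetected in any sample, then runs GeNorm and NormFinder on the
    physiologic subset (FiO2 0.21, PND 2.5-28.5, RIN > 5) and the
    hyperoxia subset, plus the two-group intergroup analyses.
    """
    from .data_io import drop_undetected_genes, filter_samples, read_cq_table

    cq_path = Path(cq_path)
    if not cq_path.exists():
        raise FileNotFoundError(
            f"raw Cq export not found at {cq_path}; the study's raw data are "
            "journal supplementary material and are not distributed with "
            "this package"
        )
    table = read_cq_table(cq_path, meta=meta_path)
    table, dropped = drop_undetected_genes(table, max_missing=0)
    base = {"pnd": ("between", (2.5, 28.5))}
    physio = filter_samples(
        table, {**base, "fio2": 0.21, "rin": (">", 5)}
    )
    hyper = filter_samples(table, {**base, "fio2": 0.8, "rin": (">", 5)})
    out: dict = {"excluded_genes": list(dropped["gene"])}

    rq = _genorm.cq_to_relquant(physio, efficiency)
    gres = _genorm.iterative_ranking(rq)
    out["genorm_physiologic_min_m"] = float(gres.m.min())
    out["genorm_physiologic_final_pair"] = list(gres.final_pair)

    nf_phys = _normfinder.analyze(physio, efficiency=efficiency)
    out["normfinder_physiologic_min_sv"] = float(nf_phys.sv.min())
    out["normfinder_physiologic_best_gene"] = nf_phys.best_gene

    nf_hyper = _normfinder.analyze(hyper, efficiency=efficiency)
    out["normfinder_hyperoxia_min_sv"] = float(nf_hyper.sv.min())
    out["normfinder_hyperoxia_best_gene"] = nf_hyper.best_gene

    oxy = GroupDesign(
        "oxygen", {"air": physio.samples, "hyperoxia": hyper.samples}
    )
    both = table.subset_samples(physio.samples + hyper.samples)
    nf_oxy = _normfinder.analyze(both, oxy, efficiency=efficiency, with_best_pair=True)
    out["oxygen_best_gene"] = nf_oxy.best_gene
    out["oxygen_best_pair"] = list(nf_oxy.best_pair)
    out["oxygen_best_pair_sd"] = nf_oxy.best_pair_sd

    rin_subset = filter_samples(table, {**base, "fio2": 0.21})
    sexed = filter_samples(rin_subset, {"rin": (">", 5), "sex": ("in", ["M", "F"])})
    if sexed.meta["sex"].nunique() == 2:
        sex_design = GroupDesign.from_metadata(sexed, "sex", "sex")
        nf_sex = _normfinder.analyze(
            sexed, sex_design, efficiency=efficiency, with_best_pair=True
        )
        out["sex_best_gene"] = nf_sex.best_gene
        out["sex_best_gene_sd"] = float(nf_sex.sv.min())
        out["sex_best_pair"] = list(nf_sex.best_pair)
        out["sex_best_pair_sd"] = nf_sex.best_pair_sd
    return out
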