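"""In-silico candidate pre-selection.

Candidate reference genes collected from literature searches, dedicated
reference-gene studies, the Genevestigator RefGenes tool and a vendor
panel are banded by expression level, pruned by exclusion rules
(duplicates, pseudogenes, ribosomal-protein genes, manual vetoes),
ranked by a pooled variability score and reduced to a final RT-qPCR
panel.

The pooled score combines two log2-scale standard deviations — one from
the RefGenes compendium (``sd_ref``) and one from the study's own
microarray data (``sd_array``) — as the square root of their averaged
variances::

    sd_overall = sqrt((sd_ref**2 + sd_array**2) / 2)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CandidateRecord",
    "ExclusionRuleSet",
    "band_expression",
    "overall_sd",
    "rank_candidates",
    "apply_exclusions",
    "select_final_panel",
    "records_from_frame",
    "records_to_frame",
]

#: log2 signal-intensity band boundaries (closed medium interval)
BAND_LOW, BAND_HIGH = 10.0, 13.0


def band_expression(
    log2_level: float, *, low: float = BAND_LOW, high: float = BAND_HIGH
) -> str:
    """Classify a log2 signal intensity into high / medium / low.

    ``level > high`` is high, ``low <= level <= high`` is medium (both
    boundaries belong to the medium band), ``level < low`` is low.
    """
    if not math.isfinite(log2_level):
        raise ValueError(f"expression level must be finite, got {log2_level!r}")
    if log2_level > high:
        return "high"
    if log2_level >= low:
        return "medium"
    return "low"


def overall_sd(sd_ref, sd_array):
    """Pooled SD: square root of the averaged variances (unweighted)."""
    sd_ref = np.asarray(sd_ref, dtype=float)
    sd_array = np.asarray(sd_array, dtype=float)
    if np.any(sd_ref < 0) or np.any(sd_array < 0):
        raise ValueError("standard deviations must be non-negative")
    out = np.sqrt((sd_ref**2 + sd_array**2) / 2.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class CandidateRecord:
    """One candidate reference gene with its pre-selection statistics."""

    symbol: str
    entrez_id: int | None = None
    sources: tuple[str, ...] = ()
    band: str | None = None
    sd_ref: float | None = None
    sd_array: float | None = None
    sd_overall: float | None = None
    rank: int | None = None
    excluded: str | None = None
    pseudogene: bool = False

    def with_overall_sd(self) -> "CandidateRecord":
        return replace(self, sd_overall=overall_sd(self.sd_ref, self.sd_array))


def records_from_frame(df: pd.DataFrame) -> list[CandidateRecord]:
    recs = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        recs.append(
            CandidateRecord(
                symbol=str(d["symbol"]),
                entrez_id=int(d["entrez_id"]) if d.get("entrez_id") is not None else None,
                sources=tuple(str(d.get("sources", "")).split(",")) if d.get("sources") else (),
                band=d.get("band"),
                sd_ref=d.get("sd_ref"),
                sd_array=d.get("sd_array"),
                sd_overall=d.get("sd_overall"),
                rank=int(d["rank"]) if d.get("rank") is not None and not pd.isna(d["rank"]) else None,
                pseudogene=bool(d.get("pseudogene", False)),
            )
        )
    return recs


def records_to_frame(records: Iterable[CandidateRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "symbol": [r.symbol for r in records],
            "entrez_id": [r.entrez_id for r in records],
            "sources": [",".join(r.sources) for r in records],
            "band": [r.band for r in records],
            "sd_ref": [r.sd_ref for r in records],
            "sd_array": [r.sd_array for r in records],
            "sd_overall": [r.sd_overall for r in records],
            "rank": [r.rank for r in records],
            "excluded": [r.excluded for r in records],
        }
    )


def rank_candidates(records: Sequence[CandidateRecord]) -> list[CandidateRecord]:
    """Rank ascending by ``sd_overall``; ties share the lower rank number
    and are listed alphabetically.  The input order is irrelevant."""
    for r in records:
        if r.sd_overall is None or pd.isna(r.sd_overall):
            raise ValueError(f"candidate {r.symbol!r} has no sd_overall")
    ordered = sorted(records, key=lambda r: (r.sd_overall, r.symbol))
    out: list[CandidateRecord] = []
    for i, r in enumerate(ordered):
        if i > 0 and r.sd_overall == ordered[i - 1].sd_overall:
            rank = out[-1].rank
        else:
            rank = i + 1
        out.append(replace(r, rank=rank))
    return out


@dataclass
class ExclusionRuleSet:
    """Pruning rules applied to the raw candidate list, in fixed order:
    duplicate -> pseudogene -> ribosomal -> manual.  A record matching
    several rules carries only the first matching reason."""

    pseudogene_symbols: tuple[str, ...] = ()
    ribosomal_prefixes: tuple[str, ...] = ("Rpl", "Rps")
    ribosomal_keep: tuple[str, ...] = ("Rpl4",)
    manual_exclusions: dict[str, str] = field(default_factory=dict)
    deduplicate_sources: bool = True

    def __post_init__(self) -> None:
        for sym in self.ribosomal_keep:
            if not any(sym.startswith(p) for p in self.ribosomal_prefixes) and self.ribosomal_prefixes:
                # keep-list entries are simply never excluded; a non-ribosomal
                # keep entry is harmless but usually a typo
                pass


def _is_ribosomal(symbol: str, rules: ExclusionRuleSet) -> bool:
    return any(symbol.startswith(p) for p in rules.ribosomal_prefixes)


def apply_exclusions(
    records: Sequence[CandidateRecord], rules: ExclusionRuleSet
) -> tuple[list[CandidateRecord], list[CandidateRecord]]:
    """Partition candidates into (kept, excluded-with-reason).

    Rule order is fixed: a symbol already seen is a ``duplicate``;
    pseudogenes go next; ribosomal-protein genes (by symbol prefix) are
    dropped except for the designated representatives; finally manual
    exclusions with their stated reason.
    """
    kept: list[CandidateRecord] = []
    excluded: list[CandidateRecord] = []
    seen: set[str] = set()
    for r in records:
        reason = None
        if rules.deduplicate_sources and r.symbol in seen:
            reason = "duplicate"
        elif r.pseudogene or r.symbol in rules.pseudogene_symbols:
            reason = "pseudogene"
        elif _is_ribosomal(r.symbol, rules) and r.symbol not in rules.ribosomal_keep:
            reason = "ribosomal"
        elif r.symbol in rules.manual_exclusions:
            reason = rules.manual_exclusions[r.symbol]
        seen.add(r.symbol)
        if reason is None:
            kept.append(r)
        else:
            excluded.append(replace(r, excluded=reason))
    return kept, excluded


def select_final_panel(
    ranked: Sequence[CandidateRecord],
    top_n: int = 20,
    extra_n: int = 4,
    extra_pool: tuple[int, int] = (21, 46),
    seed: int = 0,
) -> list[CandidateRecord]:
    """Final RT-qPCR panel: the ``top_n`` lowest-variability genes plus
    ``extra_n`` genes drawn uniformly without replacement from the rank
    range ``extra_pool`` (inclusive).  Deterministic given ``seed``."""
    ranked = list(ranked)
    if any(r.rank is None for r in ranked):
        raise ValueError("records must be ranked first (see rank_candidates)")
    top = [r for r in ranked if r.rank <= top_n]
    lo, hi = extra_pool
    if lo <= top_n:
        raise ValueError("extra_pool must not overlap the top_n ranks")
    pool = [r for r in ranked if lo <= r.rank <= hi]
    if extra_n > len(pool):
        raise ValueError(
            f"extra pool has {len(pool)} genes but extra_n={extra_n} requested"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=extra_n, replace=False)
    extras = [pool[i] for i in sorted(idx)]
    return top + extras
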