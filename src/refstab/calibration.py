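"""Inter-run (plate) calibration of Cq values.

A fixed calibrator cDNA mix is measured for one gene (here *Tbp*) on
every plate; between-plate offsets are removed by subtracting each
plate's calibrator deviation from the cross-plate calibrator mean::

    Cq'_gs = Cq_gs - (cal[plate(s)] - mean_p cal[p])

The correction is additive in Cq (multiplicative in expression), so the
adjusted calibrator series is constant and downstream log-ratio
statistics are unaffected by any residual global constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import CqTable, ValidationError

__all__ = [
    "CalibratorSeries",
    "calibrate_interrun",
    "check_calibrator_quality",
]

CALIBRATOR_GENE = "Tbp"  # Entrez 21374


@dataclass
class CalibratorSeries:
    """Plate ID -> calibrator Cq (replicates on a plate pre-averaged)."""

    values: pd.Series
    gene: str = CALIBRATOR_GENE

    def __post_init__(self) -> None:
        self.values = pd.Series(self.values, dtype=float)
        if self.values.isna().any() or not np.isfinite(self.values).all():
            bad = list(self.values.index[~np.isfinite(self.values)])
            raise ValidationError(f"non-finite calibrator Cq for plates {bad}")

    @classmethod
    def from_samples(
        cls, table: CqTable, calibrator_samples: list[str], gene: str = CALIBRATOR_GENE
    ) -> "CalibratorSeries":
        """Build the series from designated calibrator wells inside a
        CqTable, averaging replicates within a plate."""
        sub = table.subset_samples(calibrator_samples)
        if gene not in sub.cq.index:
            raise ValidationError(f"calibrator gene {gene!r} not in table")
        cq = sub.cq.loc[gene]
        plates = sub.meta["plate"]
        series = cq.groupby(plates).mean()
        return cls(series, gene)

    @classmethod
    def from_csv(cls, path, gene: str = CALIBRATOR_GENE) -> "CalibratorSeries":
        df = pd.read_csv(path)
        return cls(pd.Series(df.iloc[:, 1].to_numpy(float), index=df.iloc[:, 0].astype(str)), gene)


def calibrate_interrun(table: CqTable, cal: CalibratorSeries) -> CqTable:
    """Apply the additive inter-run correction; missing Cq stays missing.

    Idempotent once applied: a second pass sees a constant calibrator
    series and shifts nothing (callers re-deriving the series from
    calibrated data get all-zero deviations).
    """
    plates = table.meta["plate"]
    missing = sorted(set(plates) - set(cal.values.index))
    if missing:
        raise ValidationError(f"plates without calibrator value: {missing}")
    deviation = cal.values - cal.values.mean()
    shift = plates.map(deviation).astype(float)  # per sample
    adjusted = table.cq.sub(shift, axis=1)
    return CqTable(adjusted, table.meta.copy())


def check_calibrator_quality(
    cal: CalibratorSeries, tolerance: float = 0.5
) -> dict:
    """Report spread of the calibrator series and flag outlying plates.

    A plate is flagged when its calibrator Cq deviates from the central
    value by more than ``tolerance`` cycles.  The center is the median,
    so a single grossly deviating plate flags itself rather than
    dragging the mean and flagging everyone else.
    """
    if len(cal.values) < 2:
        raise ValueError("calibrator quality check needs >= 2 plates")
    dev = cal.values - cal.values.median()
    flagged = sorted(dev.index[dev.abs() > tolerance])
    return {
        "gene": cal.gene,
        "n_plates": int(len(cal.values)),
        "mean": float(cal.values.mean()),
        "range": float(cal.values.max() - cal.values.min()),
        "sd": float(cal.values.std(ddof=1)),
        "tolerance": float(tolerance),
        "flagged_plates": list(flagged),
    }
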