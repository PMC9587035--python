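"""Packaged reference tables from the neonatal mouse lung study.

Three small CSVs ship with the package (transcribed once from the
published tables and checked against the formula invariants):

``candidate_table.csv``
    46 candidate genes that passed expression confirmation, with
    source tags, expression band, the two log2-scale SDs (``sd_ref``
    from the RefGenes compendium, ``sd_array`` from the study's own
    microarrays), the pooled ``sd_overall`` and its rank; ``in_panel``
    marks the 24-gene RT-qPCR panel.

``genorm_table.csv`` / ``normfinder_table.csv``
    Per-gene GeNorm M-values / NormFinder stability values with ranks
    for each analysis condition of the 23 validated candidates.
    Condition columns: ``preselection`` (pooled SD), ``physiologic``
    (FiO2 0.21, PND2.5-28.5, RIN>5, n=17), the three developmental
    stages ``pnd2_5``/``pnd5_5``/``pnd14_5_28_5``, ``male``/``female``,
    ``low_rin`` (RIN<5, n=33) and ``hyperoxia`` (FiO2 0.8, n=36).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_candidate_table",
    "load_genorm_table",
    "load_normfinder_table",
    "fixture_tables",
    "stability_column",
    "CONDITIONS",
]

CONDITIONS = [
    "preselection",
    "physiologic",
    "pnd2_5",
    "pnd5_5",
    "pnd14_5_28_5",
    "male",
    "female",
    "low_rin",
    "hyperoxia",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("refstab").joinpath(f"data/{name}").open("r") as fh:
        return pd.read_csv(fh)


def load_candidate_table() -> pd.DataFrame:
    """The 46-gene candidate pre-selection table."""
    return _read("candidate_table.csv")


def load_genorm_table() -> pd.DataFrame:
    """Per-condition GeNorm M-values and ranks (23 genes)."""
    return _read("genorm_table.csv").set_index("gene")


def load_normfinder_table() -> pd.DataFrame:
    """Per-condition NormFinder stability values and ranks (23 genes)."""
    return _read("normfinder_table.csv").set_index("gene")


def fixture_tables() -> dict[str, pd.DataFrame]:
    """All packaged tables, keyed ``candidates`` / ``genorm`` /
    ``normfinder``.  Pure: reads package data, no other side effects."""
    return {
        "candidates": load_candidate_table(),
        "genorm": load_genorm_table(),
        "normfinder": load_normfinder_table(),
    }


def stability_column(
    table: pd.DataFrame, condition: str
) -> tuple[pd.Series, pd.Series]:
    """(values, ranks) for one analysis condition of a stability table."""
    if condition not in CONDITIONS:
        raise KeyError(f"unknown condition {condition!r}; one of {CONDITIONS}")
    return table[f"{condition}_value"], table[f"{condition}_rank"].astype(int)
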