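"""Cohort container, column schema, and G×E×outcome cell counts.

A cohort is a plain :class:`pandas.DataFrame` with a documented column
schema, wrapped together with provenance (where it came from: simulation
parameters, a cell-count table, or a CSV on disk).  Missing values are
``NaN`` in memory and empty cells on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

#: The five early psychosocial factors (EPFs), each dichotomized so that
#: 1 = adverse exposure (low warmth, poor childhood finances, any stress
#: event, parent education of 8 years or less).
EPFS: tuple[str, ...] = (
    "maternal_warmth",
    "financial_burden",
    "childhood_stress",
    "father_education",
    "mother_education",
)

#: Raw survey fields backing each EPF.
EPF_RAW_FIELDS: dict[str, tuple[str, ...]] = {
    "maternal_warmth": ("warmth_item1", "warmth_item2", "warmth_item3"),
    "financial_burden": ("child_finance",),
    "childhood_stress": ("stress_police", "stress_parent_substance", "stress_abuse"),
    "father_education": ("father_ed_gt8",),
    "mother_education": ("mother_ed_gt8",),
}

PC_COLUMNS: tuple[str, ...] = ("pc1", "pc2", "pc3", "pc4", "pc5")

FINANCE_LEVELS: tuple[str, ...] = ("pretty_well_off", "about_average", "poor")


def exposure_column(epf: str) -> str:
    """Name of the derived binary adverse-exposure column for an EPF."""
    if epf not in EPFS:
        raise ValueError(f"unknown EPF {epf!r}; expected one of {EPFS}")
    return f"E_{epf}"


def wave_columns(df: pd.DataFrame) -> list[str]:
    """Per-wave ever-smoking response columns present in a frame."""
    cols = [c for c in df.columns if c.startswith("ever_smoked_wave")]
    return sorted(cols, key=lambda c: int(c.rsplit("wave", 1)[1]))


@dataclass(frozen=True)
class CellCounts:
    """Ever-smoking cases and totals in the four G×E exposure cells.

    ``cells`` maps ``(G, E)`` with G, E in {0, 1} to ``(cases, total)``:
    the number of ever-smokers and the cell size.  Percentages in the
    published presentation are ``cases / total``.
    """

    cells: Mapping[tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        keys = {(0, 0), (0, 1), (1, 0), (1, 1)}
        if set(self.cells) != keys:
            raise ValueError(f"cells must be keyed by {sorted(keys)}")
        for key, (cases, total) in self.cells.items():
            if not (0 <= cases <= total):
                raise ValueError(
                    f"cell {key}: cases={cases} must satisfy 0 <= cases <= total={total}"
                )

    def cases(self, g: int, e: int) -> int:
        return self.cells[(g, e)][0]

    def total(self, g: int, e: int) -> int:
        return self.cells[(g, e)][1]

    @property
    def n(self) -> int:
        """Analysis N: the four cell totals summed."""
        return sum(t for _, t in self.cells.values())

    def __iter__(self) -> Iterator[tuple[tuple[int, int], tuple[int, int]]]:
        return iter(sorted(self.cells.items()))


def crosstab_cells(
    df: pd.DataFrame,
    e_col: str,
    g_col: str = "G",
    y_col: str = "ever_smoked",
) -> CellCounts:
    """Cross-tabulate a cohort into G×E cell counts of cases/totals."""
    cells: dict[tuple[int, int], tuple[int, int]] = {}
    g = df[g_col].to_numpy(dtype=float)
    e = df[e_col].to_numpy(dtype=float)
    y = df[y_col].to_numpy(dtype=float)
    for gi in (0, 1):
        for ei in (0, 1):
            mask = (g == gi) & (e == ei)
            cells[(gi, ei)] = (int(y[mask].sum()), int(mask.sum()))
    return CellCounts(cells)


@dataclass
class Cohort:
    """Participant table plus provenance.

    ``df`` holds one row per participant.  ``truth`` optionally carries the
    generating latent indicators (G, per-EPF adverse exposure) of a
    simulated cohort; it is never written to disk and exists so that
    recovery of generating parameters can be tested without re-deriving
    exposures through the harmonization layer.
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    truth: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path: str | Path) -> None:
        """Write the cohort CSV; missing values become empty cells."""
        self.df.to_csv(path, index=False, na_rep="")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Cohort":
        """Read a cohort CSV written by :meth:`to_csv`.

        Empty cells become ``NaN``; categorical fields stay as strings.
        """
        str_cols = [
            "id",
            "group",
            "gender",
            "child_finance",
            "stress_police",
            "stress_parent_substance",
            "stress_abuse",
            "father_ed_gt8",
            "mother_ed_gt8",
        ]
        head = pd.read_csv(path, nrows=0)
        dtype = {c: "string" for c in str_cols if c in head.columns}
        dtype.update(
            {c: "string" for c in head.columns if c.startswith("ever_smoked_wave")}
        )
        df = pd.read_csv(path, dtype=dtype, keep_default_na=True)
        for c in df.columns:
            if df[c].dtype == "string":
                df[c] = df[c].astype(object).where(df[c].notna(), np.nan)
        return cls(df=df, provenance={"source": str(path)})
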