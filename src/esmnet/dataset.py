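"""Long-format daily-diary dataset container and CSV round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Default symptom labels (DSM-5 based daily anxiety items, study order).
DEFAULT_VARIABLE_NAMES = [
    "excessive_worry",
    "uncontrollable_worry",
    "restlessness",
    "fatigue",
    "difficulty_concentrating",
    "irritability",
    "muscle_tension",
    "sleep_disturbance",
]

META_COLUMNS = ("person_id", "day", "attention_pass")


@dataclass
class EsmDataset:
    """A long-format panel of per-person, per-day ordinal symptom ratings.

    Parameters
    ----------
    data
        One row per (person, day). Columns: ``person_id``, ``day`` (integer,
        strictly increasing within person), one float column per symptom
        (NaN = missing), and boolean ``attention_pass``.
    variable_names
        Ordered symptom column labels.
    likert_bounds
        Inclusive observation range for non-missing ratings, or ``None`` for
        continuous (non-discretized) data.
    """

    data: pd.DataFrame
    variable_names: list[str] = field(default_factory=lambda: list(DEFAULT_VARIABLE_NAMES))
    likert_bounds: tuple[int, int] | None = (1, 7)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ----------------------------------------------------------
    @property
    def n_vars(self) -> int:
        return len(self.variable_names)

    @property
    def persons(self) -> list:
        return list(pd.unique(self.data["person_id"]))

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on violation."""
        missing_cols = [c for c in ("person_id", "day", *self.variable_names) if c not in self.data.columns]
        if missing_cols:
            raise ValueError(f"dataset missing columns: {missing_cols}")
        if "attention_pass" not in self.data.columns:
            self.data = self.data.assign(attention_pass=True)
        dup = self.data.duplicated(subset=["person_id", "day"])
        if dup.any():
            raise ValueError("duplicate (person_id, day) records")
        for pid, grp in self.data.groupby("person_id", sort=False):
            days = grp["day"].to_numpy()
            if not np.all(np.diff(days) > 0):
                raise ValueError(f"day index not strictly increasing for person {pid!r}")
        if self.likert_bounds is not None:
            lo, hi = self.likert_bounds
            vals = self.data[self.variable_names].to_numpy(dtype=float)
            obs = vals[~np.isnan(vals)]
            if obs.size and (obs.min() < lo or obs.max() > hi):
                raise ValueError(f"observed values outside likert bounds [{lo}, {hi}]")

    def values_matrix(self) -> np.ndarray:
        """All symptom cells as a float matrix (rows follow ``data``)."""
        return self.data[self.variable_names].to_numpy(dtype=float)

    def person_frame(self, person_id) -> pd.DataFrame:
        return self.data[self.data["person_id"] == person_id]

    def copy(self) -> "EsmDataset":
        return EsmDataset(self.data.copy(), list(self.variable_names), self.likert_bounds)

    # -- I/O ----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write long-format CSV; missing cells become empty fields."""
        cols = ["person_id", "day", *self.variable_names, "attention_pass"]
        self.data[cols].to_csv(path, index=False, na_rep="")

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        variable_names: list[str] | None = None,
        likert_bounds: tuple[int, int] | None = (1, 7),
    ) -> "EsmDataset":
        """Read a long-format CSV written by :meth:`to_csv`.

        If ``variable_names`` is omitted, every column other than the meta
        columns is treated as a symptom variable, in file order.
        """
        df = pd.read_csv(path, float_precision="round_trip")
        if variable_names is None:
            variable_names = [c for c in df.columns if c not in META_COLUMNS]
        if "attention_pass" in df.columns:
            df["attention_pass"] = df["attention_pass"].astype(bool)
        df["day"] = df["day"].astype(int)
        for v in variable_names:
            df[v] = pd.to_numeric(df[v], errors="coerce")
        return cls(df, list(variable_names), likert_bounds)


def missingness_summary(dataset: EsmDataset) -> dict:
    """Account for scheduled vs. missing symptom cells.

    A "scheduled" cell is one symptom rating of one person on one calendar
    day of that person's recorded range; rows absent from the panel do not
    count (the generator always emits the full schedule).
    """
    values = dataset.values_matrix()
    scheduled = int(values.size)
    missing = int(np.isnan(values).sum())
    return {
        "scheduled_cells": scheduled,
        "missing_cells": missing,
        "missing_percent": missing_percentage(missing, scheduled),
    }


def missing_percentage(n_missing: int, n_scheduled: int, decimals: int = 2) -> float:
    """Percentage of missing cells, rounded half-away-from-zero."""
    if n_scheduled <= 0:
        raise ValueError("n_scheduled must be positive")
    pct = 100.0 * n_missing / n_scheduled
    scale = 10**decimals
    return float(np.floor(pct * scale + 0.5) / scale)


def scheduled_cells(n_persons: int, n_days: int, n_vars: int) -> int:
    """Total symptom cells implied by a complete assessment schedule."""
    if min(n_persons, n_days, n_vars) < 1:
        raise ValueError("all design dimensions must be >= 1")
    return int(n_persons) * int(n_days) * int(n_vars)
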