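"""BMI weight-state space, participant categorization and cohort inclusion filters.

The state space is the CDC's four BMI categories, in a fixed total order:

======  ============  ==================
index   label         BMI (kg/m^2)
======  ============  ==================
0       underweight   bmi < 18.5
1       normal        18.5 <= bmi < 25
2       overweight    25 <= bmi < 30
3       obese         bmi >= 30
======  ============  ==================

Intervals are half-open on the right, so every finite positive BMI maps to
exactly one state (BMI = 30.0 is obese).  A participant contributes one
origin state (weight ten years ago) and one destination state (current
weight); because surveys record no historical height, the current measured
height is used for both time points unless a precomputed past BMI is
supplied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "WeightState",
    "STATE_LABELS",
    "BMI_EDGES",
    "CohortRecord",
    "Cohort",
    "FilterReport",
    "categorize_bmi",
    "categorize_bmi_array",
    "state_pair",
    "state_pairs",
    "current_states",
    "apply_inclusion_filters",
]

STATE_LABELS: tuple[str, ...] = ("underweight", "normal", "overweight", "obese")

#: Right-open category boundaries: [.., 18.5), [18.5, 25), [25, 30), [30, ..)
BMI_EDGES: tuple[float, float, float] = (18.5, 25.0, 30.0)

SEX_LEVELS: tuple[str, ...] = ("male", "female")
RACE_LEVELS: tuple[str, ...] = ("white", "hispanic", "black", "asian", "other")

REQUIRED_COLUMNS: tuple[str, ...] = (
    "id",
    "age",
    "sex",
    "race",
    "weight_now_kg",
    "weight_10y_ago_kg",
    "height_m",
)


class WeightState(IntEnum):
    """One of the four ordered CDC BMI categories."""

    UNDERWEIGHT = 0
    NORMAL = 1
    OVERWEIGHT = 2
    OBESE = 3

    @property
    def label(self) -> str:
        return STATE_LABELS[self.value]

    @classmethod
    def from_label(cls, label: str) -> "WeightState":
        try:
            return cls(STATE_LABELS.index(str(label).strip().lower()))
        except ValueError:
            raise InvalidInputError(f"unknown weight state label: {label!r}") from None

    @classmethod
    def from_bmi(cls, bmi: float) -> "WeightState":
        return categorize_bmi(bmi)


def categorize_bmi(bmi: float) -> WeightState:
    """Map a BMI value (kg/m^2) to its weight state.

    Raises
    ------
    InvalidInputError
        If ``bmi`` is non-finite or non-positive.
    """
    bmi = float(bmi)
    if not np.isfinite(bmi) or bmi <= 0:
        raise InvalidInputError(f"BMI must be finite and positive, got {bmi!r}")
    return WeightState(int(np.searchsorted(BMI_EDGES, bmi, side="right")))


def categorize_bmi_array(bmi: np.ndarray) -> np.ndarray:
    """Vectorized :func:`categorize_bmi`; returns int state indices 0..3."""
    bmi = np.asarray(bmi, dtype=float)
    if bmi.size and (not np.all(np.isfinite(bmi)) or np.any(bmi <= 0)):
        raise InvalidInputError("all BMI values must be finite and positive")
    return np.searchsorted(np.asarray(BMI_EDGES), bmi, side="right").astype(np.int64)


@dataclass
class CohortRecord:
    """One participant: covariates plus weights at two time points a decade apart."""

    id: str
    age: float
    sex: str
    race: str
    weight_now_kg: float
    weight_10y_ago_kg: float
    height_m: float
    extras: dict = field(default_factory=dict)

    def bmi_now(self) -> float:
        return self.weight_now_kg / self.height_m**2

    def bmi_10y_ago(self) -> float:
        return self.weight_10y_ago_kg / self.height_m**2


@dataclass
class Cohort:
    """An ordered collection of participants, backed by a pandas DataFrame.

    The frame must carry :data:`REQUIRED_COLUMNS`; any additional columns are
    treated as extra covariates. ``ids`` must be unique.
    """

    data: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise InvalidInputError(f"cohort frame is missing columns: {missing}")
        ids = self.data["id"]
        if ids.notna().sum() and ids.dropna().duplicated().any():
            dupes = ids[ids.duplicated()].head(3).tolist()
            raise InvalidInputError(f"cohort ids must be unique; duplicates include {dupes}")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def extra_columns(self) -> tuple[str, ...]:
        return tuple(c for c in self.data.columns if c not in REQUIRED_COLUMNS)

    def records(self) -> Iterator[CohortRecord]:
        extra_cols = self.extra_columns
        for row in self.data.itertuples(index=False):
            d = row._asdict()
            yield CohortRecord(
                id=str(d["id"]),
                age=float(d["age"]),
                sex=d["sex"],
                race=d["race"],
                weight_now_kg=float(d["weight_now_kg"]),
                weight_10y_ago_kg=float(d["weight_10y_ago_kg"]),
                height_m=float(d["height_m"]),
                extras={c: d[c] for c in extra_cols},
            )

    @classmethod
    def from_records(cls, records: Sequence[CohortRecord], provenance: str = "") -> "Cohort":
        rows = []
        for r in records:
            row = {
                "id": r.id,
                "age": r.age,
                "sex": r.sex,
                "race": r.race,
                "weight_now_kg": r.weight_now_kg,
                "weight_10y_ago_kg": r.weight_10y_ago_kg,
                "height_m": r.height_m,
            }
            row.update(r.extras)
            rows.append(row)
        return cls(pd.DataFrame(rows, columns=None), provenance=provenance)

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str | None = None) -> "Cohort":
        """Read the standard cohort CSV (header row; empty fields = missing)."""
        frame = pd.read_csv(path, dtype={"id": str})
        return cls(frame, provenance=provenance if provenance is not None else str(path))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def state_pair(record: CohortRecord, past_bmi: float | None = None) -> tuple[WeightState, WeightState]:
    """Classify a participant at both time points.

    Origin uses the weight ten years ago, destination the current weight;
    the current measured height enters both BMIs unless ``past_bmi`` is
    given (for sources that supply a precomputed historical BMI).
    """
    if record.height_m is None or not np.isfinite(record.height_m) or record.height_m <= 0:
        raise InvalidInputError(f"record {record.id!r}: height must be positive, got {record.height_m!r}")
    origin_bmi = past_bmi if past_bmi is not None else record.bmi_10y_ago()
    return categorize_bmi(origin_bmi), categorize_bmi(record.bmi_now())


def state_pairs(cohort: Cohort, past_bmi_column: str | None = None) -> np.ndarray:
    """(n, 2) int array of (origin, destination) state indices for a cohort."""
    d = cohort.data
    h2 = d["height_m"].to_numpy(float) ** 2
    if past_bmi_column is not None:
        origin_bmi = d[past_bmi_column].to_numpy(float)
    else:
        origin_bmi = d["weight_10y_ago_kg"].to_numpy(float) / h2
    dest_bmi = d["weight_now_kg"].to_numpy(float) / h2
    return np.column_stack([categorize_bmi_array(origin_bmi), categorize_bmi_array(dest_bmi)])


def current_states(cohort: Cohort) -> np.ndarray:
    """Int state indices of each participant at survey time."""
    d = cohort.data
    bmi = d["weight_now_kg"].to_numpy(float) / d["height_m"].to_numpy(float) ** 2
    return categorize_bmi_array(bmi)


@dataclass
class FilterReport:
    """Outcome of :func:`apply_inclusion_filters`."""

    filtered: Cohort
    removed: dict[str, int]  # rule name -> count, in application order
    n_input: int

    @property
    def n_retained(self) -> int:
        return len(self.filtered)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"n_input": self.n_input, "n_retained": self.n_retained, "removed": self.removed},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def apply_inclusion_filters(
    cohort: Cohort,
    min_age: float = 18.0,
    weight_bounds: tuple[float, float] = (20.0, 350.0),
    strict_categories: bool = False,
) -> FilterReport:
    """Apply the cohort inclusion rules and report per-rule exclusion counts.

    Rules, in order:

    1. ``adult``: age present and >= ``min_age`` (inclusive).
    2. ``complete_weights``: both weights and the height are present.
    3. ``plausible_values``: weights within ``weight_bounds`` (kg) and
       height positive.

    Sex/race levels outside the fixed vocabularies are remapped to
    ``"other"`` (race) or dropped under rule ``known_categories`` when
    ``strict_categories`` is set.

    An empty cohort yields an empty cohort with a zeroed report.
    """
    d = cohort.data.copy()
    removed: dict[str, int] = {}
    n_input = len(d)

    age = pd.to_numeric(d["age"], errors="coerce")
    keep = age.notna() & (age >= min_age)
    removed["adult"] = int((~keep).sum())
    d = d[keep]

    wn = pd.to_numeric(d["weight_now_kg"], errors="coerce")
    wp = pd.to_numeric(d["weight_10y_ago_kg"], errors="coerce")
    h = pd.to_numeric(d["height_m"], errors="coerce")
    keep = wn.notna() & wp.notna() & h.notna()
    removed["complete_weights"] = int((~keep).sum())
    d = d[keep]

    wn, wp, h = wn[keep], wp[keep], h[keep]
    lo, hi = weight_bounds
    keep = (wn >= lo) & (wn <= hi) & (wp >= lo) & (wp <= hi) & (h > 0)
    removed["plausible_values"] = int((~keep).sum())
    d = d[keep]

    sex = d["sex"].astype(str).str.strip().str.lower()
    race = d["race"].astype(str).str.strip().str.lower()
    if strict_categories:
        keep = sex.isin(SEX_LEVELS) & race.isin(RACE_LEVELS)
        removed["known_categories"] = int((~keep).sum())
        d = d[keep]
        sex, race = sex[keep], race[keep]
    else:
        race = race.where(race.isin(RACE_LEVELS), "other")
    d = d.assign(sex=sex, race=race)

    filtered = Cohort(d.reset_index(drop=True), provenance=cohort.provenance)
    return FilterReport(filtered=filtered, removed=removed, n_input=n_input)
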