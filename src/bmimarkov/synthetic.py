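"""Synthetic NHANES-like cohort generation with known ground truth.

The generator draws, per participant: demographic covariates from
configurable marginals (age truncated at adulthood, sex split, race mix);
an origin weight state from a baseline mix; and a destination state from
the ground-truth transition-matrix row, optionally with covariate effects
entering as additive shifts on the destination log-odds (multinomial-logit
form). Heights are sex-specific normals, and weights are placed strictly
inside each assigned state's BMI band so that categorization recovers the
intended states for every record.

Within-band dynamics: participants who stay in their category get a
destination BMI equal to their origin BMI plus a small positive-drift
Gaussian perturbation truncated to the band interior, emulating the modest
mean weight gain seen over a decade in US adults; movers draw uniformly
inside the destination band interior.

Defaults mirror the NHANES 2017-2020 weight-history cohort: n = 6146,
baseline state mix (87, 2058, 1376, 2625)/6146, the published decade
transition matrix (renormalized), age 58.39 (SD 12.94), 49/51 male/female,
race mix White 37% / Hispanic 20% / Black 27% / Asian 12% / Other 4%.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import ConfigurationError
from .states import BMI_EDGES, RACE_LEVELS, SEX_LEVELS, STATE_LABELS, Cohort
from .transitions import NHANES_REFERENCE_PERCENT, N_STATES

__all__ = ["CovariateEffect", "SyntheticConfig", "generate_cohort", "default_nhanes_config"]

# Band interiors for BMI placement; margin keeps draws off category edges so
# labels are recovered exactly. The obese band is right-truncated at a
# configurable maximum to avoid absurd weights; the underweight band is
# left-truncated at 14.
_BMI_FLOOR = 14.0


class CovariateEffect(BaseModel):
    """Additive shift on a destination's log-odds, per unit of a covariate.

    For a numeric covariate the shift is ``coefficient * (value - center) /
    scale`` (defaults: center 58.39, scale 10 — i.e. per decade of age).
    For a categorical covariate, ``level`` selects who receives the flat
    ``coefficient`` shift. ``origins`` restricts which origin-state rows are
    affected (default: all).
    """

    covariate: str
    destination: Literal["underweight", "normal", "overweight", "obese"]
    coefficient: float
    level: Optional[str] = None
    origins: Optional[list[Literal["underweight", "normal", "overweight", "obese"]]] = None
    center: float = 58.39
    scale: float = 10.0

    def shift(self, values: pd.Series) -> np.ndarray:
        if self.level is not None:
            return self.coefficient * (values.astype(str) == self.level).to_numpy(float)
        v = pd.to_numeric(values, errors="coerce").to_numpy(float)
        return self.coefficient * (v - self.center) / self.scale

    def origin_mask(self) -> np.ndarray:
        if self.origins is None:
            return np.ones(N_STATES, dtype=bool)
        mask = np.zeros(N_STATES, dtype=bool)
        for o in self.origins:
            mask[STATE_LABELS.index(o)] = True
        return mask


class SyntheticConfig(BaseModel):
    """Validated parameters of the synthetic cohort generator."""

    n: int = Field(default=6146, ge=1)
    seed: int = 0
    baseline_mix: list[float] = Field(default_factory=lambda: [0.01, 0.33, 0.22, 0.44])
    true_matrix: list[list[float]] = Field(
        default_factory=lambda: (
            NHANES_REFERENCE_PERCENT / NHANES_REFERENCE_PERCENT.sum(axis=1, keepdims=True)
        ).tolist()
    )
    age_mean: float = 58.39
    age_sd: float = 12.94
    min_age: float = 18.0
    female_share: float = Field(default=0.51, ge=0.0, le=1.0)
    race_mix: dict[str, float] = Field(
        default_factory=lambda: {"white": 0.37, "hispanic": 0.20, "black": 0.27, "asian": 0.12, "other": 0.04}
    )
    effects: list[CovariateEffect] = Field(default_factory=list)
    bmi_margin: float = Field(default=0.2, gt=0.0)
    obese_bmi_max: float = Field(default=45.0, gt=30.0)
    stay_drift_bmi: float = 1.2  # mean within-band BMI change for stayers
    stay_sd_bmi: float = Field(default=3.2, ge=0.0)  # its SD (weight_noise analogue)
    height_mean_male: float = 1.76
    height_mean_female: float = 1.62
    height_sd: float = 0.07

    @field_validator("baseline_mix")
    @classmethod
    def _check_mix(cls, v: list[float]) -> list[float]:
        arr = np.asarray(v, float)
        if arr.shape != (N_STATES,) or np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-6:
            raise ValueError("baseline_mix must be 4 nonnegative values summing to 1")
        return (arr / arr.sum()).tolist()

    @field_validator("true_matrix")
    @classmethod
    def _check_matrix(cls, v: list[list[float]]) -> list[list[float]]:
        arr = np.asarray(v, float)
        if arr.shape != (N_STATES, N_STATES) or np.any(arr < 0):
            raise ValueError("true_matrix must be a nonnegative 4x4 matrix")
        if np.any(np.abs(arr.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("true_matrix rows must sum to 1")
        return (arr / arr.sum(axis=1, keepdims=True)).tolist()

    @model_validator(mode="after")
    def _check_race(self) -> "SyntheticConfig":
        bad = [r for r in self.race_mix if r not in RACE_LEVELS]
        if bad:
            raise ValueError(f"unknown race level(s) in race_mix: {bad}")
        total = sum(self.race_mix.values())
        if total <= 0:
            raise ValueError("race_mix must have positive total mass")
        self.race_mix = {k: v / total for k, v in self.race_mix.items()}
        for eff in self.effects:
            if eff.covariate not in ("age", "sex", "race"):
                raise ValueError(f"effects may only reference age/sex/race, got {eff.covariate!r}")
        return self

    def band_interiors(self) -> np.ndarray:
        """(4, 2) BMI draw intervals, strictly inside category bands."""
        lo = np.array([_BMI_FLOOR, BMI_EDGES[0], BMI_EDGES[1], BMI_EDGES[2]])
        hi = np.array([BMI_EDGES[0], BMI_EDGES[1], BMI_EDGES[2], self.obese_bmi_max])
        bands = np.column_stack([lo + self.bmi_margin, hi - self.bmi_margin])
        bands[3, 1] = self.obese_bmi_max  # margin only at the lower obese edge
        if np.any(bands[:, 1] - bands[:, 0] < 0.2):
            raise ConfigurationError("bmi_margin leaves a band interior narrower than 0.2")
        return bands

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.model_dump(), indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def default_nhanes_config(n: int = 6146, seed: int = 0, **overrides) -> SyntheticConfig:
    """Configuration mirroring the NHANES 2017-2020 weight-history cohort.

    Baseline mix and race mix use the published category counts as exact
    ratios; the ground-truth matrix is the published decade matrix with
    rows renormalized to sum to 1.
    """
    params = dict(
        n=n,
        seed=seed,
        baseline_mix=(np.array([87, 2058, 1376, 2625]) / 6146).tolist(),
        age_mean=58.39,
        age_sd=12.94,
        female_share=3122 / 6146,
        race_mix={
            "white": 2252 / 6146,
            "hispanic": 1257 / 6146,
            "black": 1636 / 6146,
            "asian": 739 / 6146,
            "other": 262 / 6146,
        },
    )
    params.update(overrides)
    return SyntheticConfig(**params)


def _truncated_normal(rng: np.random.Generator, mean, sd, low, high, size) -> np.ndarray:
    """Rejection-sampled truncated normal (bounds far enough for quick acceptance)."""
    out = rng.normal(mean, sd, size)
    bad = (out < low) | (out > high)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum())) if np.isscalar(mean) else rng.normal(
            np.broadcast_to(mean, out.shape)[bad], sd, int(bad.sum())
        )
        bad = (out < low) | (out > high)
    return out


def _destination_probs(config: SyntheticConfig, origin: np.ndarray, frame: pd.DataFrame) -> np.ndarray:
    """(n, 4) per-record destination probabilities with effect shifts applied."""
    P = np.asarray(config.true_matrix)
    probs = P[origin]
    if not config.effects:
        return probs
    with np.errstate(divide="ignore"):
        logits = np.log(probs)
    for eff in config.effects:
        dest_idx = STATE_LABELS.index(eff.destination)
        shift = eff.shift(frame[eff.covariate])
        affected = eff.origin_mask()[origin]
        logits[:, dest_idx] += np.where(affected, shift, 0.0)
    logits -= logits.max(axis=1, keepdims=True)
    out = np.exp(logits)
    out /= out.sum(axis=1, keepdims=True)
    return out


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Draw a cohort from the generator; deterministic given ``config.seed``.

    Returned records always satisfy the inclusion filters, and categorizing
    their weights recovers the intended origin/destination states exactly.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n

    sex = np.where(rng.random(n) < config.female_share, "female", "male")
    races = list(config.race_mix)
    race = rng.choice(races, size=n, p=[config.race_mix[r] for r in races])
    age = _truncated_normal(rng, config.age_mean, config.age_sd, config.min_age, 110.0, n)

    origin = rng.choice(N_STATES, size=n, p=np.asarray(config.baseline_mix))

    frame = pd.DataFrame({"age": np.round(age, 1), "sex": sex, "race": race})
    probs = _destination_probs(config, origin, frame)
    u = rng.random(n)[:, None]
    destination = (probs.cumsum(axis=1) < u).sum(axis=1)
    destination = np.minimum(destination, N_STATES - 1)

    bands = config.band_interiors()
    origin_bmi = rng.uniform(bands[origin, 0], bands[origin, 1])

    stay = destination == origin
    dest_bmi = np.empty(n)
    if np.any(stay):
        lo = bands[destination[stay], 0]
        hi = bands[destination[stay], 1]
        dest_bmi[stay] = np.clip(
            origin_bmi[stay] + rng.normal(config.stay_drift_bmi, config.stay_sd_bmi, int(stay.sum())),
            lo,
            hi,
        )
    if np.any(~stay):
        mv = ~stay
        dest_bmi[mv] = rng.uniform(bands[destination[mv], 0], bands[destination[mv], 1])

    height = np.where(
        sex == "female",
        rng.normal(config.height_mean_female, config.height_sd, n),
        rng.normal(config.height_mean_male, config.height_sd, n),
    )
    height = np.clip(height, 1.40, 2.10)

    data = pd.DataFrame(
        {
            "id": [f"S{i:06d}" for i in range(n)],
            "age": frame["age"],
            "sex": sex,
            "race": race,
            "weight_now_kg": dest_bmi * height**2,
            "weight_10y_ago_kg": origin_bmi * height**2,
            "height_m": height,
        }
    )
    return Cohort(data, provenance=f"synthetic(seed={config.seed}, n={n})")
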