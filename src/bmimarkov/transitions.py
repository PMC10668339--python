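"""Decade transition-matrix estimation: overall, by subgroup, and the
published NHANES 2017-2020 reference matrix.

A transition matrix here is 4x4 and row-stochastic: rows are origin states
(weight category ten years ago), columns are destination states (category at
survey time), in the fixed order underweight / normal / overweight / obese.
Estimation is multinomial maximum likelihood per row, optionally with an
additive (Laplace) pseudo-count for sparse subgroups:

    p_ij = (c_ij + a) / (n_i + 4 a)

With ``a = 0`` an origin state that was never observed has an undefined row;
the default policy makes that row self-absorbing (probability one of
staying), with a logged warning.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EstimationError, InvalidInputError
from .states import STATE_LABELS, Cohort, WeightState, state_pairs

__all__ = [
    "TransitionMatrix",
    "SubgroupEstimates",
    "estimate_matrix",
    "estimate_from_cohort",
    "estimate_by_subgroup",
    "nhanes_reference_matrix",
    "NHANES_REFERENCE_PERCENT",
]

logger = logging.getLogger(__name__)

N_STATES = 4

#: Decade transition percentages reported for the NHANES 2017-2020
#: weight-history cohort (rows = origin, cols = destination). Rows are kept
#: verbatim: the underweight row sums to 101 and the obese row to 99 because
#: the published figures are rounded to whole percent.
NHANES_REFERENCE_PERCENT = np.array(
    [
        [65.0, 32.0, 2.0, 2.0],
        [3.0, 78.0, 17.0, 2.0],
        [0.0, 14.0, 71.0, 15.0],
        [0.0, 1.0, 14.0, 84.0],
    ]
)

ZeroRowPolicy = Literal["self", "uniform", "error"]


@dataclass
class TransitionMatrix:
    """A 4x4 row-stochastic matrix with its underlying counts.

    Attributes
    ----------
    probs : (4, 4) float array, rows sum to 1 (unless built from verbatim
        rounded percentages with ``renormalize=False``).
    counts : (4, 4) int array of observed transitions, or None when the
        matrix does not come from data (e.g. the published reference).
    smoothing : additive pseudo-count used during estimation.
    provenance : free-text source tag.
    """

    probs: np.ndarray
    counts: np.ndarray | None = None
    smoothing: float = 0.0
    provenance: str = ""
    states: tuple[str, ...] = STATE_LABELS

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (N_STATES, N_STATES):
            raise InvalidInputError(f"probs must be 4x4, got {self.probs.shape}")
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            raise InvalidInputError("transition probabilities must lie in [0, 1]")
        if self.counts is not None:
            self.counts = np.asarray(self.counts)
            if self.counts.shape != (N_STATES, N_STATES) or np.any(self.counts < 0):
                raise InvalidInputError("counts must be a nonnegative 4x4 matrix")

    @property
    def n_per_origin(self) -> np.ndarray:
        if self.counts is None:
            return np.zeros(N_STATES, dtype=int)
        return self.counts.sum(axis=1).astype(int)

    @property
    def row_sums(self) -> np.ndarray:
        return self.probs.sum(axis=1)

    @property
    def is_row_stochastic(self) -> bool:
        return bool(np.all(np.abs(self.row_sums - 1.0) < 1e-9))

    def row(self, origin: WeightState | int | str) -> np.ndarray:
        if isinstance(origin, str):
            origin = WeightState.from_label(origin)
        return self.probs[int(origin)].copy()

    def renormalized(self) -> "TransitionMatrix":
        """Divide each row by its sum; raw values are left untouched on self."""
        sums = self.row_sums
        if np.any(sums <= 0):
            raise EstimationError("cannot renormalize a matrix with a zero row")
        return replace(self, probs=self.probs / sums[:, None])

    def max_abs_diff(self, other: "TransitionMatrix | np.ndarray") -> float:
        other_probs = other.probs if isinstance(other, TransitionMatrix) else np.asarray(other)
        return float(np.max(np.abs(self.probs - other_probs)))

    # -- serialization ----------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=list(self.states), columns=list(self.states))

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index_label="state")

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str | None = None) -> "TransitionMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(frame.to_numpy(float), provenance=provenance or str(path))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "states": list(self.states),
                "probs": self.probs.tolist(),
                "counts": None if self.counts is None else np.asarray(self.counts).tolist(),
                "smoothing": self.smoothing,
                "provenance": self.provenance,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "TransitionMatrix":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        counts = None if d.get("counts") is None else np.asarray(d["counts"])
        return cls(
            np.asarray(d["probs"], float),
            counts=counts,
            smoothing=float(d.get("smoothing", 0.0)),
            provenance=d.get("provenance", ""),
            states=tuple(d.get("states", STATE_LABELS)),
        )


def _pairs_to_counts(pairs: np.ndarray) -> np.ndarray:
    pairs = np.asarray(pairs, dtype=np.int64)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise InvalidInputError("pairs must be an (n, 2) array of state indices")
    if pairs.size and (pairs.min() < 0 or pairs.max() >= N_STATES):
        raise InvalidInputError("state indices must lie in 0..3")
    codes = pairs[:, 0] * N_STATES + pairs[:, 1]
    return np.bincount(codes, minlength=N_STATES * N_STATES).reshape(N_STATES, N_STATES)


def counts_to_probs(
    counts: np.ndarray,
    smoothing: float = 0.0,
    zero_row_policy: ZeroRowPolicy = "self",
) -> np.ndarray:
    """Row-wise additive-smoothing MLE, resolving unobserved origin rows."""
    counts = np.asarray(counts, dtype=float)
    n_i = counts.sum(axis=1)
    denom = n_i + N_STATES * smoothing
    probs = np.empty_like(counts)
    observed = denom > 0
    probs[observed] = (counts[observed] + smoothing) / denom[observed, None]
    if not observed.all():
        empty = np.flatnonzero(~observed)
        if zero_row_policy == "error":
            raise EstimationError(f"origin state(s) {empty.tolist()} have no observations")
        for i in empty:
            if zero_row_policy == "uniform":
                probs[i] = 1.0 / N_STATES
            else:  # self-absorbing
                probs[i] = 0.0
                probs[i, i] = 1.0
        logger.warning(
            "origin state(s) %s unobserved; applied %r row policy",
            [STATE_LABELS[i] for i in empty],
            zero_row_policy,
        )
    return probs


def estimate_matrix(
    pairs: Iterable[tuple[int, int]] | np.ndarray,
    smoothing: float = 0.0,
    zero_row_policy: ZeroRowPolicy = "self",
    provenance: str = "",
) -> TransitionMatrix:
    """Estimate the decade transition matrix from (origin, destination) pairs.

    Parameters
    ----------
    pairs : (n, 2) array-like of state indices (or WeightState values).
    smoothing : additive pseudo-count ``a`` in ``(c_ij + a) / (n_i + 4a)``;
        default 0 gives the pure MLE.
    zero_row_policy : how to resolve an origin state with zero observations
        when smoothing is 0: ``"self"`` (default, self-absorbing row with a
        warning), ``"uniform"`` or ``"error"``.
    """
    pairs = np.asarray([(int(o), int(d)) for o, d in pairs] if not isinstance(pairs, np.ndarray) else pairs)
    if pairs.size == 0:
        raise EstimationError("cannot estimate a transition matrix from zero pairs")
    if smoothing < 0:
        raise InvalidInputError("smoothing pseudo-count must be >= 0")
    counts = _pairs_to_counts(pairs)
    probs = counts_to_probs(counts, smoothing=smoothing, zero_row_policy=zero_row_policy)
    return TransitionMatrix(probs, counts=counts, smoothing=smoothing, provenance=provenance)


def estimate_from_cohort(
    cohort: Cohort,
    smoothing: float = 0.0,
    zero_row_policy: ZeroRowPolicy = "self",
    past_bmi_column: str | None = None,
) -> TransitionMatrix:
    """Estimate the decade transition matrix directly from a filtered cohort."""
    if len(cohort) == 0:
        raise EstimationError("cohort is empty")
    return estimate_matrix(
        state_pairs(cohort, past_bmi_column=past_bmi_column),
        smoothing=smoothing,
        zero_row_policy=zero_row_policy,
        provenance=cohort.provenance or "cohort",
    )


@dataclass
class SubgroupEstimates:
    """Per-subgroup transition matrices from :func:`estimate_by_subgroup`.

    Maps a tuple of covariate levels (in ``key_vars`` order) to its
    TransitionMatrix. Subgroups smaller than ``min_size`` are estimated
    anyway but listed in ``flagged_small``.
    """

    key_vars: tuple[str, ...]
    matrices: dict[tuple, TransitionMatrix]
    sizes: dict[tuple, int]
    flagged_small: set = field(default_factory=set)

    def __getitem__(self, key) -> TransitionMatrix:
        if not isinstance(key, tuple):
            key = (key,)
        return self.matrices[key]

    def __iter__(self):
        return iter(self.matrices)

    def __len__(self) -> int:
        return len(self.matrices)


def estimate_by_subgroup(
    cohort: Cohort,
    key_vars: list[str] | tuple[str, ...],
    smoothing: float = 0.0,
    zero_row_policy: ZeroRowPolicy = "self",
    min_size: int = 50,
) -> SubgroupEstimates:
    """One transition matrix per observed combination of ``key_vars`` levels.

    With ``key_vars=[]`` this degenerates to a single whole-cohort estimate
    under the empty key ``()``.
    """
    key_vars = tuple(key_vars)
    missing = [v for v in key_vars if v not in cohort.data.columns]
    if missing:
        raise ConfigurationError(f"subgroup variables not in cohort: {missing}")
    if len(cohort) == 0:
        raise EstimationError("cohort is empty")

    pairs = state_pairs(cohort)
    matrices: dict[tuple, TransitionMatrix] = {}
    sizes: dict[tuple, int] = {}
    flagged: set = set()

    if not key_vars:
        groups: Iterable[tuple[tuple, np.ndarray]] = [((), np.arange(len(cohort)))]
    else:
        # pandas .indices maps key -> positional indices
        groups = [
            (k if isinstance(k, tuple) else (k,), np.asarray(v))
            for k, v in cohort.data.groupby(list(key_vars), observed=True, sort=True).indices.items()
        ]

    for key, idx in groups:
        label = ", ".join(f"{v}={lv}" for v, lv in zip(key_vars, key)) or "all"
        matrices[key] = estimate_matrix(
            pairs[idx],
            smoothing=smoothing,
            zero_row_policy=zero_row_policy,
            provenance=f"subgroup({label})",
        )
        sizes[key] = int(len(idx))
        if len(idx) < min_size:
            flagged.add(key)
            logger.warning("subgroup %s has only %d records (< %d)", label, len(idx), min_size)

    return SubgroupEstimates(key_vars=key_vars, matrices=matrices, sizes=sizes, flagged_small=flagged)


def nhanes_reference_matrix(renormalize: bool = False) -> TransitionMatrix:
    """The published NHANES 2017-2020 decade transition matrix.

    With ``renormalize=False`` (default) the rounded percentages are returned
    verbatim (rows sum to 0.99-1.01); with ``renormalize=True`` each row is
    divided by its sum, which is the form used for multi-decade projection.
    """
    m = TransitionMatrix(
        NHANES_REFERENCE_PERCENT / 100.0,
        counts=None,
        smoothing=0.0,
        provenance="NHANES 2017-2020 published decade transitions (rounded percent)",
    )
    return m.renormalized() if renormalize else m
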