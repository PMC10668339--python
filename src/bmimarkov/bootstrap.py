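"""Bootstrap uncertainty for transition matrices and projected trajectories.

The resampling unit is the participant (a paired origin/destination
observation), drawn with replacement at the original cohort size. Each
replicate re-estimates the transition matrix — and, for trajectories, the
baseline distribution from the same resample — and percentile intervals
(default 95%) are taken per matrix entry or per (decade, state) cell.

Replicate streams are fully reproducible from ``(cohort, B, seed)``: a
single ``numpy.random.default_rng(seed)`` generates all resample indices in
order, so replicate ``b`` is identical regardless of chunking.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import EstimationError, InvalidInputError
from .states import Cohort, current_states, state_pairs
from .transitions import (
    N_STATES,
    TransitionMatrix,
    ZeroRowPolicy,
    counts_to_probs,
    estimate_matrix,
)
from .projection import StateDistribution, Trajectory, baseline_distribution, project_forward

__all__ = ["MatrixBootstrap", "TrajectoryBootstrap", "bootstrap_matrices", "bootstrap_trajectories"]

_CHUNK_ELEMENTS = 20_000_000  # cap on B*n index elements held at once


@dataclass
class MatrixBootstrap:
    """Percentile bands for each transition-matrix entry."""

    point: TransitionMatrix
    low: np.ndarray  # (4, 4)
    high: np.ndarray  # (4, 4)
    replicates: np.ndarray  # (B, 4, 4) replicate probability matrices
    B: int
    seed: int
    level: float

    @property
    def point_within_bands(self) -> bool:
        """Sanity check: full-cohort estimate inside its own bands everywhere."""
        return bool(
            np.all(self.point.probs >= self.low - 1e-12)
            and np.all(self.point.probs <= self.high + 1e-12)
        )

    def dump_replicates(self, directory: str | Path) -> None:
        """Write each replicate matrix as a numbered CSV."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        width = len(str(self.B - 1))
        for b in range(self.B):
            TransitionMatrix(self.replicates[b], provenance=f"bootstrap replicate {b}").to_csv(
                directory / f"replicate_{b:0{width}d}.csv"
            )


@dataclass
class TrajectoryBootstrap:
    """A point trajectory with per-(decade, state) percentile bands attached."""

    trajectory: Trajectory  # carries ci_low / ci_high
    B: int
    seed: int
    level: float

    @property
    def band_widths(self) -> np.ndarray:
        return self.trajectory.ci_high - self.trajectory.ci_low


def _replicate_counts(codes: np.ndarray, B: int, rng: np.random.Generator) -> np.ndarray:
    """(B, 4, 4) transition-count arrays from patient resampling.

    ``codes`` is the length-n array origin*4 + destination. Chunked so at
    most ~_CHUNK_ELEMENTS resampled indices exist at once.
    """
    n = codes.shape[0]
    n_cells = N_STATES * N_STATES
    out = np.empty((B, n_cells), dtype=np.int64)
    chunk = max(1, _CHUNK_ELEMENTS // max(n, 1))
    done = 0
    while done < B:
        b = min(chunk, B - done)
        idx = rng.integers(0, n, size=(b, n))
        resampled = codes[idx] + n_cells * np.arange(b)[:, None]
        flat = np.bincount(resampled.ravel(), minlength=n_cells * b)
        out[done : done + b] = flat.reshape(b, n_cells)
        done += b
    return out.reshape(B, N_STATES, N_STATES)


def _check_args(cohort: Cohort, B: int, level: float) -> None:
    if len(cohort) == 0:
        raise EstimationError("cohort is empty")
    if B < 1:
        raise InvalidInputError("B must be >= 1")
    if not 0 < level < 1:
        raise InvalidInputError("level must be in (0, 1)")


def bootstrap_matrices(
    cohort: Cohort,
    B: int = 1000,
    seed: int = 0,
    smoothing: float = 0.0,
    zero_row_policy: ZeroRowPolicy = "self",
    level: float = 0.95,
) -> MatrixBootstrap:
    """Percentile bootstrap of the transition matrix by patient resampling."""
    _check_args(cohort, B, level)
    pairs = state_pairs(cohort)
    point = estimate_matrix(
        pairs, smoothing=smoothing, zero_row_policy=zero_row_policy, provenance=cohort.provenance
    )
    codes = pairs[:, 0] * N_STATES + pairs[:, 1]
    rng = np.random.default_rng(seed)
    counts = _replicate_counts(codes, B, rng)
    reps = np.stack(
        [counts_to_probs(c, smoothing=smoothing, zero_row_policy=zero_row_policy) for c in counts]
    )
    alpha = (1.0 - level) / 2.0
    low = np.quantile(reps, alpha, axis=0)
    high = np.quantile(reps, 1.0 - alpha, axis=0)
    return MatrixBootstrap(point=point, low=low, high=high, replicates=reps, B=B, seed=seed, level=level)


def bootstrap_trajectories(
    cohort: Cohort,
    B: int = 1000,
    steps: int = 10,
    seed: int = 0,
    smoothing: float = 0.0,
    zero_row_policy: ZeroRowPolicy = "self",
    level: float = 0.95,
) -> TrajectoryBootstrap:
    """Bootstrap bands for the projected prevalence trajectory.

    Each replicate re-estimates the baseline distribution *and* the matrix
    from the same patient resample, projects forward ``steps`` decades, and
    percentile bands are taken per (time_index, state) cell. The point
    trajectory uses the full cohort.
    """
    _check_args(cohort, B, level)
    if steps < 0:
        raise InvalidInputError("steps must be >= 0")

    pairs = state_pairs(cohort)
    codes = pairs[:, 0] * N_STATES + pairs[:, 1]
    rng = np.random.default_rng(seed)
    counts = _replicate_counts(codes, B, rng)  # (B, 4, 4)

    # baseline per replicate = destination-state marginals of the resample
    base = counts.sum(axis=1).astype(float)  # column sums over origins = dest counts
    base /= base.sum(axis=1, keepdims=True)

    P = np.stack(
        [counts_to_probs(c, smoothing=smoothing, zero_row_policy=zero_row_policy) for c in counts]
    )
    paths = np.empty((B, steps + 1, N_STATES))
    v = base
    paths[:, 0] = v
    for k in range(1, steps + 1):
        v = np.einsum("bi,bij->bj", v, P)
        paths[:, k] = v

    alpha = (1.0 - level) / 2.0
    low = np.quantile(paths, alpha, axis=0)
    high = np.quantile(paths, 1.0 - alpha, axis=0)

    point_matrix = estimate_matrix(
        pairs, smoothing=smoothing, zero_row_policy=zero_row_policy, provenance=cohort.provenance
    )
    point = project_forward(baseline_distribution(cohort), point_matrix, steps)
    traj = Trajectory(
        point.distributions,
        provenance=point.provenance,
        ci_low=low,
        ci_high=high,
        ci_level=level,
    )
    return TrajectoryBootstrap(trajectory=traj, B=B, seed=seed, level=level)
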