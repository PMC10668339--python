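"""Discrete-time Markov projection of weight-state prevalence.

State distributions are row vectors; one chain step is one decade:

    v_{t+1} = v_t @ P

Forward projection iterates this map. Backward projection (prevalence
*before* the observation window, used for historical context) solves the
linear system ``v_{t-1} @ P = v_t`` each step; the inverse image of a
distribution need not be a distribution, so negative entries are clipped to
zero and the vector renormalized, with the clipped mass recorded as a
distortion diagnostic. The stationary distribution is the fixed point
``v = v @ P``, computed by power iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import BackwardDistortionError, InvalidInputError, ProjectionError
from .states import STATE_LABELS, Cohort, current_states
from .transitions import N_STATES, TransitionMatrix

__all__ = [
    "StateDistribution",
    "Trajectory",
    "StationaryResult",
    "baseline_distribution",
    "project_forward",
    "project_backward",
    "stationary_distribution",
]


@dataclass
class StateDistribution:
    """A length-4 prevalence vector at a decade offset (0 = survey time)."""

    probs: np.ndarray
    time_index: int = 0
    normalized: bool = True  # False for raw propagation of rounded rows

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (N_STATES,):
            raise InvalidInputError(f"distribution must have length {N_STATES}")
        if np.any(self.probs < -1e-12):
            raise InvalidInputError("distribution entries must be nonnegative")
        if self.normalized and abs(self.probs.sum() - 1.0) > 1e-9:
            raise InvalidInputError(
                f"distribution must sum to 1 (got {self.probs.sum():.12f}); "
                "pass normalized=False for raw vectors"
            )

    def __getitem__(self, state) -> float:
        from .states import WeightState

        if isinstance(state, str):
            state = WeightState.from_label(state)
        return float(self.probs[int(state)])


@dataclass
class Trajectory:
    """A sequence of state distributions at consecutive decade offsets.

    ``ci_low``/``ci_high`` are optional (n_steps+1, 4) percentile bands
    aligned with ``distributions``; ``distortions`` records clipped mass per
    backward step (empty for forward projections).
    """

    distributions: list[StateDistribution]
    provenance: str = ""
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    ci_level: float | None = None
    distortions: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = [d.time_index for d in self.distributions]
        if any(b - a != 1 for a, b in zip(idx, idx[1:])):
            raise InvalidInputError("trajectory time indices must increase by exactly 1")

    def __len__(self) -> int:
        return len(self.distributions)

    @property
    def time_indices(self) -> list[int]:
        return [d.time_index for d in self.distributions]

    @property
    def array(self) -> np.ndarray:
        return np.vstack([d.probs for d in self.distributions])

    def at(self, time_index: int) -> StateDistribution:
        for d in self.distributions:
            if d.time_index == time_index:
                return d
        raise KeyError(f"no distribution at time index {time_index}")

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame: time_index, state, probability[, ci_low, ci_high]."""
        rows = []
        for k, d in enumerate(self.distributions):
            for s, label in enumerate(STATE_LABELS):
                row = {"time_index": d.time_index, "state": label, "probability": d.probs[s]}
                if self.ci_low is not None and self.ci_high is not None:
                    row["ci_low"] = self.ci_low[k, s]
                    row["ci_high"] = self.ci_high[k, s]
                rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, ax=None, show_bands: bool = True):
        """Prevalence-vs-decade line plot (one line per state)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4.5))
        t = self.time_indices
        arr = self.array
        for s, label in enumerate(STATE_LABELS):
            (line,) = ax.plot(t, arr[:, s], marker="o", label=label)
            if show_bands and self.ci_low is not None and self.ci_high is not None:
                ax.fill_between(t, self.ci_low[:, s], self.ci_high[:, s], alpha=0.2, color=line.get_color())
        ax.set_xlabel("time (decades from survey)")
        ax.set_ylabel("prevalence")
        ax.set_ylim(0, 1)
        ax.legend()
        return ax


def baseline_distribution(cohort: Cohort) -> StateDistribution:
    """Current-state prevalences of a filtered cohort (time index 0)."""
    if len(cohort) == 0:
        raise InvalidInputError("cannot compute a baseline distribution from an empty cohort")
    counts = np.bincount(current_states(cohort), minlength=N_STATES)
    return StateDistribution(counts / counts.sum(), time_index=0)


def _matrix_probs(matrix: TransitionMatrix | np.ndarray, renormalize: bool) -> np.ndarray:
    if isinstance(matrix, TransitionMatrix):
        if renormalize:
            return matrix.renormalized().probs
        if not matrix.is_row_stochastic:
            warnings.warn(
                "propagating a matrix whose rows do not sum to 1 "
                f"(row sums {np.round(matrix.row_sums, 4).tolist()}); "
                "raw rounded values are used as given",
                stacklevel=3,
            )
        return matrix.probs
    return np.asarray(matrix, float)


def project_forward(
    start: StateDistribution,
    matrix: TransitionMatrix,
    steps: int,
    renormalize: bool = True,
) -> Trajectory:
    """Iterate ``v <- v @ P`` for ``steps`` decades, starting at ``start``.

    With ``renormalize=False`` the matrix rows are used exactly as given
    (relevant for verbatim rounded percentages, whose one-step products then
    reproduce the printed figures exactly); projected vectors are then not
    forced to sum to 1 and are flagged unnormalized.
    """
    if steps < 0:
        raise InvalidInputError("steps must be >= 0")
    P = _matrix_probs(matrix, renormalize)
    prov = matrix.provenance if isinstance(matrix, TransitionMatrix) else ""
    dists = [start]
    v = start.probs.copy()
    for k in range(1, steps + 1):
        v = v @ P
        dists.append(
            StateDistribution(v.copy(), time_index=start.time_index + k, normalized=renormalize)
        )
    return Trajectory(dists, provenance=prov)


def project_backward(
    end: StateDistribution,
    matrix: TransitionMatrix,
    steps: int,
    distortion_tolerance: float = 0.05,
) -> Trajectory:
    """Infer earlier prevalences by solving ``v_prev @ P = v`` per step.

    The matrix is renormalized before inversion. Negative entries of each
    solution are clipped to zero and the vector renormalized; the clipped
    mass is recorded per step. If a single step clips more than
    ``distortion_tolerance`` total mass, a :class:`BackwardDistortionError`
    is raised carrying the partial trajectory.

    The returned trajectory is in increasing time order, ending at ``end``.
    """
    if steps < 0:
        raise InvalidInputError("steps must be >= 0")
    P = _matrix_probs(matrix, renormalize=True)
    cond = np.linalg.cond(P)
    if not np.isfinite(cond) or cond > 1e12:
        raise ProjectionError(f"transition matrix is singular or near-singular (cond={cond:.3g})")

    prov = matrix.provenance if isinstance(matrix, TransitionMatrix) else ""
    rev: list[StateDistribution] = [end]
    distortions: list[float] = []
    v = end.probs.copy()
    for k in range(1, steps + 1):
        v = np.linalg.solve(P.T, v)
        clipped = float(-v[v < 0].sum()) if np.any(v < 0) else 0.0
        v = np.clip(v, 0.0, None)
        total = v.sum()
        if total <= 0:
            raise ProjectionError("backward step produced a zero vector after clipping")
        v = v / total
        distortions.append(clipped)
        dist = StateDistribution(v.copy(), time_index=end.time_index - k)
        if clipped > distortion_tolerance:
            partial = Trajectory(
                list(reversed(rev)), provenance=prov, distortions=distortions[:-1]
            )
            raise BackwardDistortionError(
                f"backward step {k} clipped {clipped:.4f} probability mass "
                f"(> tolerance {distortion_tolerance})",
                partial_trajectory=partial,
                distortion=clipped,
            )
        rev.append(dist)
    return Trajectory(list(reversed(rev)), provenance=prov, distortions=list(reversed(distortions)))


@dataclass
class StationaryResult:
    """Outcome of :func:`stationary_distribution`."""

    distribution: StateDistribution
    n_iter: int
    unique: bool
    residual: float  # max |v @ P - v|


def stationary_distribution(
    matrix: TransitionMatrix,
    tol: float = 1e-12,
    max_iter: int = 10**6,
) -> StationaryResult:
    """Long-run fixed point of the chain by power iteration from uniform.

    Uniqueness is assessed from the eigenvalue spectrum: a (numerically)
    repeated unit eigenvalue marks a reducible chain whose stationary
    distribution depends on the start, and ``unique`` is set False.
    """
    P = _matrix_probs(matrix, renormalize=True)
    eigvals = np.linalg.eigvals(P)
    unique = int(np.sum(np.abs(eigvals - 1.0) < 1e-9)) == 1

    v = np.full(N_STATES, 1.0 / N_STATES)
    for it in range(1, max_iter + 1):
        v_next = v @ P
        if np.max(np.abs(v_next - v)) < tol:
            v = v_next / v_next.sum()
            residual = float(np.max(np.abs(v @ P - v)))
            return StationaryResult(
                distribution=StateDistribution(v, time_index=0),
                n_iter=it,
                unique=unique,
                residual=residual,
            )
        v = v_next
    raise ProjectionError(f"power iteration did not converge within {max_iter} iterations")
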