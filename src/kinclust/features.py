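"""The six movement features and assembly of normalized feature matrices.

Per (participant, trial, task, DOF) last-segment observation:

- peak angle: signed maximum of the joint angle over the segment;
- range of motion (RoM): max - min;
- path distance (PDist): sum of absolute successive differences of the
  segment resampled to a common length n, so trials of different duration
  are comparable without further normalization;
- mean angle: arithmetic mean over the segment;
- peak angular velocity: maximum of the angle derivative (signed by default,
  absolute behind a switch), degrees/s;
- zero crossings: number of strict sign changes of the angular velocity, a
  smoothness count.

Velocity and zero crossings are computed on the filtered, segmented trace at
native sampling; only PDist uses the resampled trace. Max normalization
(divide each feature column by its maximum absolute value) is applied per
analysis matrix, i.e. per condition-pair x task x DOF x iteration.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .config import RunConfig
from .inventory import DOFS, FEATURE_NAMES
from .preprocessing import last_segment_slice, lowpass_filter, resample_to_length
from .recording import Cohort, TrialRecording

logger = logging.getLogger(__name__)


def peak_angle(trace: np.ndarray) -> float:
    trace = _check_trace(trace)
    return float(np.max(trace))


def range_of_motion(trace: np.ndarray) -> float:
    trace = _check_trace(trace)
    return float(np.max(trace) - np.min(trace))


def path_distance(trace: np.ndarray) -> float:
    """Sum of absolute successive differences (expects the resampled trace)."""
    trace = _check_trace(trace)
    if trace.size < 2:
        raise ValueError("path_distance needs at least 2 samples")
    return float(np.sum(np.abs(np.diff(trace))))


def mean_angle(trace: np.ndarray) -> float:
    trace = _check_trace(trace)
    return float(np.mean(trace))


def angular_velocity(trace: np.ndarray, frame_rate: float) -> np.ndarray:
    """Angle derivative in degrees/s, same length as the trace.

    Central differences at interior samples, one-sided at the ends
    (numpy.gradient), scaled by the frame rate.
    """
    trace = _check_trace(trace)
    if trace.size < 2:
        raise ValueError("angular_velocity needs at least 2 samples")
    return np.gradient(trace) * frame_rate


def peak_angular_velocity(
    trace: np.ndarray, frame_rate: float, absolute: bool = False
) -> float:
    vel = angular_velocity(trace, frame_rate)
    return float(np.max(np.abs(vel))) if absolute else float(np.max(vel))


def zero_crossings(velocity: np.ndarray) -> int:
    """Strict sign changes in a sequence, ignoring interior exact zeros.

    A run like +, 0, - counts as one crossing; leading/trailing zeros are
    ignored entirely.
    """
    velocity = _check_trace(velocity)
    signs = np.sign(velocity)
    signs = signs[signs != 0]
    if signs.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(signs)))


def _check_trace(trace) -> np.ndarray:
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite values")
    return trace.ravel()


def trial_features(
    trial: TrialRecording, config: RunConfig | None = None
) -> list[dict]:
    """Feature rows for one trial: filter, take the last segment, one row per DOF."""
    cfg = config or RunConfig()
    filtered = lowpass_filter(
        trial.angles,
        trial.frame_rate,
        cfg.filter.cutoff_hz,
        cfg.filter.order,
        cfg.filter.mode,
    )
    window = last_segment_slice(trial, cfg.segment)
    segment = filtered[window]
    rows = []
    for d, dof in enumerate(DOFS):
        trace = segment[:, d]
        resampled = resample_to_length(trace, cfg.resample.n)
        vel = angular_velocity(trace, trial.frame_rate)
        rows.append(
            {
                "participant_id": trial.participant_id,
                "condition": trial.condition,
                "task": trial.task,
                "trial_index": trial.trial_index,
                "dof": dof,
                "peak_angle": peak_angle(trace),
                "range_of_motion": range_of_motion(trace),
                "path_distance": path_distance(resampled),
                "mean_angle": mean_angle(trace),
                "peak_angular_velocity": (
                    float(np.max(np.abs(vel)))
                    if cfg.analysis.peak_velocity_abs
                    else float(np.max(vel))
                ),
                "zero_crossings": zero_crossings(vel),
            }
        )
    return rows


def extract_features(dataset: Cohort, config: RunConfig | None = None) -> pd.DataFrame:
    """Tidy feature table: one row per (participant, trial, task, DOF)."""
    rows: list[dict] = []
    for trial in dataset:
        rows.extend(trial_features(trial, config))
    frame = pd.DataFrame(rows)
    logger.info(
        "extracted %d feature rows from %d recordings", len(frame), len(dataset)
    )
    return frame


def max_normalize(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Divide each column by its maximum absolute value; all-zero columns pass through.

    Returns the normalized matrix and the per-column constants used.
    """
    matrix = np.asarray(matrix, dtype=float)
    scales = np.max(np.abs(matrix), axis=0)
    zero_cols = scales == 0
    if np.any(zero_cols):
        warnings.warn(
            f"{int(zero_cols.sum())} all-zero feature column(s) left unnormalized",
            stacklevel=2,
        )
    safe = np.where(zero_cols, 1.0, scales)
    return matrix / safe, scales


def build_feature_matrix(
    features: pd.DataFrame,
    task: str,
    dof: str,
    participants: dict[str, int],
    normalize: bool = True,
    average_trials: bool = False,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Assemble the matrix for one k-means analysis.

    Parameters
    ----------
    features : tidy feature table from :func:`extract_features`.
    task, dof : the analysis cell.
    participants : mapping participant_id -> truth label (0 = norm side,
        1 = bypass side) for the observations entering this analysis.
    normalize : apply max normalization per column of this matrix.
    average_trials : collapse each participant's trials to their mean row.

    Returns (X, truth_labels, row_metadata).
    """
    sub = features[
        (features["task"] == task)
        & (features["dof"] == dof)
        & features["participant_id"].isin(participants)
    ].copy()
    counts = sub.groupby("participant_id").size()
    missing = sorted(set(participants) - set(counts.index))
    if missing:
        raise ValueError(
            f"missing feature observations for task={task} dof={dof}: {missing}"
        )
    if average_trials:
        sub = (
            sub.groupby("participant_id", as_index=False)[list(FEATURE_NAMES)]
            .mean()
            .assign(task=task, dof=dof)
        )
    sub = sub.sort_values(
        ["participant_id"] + (["trial_index"] if "trial_index" in sub else [])
    ).reset_index(drop=True)
    labels = sub["participant_id"].map(participants).to_numpy(int)
    if len(np.unique(labels)) != 2:
        raise ValueError("feature matrix needs observations from both groups")
    X = sub[list(FEATURE_NAMES)].to_numpy(float)
    if normalize:
        X, _ = max_normalize(X)
    return X, labels, sub
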