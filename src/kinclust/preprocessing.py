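"""Filtering, segmentation, analysis-segment selection and resampling.

The pipeline contract is: low-pass filter the whole trial first, then cut
windows around each object manipulation (10 frames before contact to 10
frames after release, closed interval, clamped to trial bounds), keep the
last window only, and — for the path-distance feature — linearly resample the
windowed trace onto a common length.

"4th order, zero lag" Butterworth is realized, by the usual biomechanics
convention, as a 2nd-order filter run forward then backward: the dual pass
squares the magnitude response (effective 4th order) and cancels the phase.
A config switch selects the literal reading (4th order per pass) instead.
"""

from __future__ import annotations

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .config import FilterConfig, ResampleConfig, SegmentConfig
from .recording import TrialRecording


def _design_sos(frame_rate: float, cutoff: float, per_pass_order: int) -> np.ndarray:
    return signal.butter(
        per_pass_order, cutoff, btype="low", fs=frame_rate, output="sos"
    )


def per_pass_order(config: FilterConfig) -> int:
    return config.order // 2 if config.mode == "half_order_dual_pass" else config.order


def lowpass_filter(
    angles: np.ndarray,
    frame_rate: float,
    cutoff_hz: float = 6.0,
    order: int = 4,
    mode: str = "half_order_dual_pass",
) -> np.ndarray:
    """Zero-lag Butterworth low-pass, applied per column.

    Forward-backward (``sosfiltfilt``) application with odd-reflection edge
    padding of 3 x (order + 1) samples bounds end transients on short inputs.
    """
    cfg = FilterConfig(cutoff_hz=cutoff_hz, order=order, mode=mode)
    cfg.validate()
    if frame_rate <= 2 * cutoff_hz:
        raise ValueError(
            f"frame rate {frame_rate} Hz must exceed twice the cutoff {cutoff_hz} Hz"
        )
    angles = np.asarray(angles, dtype=float)
    squeeze = angles.ndim == 1
    if squeeze:
        angles = angles[:, None]
    n_pp = per_pass_order(cfg)
    padlen = 3 * (n_pp + 1)
    if angles.shape[0] <= padlen:
        raise ValueError(
            f"signal of {angles.shape[0]} samples is too short for the "
            f"edge padding of {padlen} samples"
        )
    sos = _design_sos(frame_rate, cutoff_hz, n_pp)
    out = signal.sosfiltfilt(sos, angles, axis=0, padtype="odd", padlen=padlen)
    return out[:, 0] if squeeze else out


def filter_gain(
    freq_hz: float | np.ndarray,
    frame_rate: float,
    cutoff_hz: float = 6.0,
    order: int = 4,
    mode: str = "half_order_dual_pass",
) -> np.ndarray:
    """Magnitude response of the effective (dual-pass) filter at ``freq_hz``.

    The forward-backward application squares the single-pass magnitude; this
    closed form is the oracle the pass/stop-band tests compare against.
    """
    cfg = FilterConfig(cutoff_hz=cutoff_hz, order=order, mode=mode)
    cfg.validate()
    sos = _design_sos(frame_rate, cutoff_hz, per_pass_order(cfg))
    _, h = signal.sosfreqz(sos, worN=np.atleast_1d(freq_hz), fs=frame_rate)
    return np.abs(h) ** 2


class ButterworthLowPass(BaseEstimator, TransformerMixin):
    """Zero-lag Butterworth low-pass as a stateless sklearn transformer.

    Parameters
    ----------
    frame_rate : float
        Sampling rate of the incoming columns, Hz.
    cutoff_hz, order, mode : see :func:`lowpass_filter`.
    """

    def __init__(
        self,
        frame_rate: float = 100.0,
        cutoff_hz: float = 6.0,
        order: int = 4,
        mode: str = "half_order_dual_pass",
    ):
        self.frame_rate = frame_rate
        self.cutoff_hz = cutoff_hz
        self.order = order
        self.mode = mode

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1] if np.ndim(X) == 2 else 1
        return self

    def transform(self, X):
        return lowpass_filter(
            X, self.frame_rate, self.cutoff_hz, self.order, self.mode
        )


def segment_trial(
    trial: TrialRecording, pre_frames: int = 10, post_frames: int = 10
) -> list[tuple[int, int, int]]:
    """Windows (start_frame, end_frame, object_index), one per event pair.

    Each closed window runs from ``contact - pre_frames`` to
    ``release + post_frames``, clamped to the trial bounds, ordered by
    object index.
    """
    if not trial.events:
        raise ValueError(f"trial {trial.key} has no events to segment")
    windows = []
    last = trial.n_frames - 1
    for event in sorted(trial.events, key=lambda e: e.object_index):
        start = max(0, event.contact_frame - pre_frames)
        end = min(last, event.release_frame + post_frames)
        windows.append((start, end, event.object_index))
    return windows


def select_analysis_segment(
    windows: list[tuple[int, int, int]]
) -> tuple[int, int, int]:
    """The analysis segment: the window of the last object manipulated."""
    if not windows:
        raise ValueError("no segment windows to select from")
    return max(windows, key=lambda w: w[2])


def last_segment_slice(trial: TrialRecording, config: SegmentConfig | None = None):
    cfg = config or SegmentConfig()
    start, end, _ = select_analysis_segment(
        segment_trial(trial, cfg.pre_frames, cfg.post_frames)
    )
    return slice(start, end + 1)


def resample_to_length(trace: np.ndarray, n_target: int) -> np.ndarray:
    """Linear interpolation onto ``n_target`` uniform points in normalized time.

    Endpoints are preserved exactly; a trace already at the target length is
    returned unchanged in value.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or trace.size < 2:
        raise ValueError("trace must be 1-D with at least 2 samples")
    if n_target < 2:
        raise ValueError(f"n_target must be >= 2, got {n_target}")
    src = np.linspace(0.0, 1.0, trace.size)
    dst = np.linspace(0.0, 1.0, n_target)
    return np.interp(dst, src, trace)


class TraceResampler(BaseEstimator, TransformerMixin):
    """Resample 1-D traces (rows of X) to a common length ``n``."""

    def __init__(self, n: int = 101):
        self.n = n

    def fit(self, X, y=None):
        ResampleConfig(n=self.n).validate()
        return self

    def transform(self, X):
        return np.vstack([resample_to_length(np.asarray(row), self.n) for row in X])
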