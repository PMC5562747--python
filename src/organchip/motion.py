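"""Thresholded pixel-movement motion quantification.

The contraction signal is obtained by frame differencing: for each pair of
consecutive frames the per-pixel absolute intensity difference is computed,
a threshold is applied, and the number of supra-threshold ("moving") pixels
is counted.  The resulting per-frame-pair count trace is the substrate for
beat detection.

The threshold can be fixed or automatic; the automatic rule is
``mean + auto_k * SD`` over the pooled difference values of the whole clip
(default ``auto_k = 3``), which adapts to the clip's own noise level without
any absolute intensity assumption.  Counting uses strict inequality
(> tau); ties are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ArgumentError
from .io_media import FrameSequence, to_grayscale

__all__ = [
    "MotionParams",
    "MotionTrace",
    "frame_difference",
    "auto_threshold",
    "threshold_motion",
    "smooth_trace",
    "compute_motion_trace",
]

#: Strictly positive sentinel threshold returned when a clip has zero motion,
#: so that all counts are reported as 0 rather than dividing by a zero SD.
ZERO_MOTION_SENTINEL = 1.0


@dataclass
class MotionParams:
    """Parameters of the moving-pixel conversion.

    threshold_mode : {"auto", "fixed"}
        "auto" derives tau from the clip (mean + auto_k * SD of pooled
        differences); "fixed" applies ``tau`` directly.
    tau : float
        Fixed intensity-difference threshold, used when mode is "fixed".
    auto_k : float
        SD multiplier for the automatic rule.
    smooth_window_s : float
        Moving-average window (seconds) applied to the count trace after
        counting; 0 disables smoothing.
    """

    threshold_mode: str = "auto"
    tau: float | None = None
    auto_k: float = 3.0
    smooth_window_s: float = 0.1

    def __post_init__(self) -> None:
        if self.threshold_mode not in {"auto", "fixed"}:
            raise ArgumentError(f"threshold_mode must be auto or fixed, got {self.threshold_mode!r}")
        if self.threshold_mode == "fixed":
            if self.tau is None or self.tau <= 0:
                raise ArgumentError("fixed mode requires tau > 0")
        if self.auto_k <= 0:
            raise ArgumentError("auto_k must be positive")
        if self.smooth_window_s < 0:
            raise ArgumentError("smooth_window_s must be >= 0")


@dataclass
class MotionTrace:
    """Per-frame-pair moving-pixel counts.

    ``counts`` holds the working trace (smoothed if ``smoothed`` is True);
    ``counts_raw`` always holds the integer-valued pre-smoothing counts.
    ``intensity`` optionally carries the summed supra-threshold difference
    intensity as a secondary statistic.
    """

    counts: np.ndarray
    fps: float
    tau_used: float
    smoothed: bool = False
    counts_raw: np.ndarray | None = None
    intensity: np.ndarray | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ArgumentError("counts must be 1-D")
        if self.counts_raw is None:
            self.counts_raw = self.counts.copy()
        if np.any(self.counts < 0):
            raise ArgumentError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.counts.size

    @property
    def duration_s(self) -> float:
        """Duration of the underlying clip (n counts span n+1 frames)."""
        return (self.n + 1) / self.fps

    def times(self) -> np.ndarray:
        """Midpoint time of each frame pair: t0 + (i + 0.5) / fps."""
        return self.t0 + (np.arange(self.n) + 0.5) / self.fps


def frame_difference(seq: FrameSequence) -> np.ndarray:
    """Elementwise absolute difference of consecutive frames.

    Returns an array of shape ``(n_frames - 1, height, width)`` where grid
    ``i`` is ``|frame[i+1] - frame[i]|``.
    """
    if seq.n_frames < 2:
        raise ArgumentError("motion computation requires at least 2 frames")
    frames = seq.frames.astype(float)
    return np.abs(np.diff(frames, axis=0))


def auto_threshold(diffs: np.ndarray, auto_k: float = 3.0) -> float:
    """Automatic threshold: mean + auto_k * SD of the pooled difference values.

    If every difference is zero (a perfectly static clip) a strictly positive
    sentinel (1.0) is returned so that downstream counts are all zero rather
    than the thresholding being degenerate.
    """
    pooled = np.asarray(diffs, dtype=float).ravel()
    if pooled.size == 0:
        raise ArgumentError("diffs must be non-empty")
    if np.all(pooled == 0):
        return ZERO_MOTION_SENTINEL
    return float(pooled.mean() + auto_k * pooled.std())


def threshold_motion(diffs: np.ndarray, tau: float, fps: float,
                     with_intensity: bool = False) -> MotionTrace:
    """Count pixels strictly above ``tau`` in each difference grid."""
    if tau <= 0:
        raise ArgumentError(f"tau must be positive, got {tau}")
    diffs = np.asarray(diffs, dtype=float)
    mask = diffs > tau
    counts = mask.sum(axis=(1, 2)).astype(float)
    intensity = None
    if with_intensity:
        intensity = np.where(mask, diffs, 0.0).sum(axis=(1, 2))
    return MotionTrace(counts=counts, fps=fps, tau_used=float(tau), intensity=intensity)


def smooth_trace(counts: np.ndarray, window: int) -> np.ndarray:
    """Length-preserving moving average with symmetric edge padding."""
    counts = np.asarray(counts, dtype=float)
    if window <= 1:
        return counts.copy()
    left = window // 2
    right = window - 1 - left
    padded = np.pad(counts, (left, right), mode="edge")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def compute_motion_trace(seq: FrameSequence, params: MotionParams | None = None,
                         with_intensity: bool = False) -> MotionTrace:
    """Full moving-pixel conversion of a clip.

    Pipeline: grayscale (if needed) -> frame differencing -> threshold
    (auto or fixed) -> strict supra-threshold counting -> optional moving
    average over ``round(smooth_window_s * fps)`` samples.
    """
    params = params or MotionParams()
    if seq.frames.ndim == 4:  # colour stack: reduce first
        seq = FrameSequence(
            np.stack([to_grayscale(f) for f in seq.frames]), seq.fps, seq.t0, seq.source
        )
    diffs = frame_difference(seq)
    if params.threshold_mode == "auto":
        tau = auto_threshold(diffs, params.auto_k)
    else:
        tau = float(params.tau)
    trace = threshold_motion(diffs, tau, seq.fps, with_intensity=with_intensity)
    trace.t0 = seq.t0
    window = int(round(params.smooth_window_s * seq.fps))
    if window > 1:
        raw = trace.counts.copy()
        trace.counts = smooth_trace(raw, window)
        trace.counts_raw = raw
        trace.smoothed = True
    return trace
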