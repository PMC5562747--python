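"""Ground-truthed synthetic inputs for every pipeline stage.

Two generators are provided:

* :func:`generate_beating_video` renders a roughly circular organoid as a
  bright disk whose radius contracts periodically, with additive Gaussian
  pixel noise and slow linear background drift — emulating on-chip video of
  a beating cardiac organoid.
* :func:`generate_livedead_image` renders a green/red stained-cell image
  pair with known live/dead counts — emulating LIVE/DEAD macro-confocal
  projections.

Contraction waveform.  Each beat triggers a contraction pulse of fixed
duration ``pulse_s`` (default 0.35 s, physiological systole scale), with a
fast raised-cosine contraction (30% of the pulse) and a slower relaxation
(70%), i.e. an asymmetric pulse.  The pulse is clipped to 90% of the
instantaneous beat period at high rates.  Beat onsets come from integrating
the instantaneous rate ``bpm_trajectory(t) / 60``, so time-varying rates
(steps, ramps, cessation) are supported.

All randomness flows from one explicit seed per artifact; identical seeds
give bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .errors import ArgumentError, CapacityError
from .io_media import FrameSequence, TwoChannelImage, write_frames

__all__ = [
    "VideoTruth",
    "ImageTruth",
    "contraction_pulse",
    "generate_beating_video",
    "generate_livedead_image",
    "generate_experiment_dataset",
]

#: Default contraction pulse duration (seconds); roughly a systole.
PULSE_S = 0.35
#: Fraction of the pulse spent contracting (the rest is slower relaxation).
RISE_FRAC = 0.3
#: A pulse never occupies more than this fraction of the instantaneous cycle.
MAX_DUTY = 0.9


@dataclass
class VideoTruth:
    """Ground truth and rendering parameters of a synthetic beating video.

    ``bpm_trajectory`` may be a constant (beats/min) or a callable of time
    in seconds.  After generation, ``beat_times_s`` and ``n_pulses`` record
    the realized contraction pulses.
    """

    bpm_trajectory: float | Callable[[float], float] = 60.0
    amplitude_frac: float = 0.1
    rest_radius_px: float = 40.0
    noise_sd: float = 2.0
    drift_per_s: float = 0.0
    fps: float = 30.0
    duration_s: float = 30.0
    seed: int = 0
    size_px: int = 128
    bg_intensity: float = 20.0
    fg_intensity: float = 180.0
    pulse_s: float = PULSE_S
    # filled in by the generator:
    beat_times_s: list[float] = field(default_factory=list)
    n_pulses: int = 0
    mean_bpm: float = 0.0

    def rate_at(self, t: float | np.ndarray) -> np.ndarray:
        if callable(self.bpm_trajectory):
            return np.asarray([self.bpm_trajectory(ti) for ti in np.atleast_1d(t)])
        return np.full(np.atleast_1d(np.asarray(t, dtype=float)).shape,
                       float(self.bpm_trajectory))

    def validate(self) -> None:
        if not 0 <= self.amplitude_frac < 0.5:
            raise ArgumentError("amplitude_frac must lie in [0, 0.5)")
        if self.noise_sd < 0:
            raise ArgumentError("noise_sd must be >= 0")
        t = np.arange(0, self.duration_s, 1.0 / self.fps)
        max_bpm = float(self.rate_at(t).max()) if t.size else 0.0
        if self.fps < 4.0 * max_bpm / 60.0:
            raise ArgumentError(
                f"fps {self.fps} violates the Nyquist margin for {max_bpm} BPM "
                f"(need >= {4.0 * max_bpm / 60.0:.1f})"
            )


@dataclass
class ImageTruth:
    """Ground truth for a synthetic LIVE/DEAD two-channel image."""

    n_live: int = 80
    n_dead: int = 20
    radius_range_px: tuple[float, float] = (3.0, 5.0)
    blur_sigma_px: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    size_px: int = 384
    bg_intensity: float = 15.0
    fg_intensity: float = 190.0

    def validate(self) -> None:
        if self.n_live < 0 or self.n_dead < 0:
            raise ArgumentError("counts must be >= 0")
        if self.radius_range_px[0] <= 0 or self.radius_range_px[1] < self.radius_range_px[0]:
            raise ArgumentError("invalid radius range")


def contraction_pulse(u: np.ndarray, rise_frac: float = RISE_FRAC) -> np.ndarray:
    """Asymmetric raised-cosine pulse on normalized pulse time ``u`` in [0, 1].

    Rises 0 -> 1 over ``rise_frac`` of the pulse, falls 1 -> 0 over the
    remainder; 0 outside [0, 1].
    """
    u = np.asarray(u, dtype=float)
    w = np.zeros_like(u)
    rising = (u >= 0) & (u < rise_frac)
    falling = (u >= rise_frac) & (u <= 1.0)
    w[rising] = 0.5 * (1.0 - np.cos(np.pi * u[rising] / rise_frac))
    w[falling] = 0.5 * (1.0 + np.cos(np.pi * (u[falling] - rise_frac) / (1.0 - rise_frac)))
    return w


def _beat_onsets(truth: VideoTruth, t: np.ndarray) -> np.ndarray:
    """Beat onset times from integrating the instantaneous rate."""
    rate_hz = truth.rate_at(t) / 60.0
    dt = 1.0 / truth.fps
    phase = np.concatenate([[0.0], np.cumsum(rate_hz) * dt])  # phase at frame starts
    n_beats = int(np.floor(phase[-1] - 1e-9)) + (1 if phase[-1] > 0 else 0)
    onsets = []
    for k in range(n_beats):
        # first frame time at which phase crosses k (phase[0] = 0 counts as beat 0)
        idx = np.searchsorted(phase, k, side="left")
        if idx >= t.size:
            break
        # linear interpolation inside the frame interval
        if idx == 0:
            onsets.append(float(t[0]))
        else:
            p0, p1 = phase[idx - 1], phase[idx]
            frac = 0.0 if p1 == p0 else (k - p0) / (p1 - p0)
            onsets.append(float(t[idx - 1] + frac * dt))
    return np.asarray(onsets)


def generate_beating_video(truth: VideoTruth) -> tuple[FrameSequence, VideoTruth]:
    """Render a beating-organoid video; returns the clip and completed truth."""
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    n_frames = int(round(truth.duration_s * truth.fps))
    t = np.arange(n_frames) / truth.fps
    onsets = _beat_onsets(truth, t) if truth.amplitude_frac > 0 else np.array([])

    # per-frame pulse value: superpose (non-overlapping) pulses
    w = np.zeros(n_frames)
    for k, onset in enumerate(onsets):
        rate = float(truth.rate_at(onset)[0])
        period = 60.0 / rate if rate > 0 else np.inf
        dur = min(truth.pulse_s, MAX_DUTY * period)
        lo = np.searchsorted(t, onset)
        hi = np.searchsorted(t, onset + dur, side="right")
        u = (t[lo:hi] - onset) / dur
        w[lo:hi] = np.maximum(w[lo:hi], contraction_pulse(u))

    size = truth.size_px
    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = (size - 1) / 2.0
    dist = np.hypot(yy - cy, xx - cx)

    frames = np.empty((n_frames, size, size), dtype=np.float32)
    radius = truth.rest_radius_px * (1.0 - truth.amplitude_frac * w)
    for i in range(n_frames):
        disk = np.clip(radius[i] + 0.5 - dist, 0.0, 1.0)  # anti-aliased edge
        img = truth.bg_intensity + (truth.fg_intensity - truth.bg_intensity) * disk
        img = img + truth.drift_per_s * t[i]
        if truth.noise_sd > 0:
            img = img + rng.normal(0.0, truth.noise_sd, size=(size, size))
        frames[i] = img
    frames = np.clip(np.round(frames), 0, 255).astype(np.uint8).astype(np.float32)

    truth.beat_times_s = [float(o) for o in onsets]
    truth.n_pulses = int(onsets.size)
    truth.mean_bpm = float(self_mean_rate(truth, t))
    seq = FrameSequence(frames, fps=truth.fps,
                        source=f"organchip.synth seed={truth.seed}")
    return seq, truth


def self_mean_rate(truth: VideoTruth, t: np.ndarray) -> float:
    r = truth.rate_at(t)
    return float(r.mean()) if r.size else 0.0


def generate_livedead_image(truth: ImageTruth) -> tuple[TwoChannelImage, ImageTruth]:
    """Render a LIVE/DEAD image pair with known counts.

    Live cells are green disks, dead cells red disks, placed without overlap
    (rejection sampling with a 3 px inter-disk gap so blurring keeps objects
    separate).  Raises :class:`CapacityError` when placement fails.
    """
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    size = truth.size_px
    rmin, rmax = truth.radius_range_px
    margin = rmax + 2.0

    n_total = truth.n_live + truth.n_dead
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    max_tries = 200 * max(1, n_total)
    tries = 0
    while len(centers) < n_total:
        tries += 1
        if tries > max_tries:
            raise CapacityError(
                f"could not place {n_total} non-overlapping disks of radius "
                f"{rmin}-{rmax} on a {size}x{size} canvas"
            )
        cy = rng.uniform(margin, size - margin)
        cx = rng.uniform(margin, size - margin)
        r = rng.uniform(rmin, rmax)
        if all(np.hypot(cy - y, cx - x) >= r + ro + 3.0 for (y, x), ro in zip(centers, radii)):
            centers.append((cy, cx))
            radii.append(r)

    yy, xx = np.mgrid[0:size, 0:size]
    green = np.full((size, size), truth.bg_intensity, dtype=float)
    red = np.full((size, size), truth.bg_intensity, dtype=float)
    amplitude = truth.fg_intensity - truth.bg_intensity
    for k, ((cy, cx), r) in enumerate(zip(centers, radii)):
        disk = np.clip(r + 0.5 - np.hypot(yy - cy, xx - cx), 0.0, 1.0)
        target = green if k < truth.n_live else red
        np.maximum(target, truth.bg_intensity + amplitude * disk, out=target)

    if truth.blur_sigma_px > 0:
        from scipy.ndimage import gaussian_filter

        green = gaussian_filter(green, truth.blur_sigma_px)
        red = gaussian_filter(red, truth.blur_sigma_px)
    if truth.noise_sd > 0:
        green = green + rng.normal(0.0, truth.noise_sd, green.shape)
        red = red + rng.normal(0.0, truth.noise_sd, red.shape)
    green = np.clip(np.round(green), 0, 255)
    red = np.clip(np.round(red), 0, 255)
    return TwoChannelImage(green=green, red=red), truth


def generate_experiment_dataset(protocol, video_cfg: VideoTruth,
                                out_dir: str | Path,
                                window_offset_h: float = 0.5) -> dict:
    """Render one video per observation window of a simulated chip experiment.

    Runs the PK/PD simulator for ``protocol`` and writes a multi-page TIFF
    per window (baseline before the first drug event, then one per event at
    ``event + window_offset_h``), each driven by the simulated beat rate at
    that moment.  A ceased window is rendered with contraction amplitude 0.
    Returns the manifest (also written as ``manifest.json``) recording
    seeds, true BPM and condition labels; regenerating from the manifest's
    seeds is bit-identical.
    """
    from dataclasses import replace

    from .pkpd import default_pd_params, simulate_two_tissue_experiment

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    result = simulate_two_tissue_experiment(protocol)
    ts = result.timeseries

    windows: list[tuple[str, float]] = []
    first_event = min((e[0] for e in protocol.events), default=protocol.duration_h)
    windows.append(("baseline", max(0.0, first_event - window_offset_h)))
    for time_h, drug, conc in sorted(protocol.events):
        windows.append((f"post_{drug}_{conc:g}uM", min(protocol.duration_h, time_h + window_offset_h)))

    manifest = {"protocol_mode": protocol.mode, "seed": protocol.seed, "videos": []}
    for k, (label, t_h) in enumerate(windows):
        idx = int(np.argmin(np.abs(ts["t_h"].to_numpy() - t_h)))
        bpm = float(ts["bpm"].iloc[idx])
        ceased = bool(ts["ceased"].iloc[idx]) if "ceased" in ts else False
        cfg = replace(
            video_cfg,
            bpm_trajectory=bpm,
            amplitude_frac=0.0 if (ceased or bpm <= 0) else video_cfg.amplitude_frac,
            seed=int(protocol.seed + 1000 * k) % (2**31),
            beat_times_s=[],
        )
        seq, truth = generate_beating_video(cfg)
        fname = f"{k:02d}_{label}.tif"
        write_frames(seq, out_dir / fname)
        manifest["videos"].append({
            "file": fname,
            "condition": label,
            "t_h": t_h,
            "true_bpm": bpm,
            "ceased": ceased,
            "seed": cfg.seed,
            "fps": cfg.fps,
            "duration_s": cfg.duration_s,
            "n_pulses": truth.n_pulses,
        })
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
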