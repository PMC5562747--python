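"""Reading and writing video frame stacks, two-channel images and reports.

The canonical in-memory video container is :class:`FrameSequence`: an ordered
stack of single-channel frames on a common 8-bit intensity scale ([0, 255]),
with an explicit frame rate.  Multi-page TIFF is the primary on-disk format;
common video containers are read through imageio when an ffmpeg backend is
available.  16-bit TIFF input is rescaled linearly by its own maximum so that
downstream thresholds operate on one scale.

Pixel coordinates are 0-based, row-major, origin top-left.  ROI rectangles
are half-open ``[y0, y1) x [x0, x1)``.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import ArgumentError, FormatError, InputError

__all__ = [
    "FrameSequence",
    "TwoChannelImage",
    "LUMA_WEIGHTS",
    "to_grayscale",
    "read_frames",
    "write_frames",
    "read_two_channel",
    "write_two_channel",
    "write_report",
    "read_report",
]

#: Standard video luma weights (ITU-R BT.601) used for 3-channel conversion.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

SCHEMA_VERSION = 1


@dataclass
class FrameSequence:
    """Ordered stack of single-channel intensity frames with a frame rate.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)`` with values in [0, 255].
    fps
        Frames per second; must be positive.
    t0
        Acquisition start time in seconds.
    source
        Free-text provenance (file path, generator description, ...).
    """

    frames: np.ndarray
    fps: float
    t0: float = 0.0
    source: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ArgumentError(
                f"frames must be a (n, height, width) stack, got ndim={self.frames.ndim}"
            )
        if self.fps <= 0:
            raise ArgumentError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of every frame."""
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def times(self) -> np.ndarray:
        """Per-frame timestamps ``t0 + i / fps`` (strictly increasing)."""
        return self.t0 + np.arange(self.n_frames) / self.fps

    def crop(self, roi: tuple[int, int, int, int]) -> "FrameSequence":
        """Return a view restricted to the half-open rectangle (y0, y1, x0, x1)."""
        y0, y1, x0, x1 = roi
        h, w = self.shape
        if not (0 <= y0 < y1 <= h and 0 <= x0 < x1 <= w):
            raise ArgumentError(f"roi {roi} outside frame bounds {h}x{w}")
        return FrameSequence(self.frames[:, y0:y1, x0:x1], self.fps, self.t0, self.source)


@dataclass
class TwoChannelImage:
    """A green (live stain) / red (dead stain) fluorescence image pair.

    The channels mirror calcein-AM (green, live cells) and ethidium
    homodimer-1 (red, membrane-compromised cells) staining.
    """

    green: np.ndarray
    red: np.ndarray
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green)
        self.red = np.asarray(self.red)
        if self.green.shape != self.red.shape:
            raise ArgumentError(
                f"channel shapes differ: green {self.green.shape} vs red {self.red.shape}"
            )
        if self.green.ndim != 2:
            raise ArgumentError("channels must be 2-D intensity grids")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ArgumentError("pixel_size_um must be positive")


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Reduce a frame to a single channel.

    Single-channel input is returned unchanged (idempotent).  3-channel
    (H, W, 3) input is reduced with fixed luma weights 0.299/0.587/0.114,
    which sum to 1 so uniform frames keep their value.
    """
    frame = np.asarray(frame)
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[2] == 3:
        return frame.astype(float) @ LUMA_WEIGHTS
    raise FormatError(f"expected 1 or 3 channels, got shape {frame.shape}")


def _normalize_to_8bit(stack: np.ndarray) -> np.ndarray:
    """Linearly rescale >8-bit data onto [0, 255] by its own maximum."""
    stack = np.asarray(stack)
    if stack.dtype == np.uint8:
        return stack.astype(np.float32)
    stack = stack.astype(np.float32)
    peak = float(stack.max()) if stack.size else 0.0
    if peak > 255.0:
        stack = stack * (255.0 / peak)
    return stack


def read_frames(
    path: str | os.PathLike,
    fps: float | None = None,
    roi: tuple[int, int, int, int] | None = None,
) -> FrameSequence:
    """Read a multi-page TIFF stack or a video container into a FrameSequence.

    ``fps`` is taken from container metadata when available and is otherwise
    mandatory — a beat rate is meaningless without it, so there is no silent
    default.  Multi-channel sources are converted via :func:`to_grayscale`;
    16-bit data is rescaled onto [0, 255].
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")

    meta_fps: float | None = None
    if path.suffix.lower() in {".tif", ".tiff"}:
        try:
            stack = tifffile.imread(path)
        except Exception as exc:  # malformed TIFF
            raise FormatError(f"could not read TIFF {path}: {exc}") from exc
        stack = np.asarray(stack)
        if stack.ndim == 2:
            stack = stack[None]
    else:
        try:
            import imageio.v3 as iio

            stack = np.asarray(iio.imread(path, index=None))
            try:
                meta_fps = iio.immeta(path).get("fps")
            except Exception:
                meta_fps = None
        except Exception as exc:
            raise FormatError(f"could not read video container {path}: {exc}") from exc

    if stack.size == 0 or stack.shape[0] == 0:
        raise FormatError(f"{path}: zero readable frames")
    if stack.ndim == 4:
        stack = np.stack([to_grayscale(f) for f in stack])
    elif stack.ndim != 3:
        raise FormatError(f"{path}: unsupported frame layout {stack.shape}")

    stack = _normalize_to_8bit(stack)

    fps = fps if fps is not None else meta_fps
    if fps is None:
        raise ArgumentError(
            f"{path}: no frame-rate metadata found; pass fps explicitly"
        )
    seq = FrameSequence(stack, fps=float(fps), source=str(path))
    if roi is not None:
        seq = seq.crop(roi)
    return seq


def write_frames(seq: FrameSequence, path: str | os.PathLike) -> None:
    """Write a FrameSequence as an 8-bit multi-page TIFF (lossless for 8-bit data)."""
    data = np.clip(np.round(seq.frames), 0, 255).astype(np.uint8)
    tifffile.imwrite(Path(path), data, photometric="minisblack")


def read_two_channel(
    path: str | os.PathLike,
    red_path: str | os.PathLike | None = None,
    pixel_size_um: float | None = None,
) -> TwoChannelImage:
    """Read a 2-page TIFF (page 0 = green, page 1 = red) or paired files."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if red_path is None:
        pages = tifffile.imread(path)
        pages = np.asarray(pages)
        if pages.ndim != 3 or pages.shape[0] != 2:
            raise FormatError(
                f"{path}: expected a 2-page TIFF (green, red), got shape {pages.shape}"
            )
        green, red = pages[0], pages[1]
    else:
        red_path = Path(red_path)
        if not red_path.exists():
            raise InputError(f"no such file: {red_path}")
        green = np.asarray(tifffile.imread(path))
        red = np.asarray(tifffile.imread(red_path))
    green = _normalize_to_8bit(green[None])[0]
    red = _normalize_to_8bit(red[None])[0]
    return TwoChannelImage(green=green, red=red, pixel_size_um=pixel_size_um)


def write_two_channel(image: TwoChannelImage, path: str | os.PathLike) -> None:
    """Write a TwoChannelImage as a 2-page TIFF (green page first)."""
    pages = np.stack([image.green, image.red])
    tifffile.imwrite(Path(path), np.clip(np.round(pages), 0, 255).astype(np.uint8),
                     photometric="minisblack")


def _to_record(obj: Any) -> Any:
    """Recursively turn dataclasses / arrays into plain JSON-serializable data."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_record(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_record(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_record(v) for v in obj]
    if callable(obj):
        return repr(obj)
    return obj


def write_report(
    results: Any,
    path: str | os.PathLike,
    format: str = "json",
    provenance: dict | None = None,
) -> None:
    """Write an analysis record to CSV or JSON.

    JSON reports carry a versioned envelope with the package version and any
    caller-supplied provenance (resolved parameters, seed), so every output
    file records how it was produced.  Numeric fields round-trip at full
    precision in both formats.
    """
    path = Path(path)
    record = _to_record(results)
    try:
        if format == "json":
            from . import __version__

            envelope = {
                "schema_version": SCHEMA_VERSION,
                "package": "organchip",
                "package_version": __version__,
                "provenance": _to_record(provenance or {}),
                "results": record,
            }
            path.write_text(json.dumps(envelope, indent=2) + "\n")
        elif format == "csv":
            if isinstance(record, dict):
                record = [record]
            df = pd.DataFrame(record)
            df.to_csv(path, index=False)
        else:
            raise ArgumentError(f"unknown report format {format!r} (use csv or json)")
    except OSError as exc:
        raise InputError(f"cannot write report to {path}: {exc}") from exc


def read_report(path: str | os.PathLike, format: str = "json") -> Any:
    """Re-read a report written by :func:`write_report` (returns the results payload)."""
    path = Path(path)
    if format == "json":
        return json.loads(path.read_text())["results"]
    if format == "csv":
        return pd.read_csv(path).to_dict(orient="records")
    raise ArgumentError(f"unknown report format {format!r}")
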