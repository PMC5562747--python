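"""LIVE/DEAD staining quantification.

Cells are counted per channel (calcein-AM green = live, EthD-1 red = dead)
by global thresholding (Otsu by default), 8-connected component labeling and
small-object removal.  Viability is the object-count ratio
``100 * live / (live + dead)``; a stained-area ratio is exposed as a
secondary statistic.  An object detected in both channels is counted as
dead only — EthD-1 entry indicates a compromised membrane — so each
physical object is counted exactly once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .errors import ArgumentError
from .io_media import TwoChannelImage

__all__ = ["ViabilityParams", "ViabilityResult", "SegmentedObject",
           "segment_channel", "count_live_dead"]


@dataclass
class ViabilityParams:
    """Segmentation parameters for stained-cell counting."""

    min_object_px: int = 20
    channel_threshold_mode: str = "otsu"
    fixed_thresholds: tuple[float, float] | None = None  # (green, red)
    dual_positive_counts_as: str = "dead"

    def __post_init__(self) -> None:
        if self.min_object_px < 1:
            raise ArgumentError("min_object_px must be >= 1")
        if self.channel_threshold_mode not in {"otsu", "fixed"}:
            raise ArgumentError("channel_threshold_mode must be otsu or fixed")
        if self.channel_threshold_mode == "fixed" and self.fixed_thresholds is None:
            raise ArgumentError("fixed mode requires fixed_thresholds")
        if self.dual_positive_counts_as not in {"dead", "live"}:
            raise ArgumentError("dual_positive_counts_as must be dead or live")


@dataclass
class SegmentedObject:
    """One labeled connected component."""

    label: int
    centroid: tuple[float, float]
    area_px: int


@dataclass
class ViabilityResult:
    """Live/dead counts and the derived viability percentage."""

    live_count: int
    dead_count: int
    viability_pct: float
    live_area_px: int = 0
    dead_area_px: int = 0
    area_viability_pct: float = 0.0
    n_dual_positive: int = 0


def _channel_threshold(image: np.ndarray, params: ViabilityParams,
                       channel_index: int) -> float | None:
    if params.channel_threshold_mode == "fixed":
        return float(params.fixed_thresholds[channel_index])
    if np.all(image == image.flat[0]):
        return None  # zero-variance channel; no objects
    return float(threshold_otsu(image))


def segment_channel(image: np.ndarray, params: ViabilityParams | None = None,
                    channel_index: int = 0,
                    return_labels: bool = False):
    """Segment one fluorescence channel into labeled objects.

    Global threshold -> 8-connected labeling -> removal of objects smaller
    than ``min_object_px``.  A blank (zero-variance) channel yields an empty
    object set with a warning.
    """
    params = params or ViabilityParams()
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ArgumentError("empty image")
    thresh = _channel_threshold(image, params, channel_index)
    if thresh is None:
        warnings.warn("blank channel (zero variance): no objects segmented")
        objects: list[SegmentedObject] = []
        labels = np.zeros(image.shape, dtype=int)
        return (objects, labels) if return_labels else objects

    mask = image > thresh
    labels = label(mask, connectivity=2)
    objects = []
    keep = np.zeros(labels.max() + 1, dtype=bool)
    for region in regionprops(labels):
        if region.area >= params.min_object_px:
            objects.append(SegmentedObject(
                label=int(region.label),
                centroid=(float(region.centroid[0]), float(region.centroid[1])),
                area_px=int(region.area),
            ))
            keep[region.label] = True
    labels = np.where(keep[labels], labels, 0)
    return (objects, labels) if return_labels else objects


def count_live_dead(image: TwoChannelImage,
                    params: ViabilityParams | None = None) -> ViabilityResult:
    """Count live and dead cells in a two-channel LIVE/DEAD image.

    An object appearing in both channels (a green object whose centroid
    falls inside a red object, or vice versa) is a single physical cell and
    is attributed to the channel configured in ``dual_positive_counts_as``
    (dead by default).  When the total count is zero, viability is defined
    as 0 with a warning.
    """
    params = params or ViabilityParams()
    green_objs, green_labels = segment_channel(image.green, params, 0, return_labels=True)
    red_objs, red_labels = segment_channel(image.red, params, 1, return_labels=True)

    def _dual(obj: SegmentedObject, other_labels: np.ndarray) -> bool:
        y, x = int(round(obj.centroid[0])), int(round(obj.centroid[1]))
        y = min(max(y, 0), other_labels.shape[0] - 1)
        x = min(max(x, 0), other_labels.shape[1] - 1)
        return other_labels[y, x] > 0

    green_dual = [_dual(o, red_labels) for o in green_objs]
    red_dual = [_dual(o, green_labels) for o in red_objs]
    n_dual = 0
    if params.dual_positive_counts_as == "dead":
        # dual objects live with the red count; drop their green duplicates
        live_objs = [o for o, d in zip(green_objs, green_dual) if not d]
        dead_objs = list(red_objs)
        n_dual = sum(green_dual)
    else:
        live_objs = list(green_objs)
        dead_objs = [o for o, d in zip(red_objs, red_dual) if not d]
        n_dual = sum(red_dual)

    live, dead = len(live_objs), len(dead_objs)
    total = live + dead
    if total == 0:
        warnings.warn("no objects detected in either channel; viability reported as 0")
        pct = 0.0
    else:
        pct = 100.0 * live / total

    live_area = sum(o.area_px for o in live_objs)
    dead_area = sum(o.area_px for o in dead_objs)
    area_total = live_area + dead_area
    return ViabilityResult(
        live_count=live,
        dead_count=dead,
        viability_pct=pct,
        live_area_px=live_area,
        dead_area_px=dead_area,
        area_viability_pct=100.0 * live_area / area_total if area_total else 0.0,
        n_dual_positive=int(n_dual),
    )
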