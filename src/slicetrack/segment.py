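"""Normalised-threshold segmentation of projections into Detections.

Each aligned 2-D projection is scaled by a robust (percentile) maximum,
thresholded at a fixed fraction of the normalised range, and its
8-connected components filtered by calibrated area and optionally by
mean intensity.  The scheme is deterministic and invariant to global
intensity rescaling, which is what makes fully automated longitudinal
segmentation reproducible across sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .imgio import Projection


@dataclass
class SegmentConfig:
    """Segmentation parameters.

    normalize_percentile
        Percentile used as the robust maximum when scaling intensities
        to [0, 1]; must lie in (50, 100].
    threshold_fraction
        Foreground threshold as a fraction of the normalised range.
    min_area_um2 / max_area_um2
        Calibrated component-size window; objects outside are dropped.
        ``min_area_um2`` defaults to 20 µm² (roughly a quarter of a
        small soma cross-section) — a pipeline choice, not a measured
        biological constant.
    min_mean_intensity
        Optional raw-intensity floor on the mean of each component.
    max_foreground_fraction
        Normalised thresholding presumes sparse bright objects on a dim
        background; if the thresholded foreground covers more than this
        fraction of the image there is no meaningful signal (e.g. a
        noise-only field, where the robust maximum is itself noise) and
        segmentation returns no objects, with a warning.
    method
        "fraction" (default, normalised fixed-fraction threshold) or
        "otsu" for comparison runs.
    """

    normalize_percentile: float = 99.9
    threshold_fraction: float = 0.2
    min_area_um2: float = 20.0
    max_area_um2: float = np.inf
    min_mean_intensity: float | None = None
    max_foreground_fraction: float = 0.5
    method: str = "fraction"

    def __post_init__(self) -> None:
        if not 0 < self.threshold_fraction < 1:
            raise ValueError("threshold_fraction must be in (0, 1)")
        if not 50 < self.normalize_percentile <= 100:
            raise ValueError("normalize_percentile must be in (50, 100]")
        if self.min_area_um2 < 0:
            raise ValueError("min_area_um2 must be >= 0")
        if not 0 < self.max_foreground_fraction <= 1:
            raise ValueError("max_foreground_fraction must be in (0, 1]")
        if self.method not in ("fraction", "otsu"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class Detection:
    """One segmented object at one timepoint.

    Centroids are intensity-weighted and expressed in micrometres
    (x = column index x dx, y = row index x dy).
    """

    timepoint_h: float
    label: int
    centroid_um: tuple[float, float]  # (x, y)
    area_um2: float
    mean_intensity: dict[str, float] = field(default_factory=dict)
    bbox: tuple[int, int, int, int] = (0, 0, 0, 0)  # (min_row, min_col, max_row, max_col)
    well: str = ""

    @property
    def x_um(self) -> float:
        return self.centroid_um[0]

    @property
    def y_um(self) -> float:
        return self.centroid_um[1]

    def distance_to(self, other: "Detection") -> float:
        return float(np.hypot(self.x_um - other.x_um, self.y_um - other.y_um))


def normalize(projection: Projection, percentile: float = 99.9) -> np.ndarray:
    """Scale intensities to [0, 1] by the given robust percentile.

    Values above the percentile clip to 1.  An all-zero image comes back
    all-zero with a warning rather than dividing by zero.
    """
    img = np.asarray(projection.pixels, dtype=float)
    if img.min() < 0:
        raise ValueError("negative intensities")
    scale = np.percentile(img, percentile)
    if scale == 0:
        warnings.warn("all-zero image: normalization is identity")
        return np.zeros_like(img)
    return np.clip(img / scale, 0.0, 1.0)


def segment_cells(
    projection: Projection,
    config: SegmentConfig | None = None,
    extra_channels: dict[str, np.ndarray] | None = None,
    well: str = "",
) -> list[Detection]:
    """Segment one calibrated projection into a list of Detections.

    The binary mask is ``normalize(img) >= threshold_fraction``; its
    8-connected components are labelled, filtered by calibrated area
    (and optional mean intensity), and summarised by intensity-weighted
    centroids.  ``extra_channels`` supplies co-registered images (e.g. a
    reporter channel) whose per-object mean intensities are recorded
    alongside the segmentation channel's.
    """
    if config is None:
        config = SegmentConfig()
    labels, mask = label_mask(projection, config)
    if mask.mean() > config.max_foreground_fraction:
        warnings.warn(
            "foreground covers "
            f"{mask.mean():.0%} of the image (> "
            f"{config.max_foreground_fraction:.0%}): no sparse bright "
            "objects to segment"
        )
        return []
    img = np.asarray(projection.pixels, dtype=float)
    dx, dy = projection.pixel_size
    px_area = dx * dy
    detections: list[Detection] = []
    channels = {projection.channel: img}
    if extra_channels:
        channels.update(
            {k: np.asarray(v, dtype=float) for k, v in extra_channels.items()}
        )
    for prop in regionprops(labels, intensity_image=img):
        area = prop.area * px_area
        if not (config.min_area_um2 <= area <= config.max_area_um2):
            continue
        if (
            config.min_mean_intensity is not None
            and prop.intensity_mean < config.min_mean_intensity
        ):
            continue
        cy, cx = prop.centroid_weighted if prop.intensity_max > 0 else prop.centroid
        rows, cols = prop.coords[:, 0], prop.coords[:, 1]
        means = {name: float(ch[rows, cols].mean()) for name, ch in channels.items()}
        detections.append(
            Detection(
                timepoint_h=projection.timepoint_h,
                label=int(prop.label),
                centroid_um=(float(cx) * dx, float(cy) * dy),
                area_um2=float(area),
                mean_intensity=means,
                bbox=tuple(int(b) for b in prop.bbox),
                well=well,
            )
        )
    return detections


def label_mask(
    projection: Projection, config: SegmentConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Binary foreground mask and 8-connected label image (no area filter)."""
    if config is None:
        config = SegmentConfig()
    norm = normalize(projection, config.normalize_percentile)
    if config.method == "otsu":
        thr = threshold_otsu(norm) if np.ptp(norm) > 0 else 1.0
        mask = norm >= thr
    else:
        mask = norm >= config.threshold_fraction
    return cc_label(mask, connectivity=2), mask
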