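"""Inclusion-body particle analysis.

Neuron masks built from the morphology channel are applied to the
reporter channel to discard signal outside cells; the filtered image is
rescaled to 8-bit, thresholded over a fixed 8-bit range, and its
connected components above a calibrated minimum area become puncta.
Puncta are classed small/large at an 80 µm² boundary, attributed to the
cell whose mask contains them, matched across timepoints, and their
cumulative per-slice accumulation compared between groups (endpoint
t-test plus ANCOVA on accumulation rates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .imgio import Projection
from .quantify import compare_slopes_ancova
from .segment import Detection, SegmentConfig, label_mask, segment_cells

SMALL = "small"
LARGE = "large"


@dataclass
class PunctaConfig:
    """Particle-analysis parameters.

    min_particle_area_um2
        Smallest particle retained (calibrated area); 10 µm² by default.
    small_large_boundary_um2
        Small/large class boundary: small is strictly below 80 µm²;
        exactly 80 µm² classes as large so the classes partition.
    threshold_range
        Inclusive (low, high) window on the 8-bit rescaled intensity;
        default (5, 255).
    calibrated_units
        When False, areas are in pixels rather than µm².
    match_radius_um
        Two puncta of the same cell at consecutive timepoints closer
        than this are the same punctum (default: one soma radius, 8 µm);
        this makes "cumulative formation" well defined.
    """

    min_particle_area_um2: float = 10.0
    small_large_boundary_um2: float = 80.0
    threshold_range: tuple[int, int] = (5, 255)
    calibrated_units: bool = True
    match_radius_um: float = 8.0

    def __post_init__(self) -> None:
        if not 0 < self.min_particle_area_um2 < self.small_large_boundary_um2:
            raise ValueError("need 0 < min_particle_area < small/large boundary")
        if not self.threshold_range[0] < self.threshold_range[1]:
            raise ValueError("threshold low must be < high")


@dataclass
class Punctum:
    """One sub-cellular particle inside a neuron mask."""

    timepoint_h: float
    cell_id: int  # owner cell (-1 when no track covers the mask region)
    centroid_um: tuple[float, float]
    area_um2: float
    size_class: str
    slice_id: str = ""


def classify_size(area_um2: float, config: PunctaConfig | None = None) -> str:
    """Small iff strictly below the boundary (default 80 µm²)."""
    if config is None:
        config = PunctaConfig()
    return SMALL if area_um2 < config.small_large_boundary_um2 else LARGE


def neuron_mask(
    morphology_projection: Projection,
    segment_config: SegmentConfig | None = None,
    detections: list[Detection] | None = None,
    cell_ids: dict[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary neuron mask and per-cell label map from the morphology channel.

    The mask is the union of the components retained by
    :func:`slicetrack.segment.segment_cells`; the label map carries each
    retained component's detection label (mapped through ``cell_ids``,
    a detection-label -> cell_id mapping from the track table, when
    given).  An empty segmentation yields an empty mask.
    """
    if segment_config is None:
        segment_config = SegmentConfig()
    if detections is None:
        detections = segment_cells(morphology_projection, segment_config)
    labels, _ = label_mask(morphology_projection, segment_config)
    keep = {d.label for d in detections}
    mask = np.isin(labels, list(keep))
    label_map = np.where(mask, labels, 0)
    if cell_ids is not None:
        out = np.zeros_like(label_map)
        for lab, cid in cell_ids.items():
            out[label_map == lab] = cid + 1  # 0 stays background
        label_map = out
    return mask, label_map


def detect_puncta(
    reporter_projection: Projection,
    mask: np.ndarray,
    config: PunctaConfig | None = None,
    label_map: np.ndarray | None = None,
    slice_id: str = "",
    rescale_range: tuple[float, float] | None = None,
) -> list[Punctum]:
    """Particle detection inside neuron masks.

    Reporter pixels outside the mask are zeroed, the image is linearly
    rescaled to 8-bit (by its own min-max, or by ``rescale_range`` —
    pass a range shared across the whole series so dim frames stay
    dim), pixels whose value lies in the inclusive threshold window
    become foreground, and 8-connected components at or above the
    minimum calibrated area become puncta.  Ownership comes from
    ``label_map`` (cell_id + 1 per pixel) when provided.
    """
    if config is None:
        config = PunctaConfig()
    img = np.asarray(reporter_projection.pixels, dtype=float)
    if img.shape != np.asarray(mask).shape:
        raise ValueError("mask and projection geometries differ")
    filtered = np.where(mask, img, 0.0)
    if rescale_range is None:
        lo, hi = float(filtered.min()), float(filtered.max())
    else:
        lo, hi = rescale_range
    if hi > lo:
        eight = np.round(np.clip((filtered - lo) / (hi - lo), 0, 1) * 255.0)
    else:
        eight = np.zeros_like(filtered)
    tlo, thi = config.threshold_range
    fg = (eight >= tlo) & (eight <= thi)
    labels = cc_label(fg, connectivity=2)
    dx, dy = reporter_projection.pixel_size
    px_area = dx * dy if config.calibrated_units else 1.0
    puncta = []
    for prop in regionprops(labels, intensity_image=filtered):
        area = prop.area * px_area
        if area < config.min_particle_area_um2:
            continue
        cy, cx = prop.centroid_weighted if prop.intensity_max > 0 else prop.centroid
        owner = -1
        if label_map is not None:
            vals = label_map[prop.coords[:, 0], prop.coords[:, 1]]
            vals = vals[vals > 0]
            if vals.size:
                owner = int(np.bincount(vals).argmax()) - 1
        puncta.append(
            Punctum(
                timepoint_h=reporter_projection.timepoint_h,
                cell_id=owner,
                centroid_um=(float(cx) * dx, float(cy) * dy),
                area_um2=float(area),
                size_class=classify_size(float(area), config),
                slice_id=slice_id,
            )
        )
    return puncta


def puncta_table(puncta: list[Punctum]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "slice_id": p.slice_id,
                "cell_id": p.cell_id,
                "timepoint_h": p.timepoint_h,
                "x_um": p.centroid_um[0],
                "y_um": p.centroid_um[1],
                "area_um2": p.area_um2,
                "size_class": p.size_class,
            }
            for p in puncta
        ],
        columns=[
            "slice_id", "cell_id", "timepoint_h", "x_um", "y_um",
            "area_um2", "size_class",
        ],
    )


def assign_puncta_ids(
    table: pd.DataFrame, config: PunctaConfig | None = None
) -> pd.DataFrame:
    """Match puncta across consecutive timepoints within each slice+cell.

    A punctum is "the same" as one at the previous timepoint when their
    centroids are within ``match_radius_um`` inside the same cell;
    unmatched puncta get fresh punctum_ids (their first-observation
    time defines formation).  Greedy ascending-distance matching.
    """
    if config is None:
        config = PunctaConfig()
    table = table.sort_values(["slice_id", "timepoint_h"]).reset_index(drop=True)
    table["punctum_id"] = -1
    next_id = 0
    for (_slice, _cell), sub in table.groupby(["slice_id", "cell_id"], sort=True):
        prev: list[tuple[int, float, float]] = []  # (punctum_id, x, y)
        for t in sorted(sub["timepoint_h"].unique()):
            cur = sub[sub["timepoint_h"] == t]
            pairs = []
            for idx, row in cur.iterrows():
                for pid, px, py in prev:
                    d = np.hypot(row["x_um"] - px, row["y_um"] - py)
                    if d <= config.match_radius_um:
                        pairs.append((d, idx, pid))
            used_idx: set[int] = set()
            used_pid: set[int] = set()
            for d, idx, pid in sorted(pairs, key=lambda q: q[0]):
                if idx in used_idx or pid in used_pid:
                    continue
                table.loc[idx, "punctum_id"] = pid
                used_idx.add(idx)
                used_pid.add(pid)
            for idx in cur.index:
                if idx not in used_idx:
                    table.loc[idx, "punctum_id"] = next_id
                    next_id += 1
            prev = [
                (int(table.loc[idx, "punctum_id"]), table.loc[idx, "x_um"],
                 table.loc[idx, "y_um"])
                for idx in cur.index
            ]
    return table


def accumulation_analysis(
    table: pd.DataFrame,
    group_of_slice: dict[str, str],
    config: PunctaConfig | None = None,
    size_class: str = SMALL,
) -> dict:
    """Cumulative puncta formation per slice and the group comparison.

    ``table`` is a puncta table (see :func:`puncta_table`) pooled over
    slices and timepoints; ``group_of_slice`` labels each slice.  For
    each slice the cumulative count of distinct puncta of the requested
    size class first observed up to each timepoint is computed; groups
    are compared by a t-test on the endpoint counts and an ANCOVA on the
    accumulation rates.  A group with a single slice refuses the t-test
    (logged, statistics set to NaN).
    """
    if config is None:
        config = PunctaConfig()
    timepoints = sorted(table["timepoint_h"].unique()) if len(table) else []
    matched = assign_puncta_ids(table, config) if len(table) else table.assign(punctum_id=[])
    rows = []
    for sl, grp in group_of_slice.items():
        sub = matched[matched["slice_id"] == sl]
        sub = sub[sub["size_class"] == size_class]
        first_seen = sub.groupby("punctum_id")["timepoint_h"].min()
        for t in timepoints:
            rows.append(
                {
                    "slice_id": sl,
                    "group": grp,
                    "timepoint_h": t,
                    "cumulative_count": int((first_seen <= t).sum()),
                }
            )
    cumulative = pd.DataFrame(
        rows, columns=["slice_id", "group", "timepoint_h", "cumulative_count"]
    )
    result = {
        "cumulative": cumulative,
        "t_stat": np.nan,
        "t_p": np.nan,
        "ancova_f": np.nan,
        "ancova_p": np.nan,
    }
    groups = sorted(set(group_of_slice.values()))
    if len(groups) == 2 and timepoints:
        endpoint = cumulative[cumulative["timepoint_h"] == timepoints[-1]]
        a = endpoint[endpoint["group"] == groups[0]]["cumulative_count"]
        b = endpoint[endpoint["group"] == groups[1]]["cumulative_count"]
        if len(a) < 2 or len(b) < 2:
            warnings.warn("a group has a single slice: endpoint t-test refused")
        else:
            t, p = stats.ttest_ind(a, b)
            result["t_stat"], result["t_p"] = float(t), float(p)
            ga = cumulative[cumulative["group"] == groups[0]].rename(
                columns={"slice_id": "trace_id", "cumulative_count": "value"}
            )
            gb = cumulative[cumulative["group"] == groups[1]].rename(
                columns={"slice_id": "trace_id", "cumulative_count": "value"}
            )
            f, ap = compare_slopes_ancova(ga, gb)
            result["ancova_f"], result["ancova_p"] = f, ap
    return result
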