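"""Calibrated 5-D image I/O and pre-segmentation image operations.

Image series are held as ``VolumeSeries`` objects with axis order
(time, channel, z, y, x) and physical calibration in micrometres and
hours.  Everything downstream of acquisition consumes 2-D maximum
projections along z; this module provides the projection itself plus the
mosaic stitching, translation-only alignment and two-colour overlay
steps that precede segmentation.

Coordinate convention (used package-wide): pixel indices are 0-based,
physical coordinates are pixel index x pixel size (pixel centres), and
y increases downward as in image displays.
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import tifffile
from skimage.registration import phase_cross_correlation

#: x/y/z voxel edge lengths in micrometres used when a file carries no
#: calibration of its own (0.3225 x 0.3225 x 0.5 um).
DEFAULT_VOXEL_SIZE = (0.3225, 0.3225, 0.5)

#: Default sampling interval between imaging sessions, hours.
DEFAULT_FRAME_INTERVAL_H = 24.0


@dataclass
class VolumeSeries:
    """A calibrated 5-D fluorescence image series, axes (t, c, z, y, x).

    Parameters
    ----------
    pixels
        Non-negative intensity grid of shape (T, C, Z, Y, X).
    voxel_size
        (dx, dy, dz) in micrometres.
    frame_interval_h
        Hours between consecutive timepoints.
    channel_names
        One name per channel, e.g. ``["morphology", "reporter"]``.
    t0_h
        Label of the first timepoint in hours post transfection or
        infection (imaging conventionally starts at 24 hpt).
    """

    pixels: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    frame_interval_h: float = DEFAULT_FRAME_INTERVAL_H
    channel_names: list[str] = field(default_factory=lambda: ["channel0"])
    t0_h: float = 24.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 5:
            raise ValueError(
                f"VolumeSeries needs 5 axes (t, c, z, y, x); got {self.pixels.ndim}"
            )
        if any(e < 1 for e in self.pixels.shape):
            raise ValueError(f"all extents must be >= 1; got {self.pixels.shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be positive; got {self.voxel_size}")
        if len(self.channel_names) != self.pixels.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.pixels.shape[1]} channels"
            )

    @property
    def n_timepoints(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[1]

    def timepoint_hours(self, index: int) -> float:
        return self.t0_h + index * self.frame_interval_h


@dataclass
class Projection:
    """A 2-D calibrated image, normally a maximum projection along z."""

    pixels: np.ndarray
    pixel_size: tuple[float, float] = DEFAULT_VOXEL_SIZE[:2]
    timepoint_h: float = 0.0
    channel: str = "channel0"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"Projection must be 2-D; got {self.pixels.ndim} axes")
        if any(v <= 0 for v in self.pixel_size):
            raise ValueError(f"pixel_size must be positive; got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


# ---------------------------------------------------------------------------
# OME-TIFF round trip
# ---------------------------------------------------------------------------

def write_series(series: VolumeSeries, path) -> str:
    """Write a series as OME-TIFF (TCZYX) with calibration metadata."""
    dx, dy, dz = series.voxel_size
    metadata = {
        "axes": "TCZYX",
        "PhysicalSizeX": dx,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": dy,
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeZ": dz,
        "PhysicalSizeZUnit": "µm",
        "TimeIncrement": series.frame_interval_h,
        "TimeIncrementUnit": "h",
        "Channel": {"Name": list(series.channel_names)},
    }
    tifffile.imwrite(str(path), series.pixels, ome=True, metadata=metadata)
    return str(path)


def _parse_ome_calibration(ome_xml: str):
    """Pull voxel size, frame interval and channel names out of OME XML."""
    root = ET.fromstring(ome_xml)
    ns = ""
    if root.tag.startswith("{"):
        ns = root.tag[: root.tag.index("}") + 1]
    pixels_el = root.find(f".//{ns}Pixels")
    if pixels_el is None:
        return None, None, None
    def attr(name):
        v = pixels_el.get(name)
        return float(v) if v is not None else None
    voxel = (attr("PhysicalSizeX"), attr("PhysicalSizeY"), attr("PhysicalSizeZ"))
    interval = attr("TimeIncrement")
    names = [c.get("Name") for c in pixels_el.findall(f"{ns}Channel")]
    if not names or any(n is None for n in names):
        names = None
    return voxel, interval, names


def read_series(
    path,
    default_voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    default_frame_interval_h: float = DEFAULT_FRAME_INTERVAL_H,
) -> VolumeSeries:
    """Read a TIFF / OME-TIFF into a ``VolumeSeries``.

    Axis order is taken from the file's metadata; series with fewer than
    five axes are promoted by inserting singleton axes for the missing
    ones (a 4-axis TZYX file becomes a single-channel series).  Missing
    calibration falls back to the configured defaults with a warning.
    """
    with tifffile.TiffFile(str(path)) as tf:
        ser = tf.series[0]
        data = ser.asarray()
        axes = ser.axes.upper().replace("S", "C").replace("Q", "Z")
        ome_xml = tf.ome_metadata

    for ax in axes:
        if ax not in "TCZYX":
            raise ValueError(
                f"cannot interpret axis {ax!r} in axis order {axes!r} of {path}"
            )
    if len(set(axes)) != len(axes):
        raise ValueError(f"ambiguous repeated axes {axes!r} in {path}")
    if "Y" not in axes or "X" not in axes:
        raise ValueError(f"no spatial Y/X axes inferable from {axes!r} in {path}")

    # promote to TCZYX
    for ax in "TCZYX":
        if ax not in axes:
            data = data[np.newaxis]
            axes = ax + axes
    order = [axes.index(ax) for ax in "TCZYX"]
    data = np.transpose(data, order)

    voxel, interval, names = (None, None, None)
    if ome_xml:
        voxel, interval, names = _parse_ome_calibration(ome_xml)

    if voxel is None or any(v is None for v in voxel):
        warnings.warn(
            f"{path}: no voxel calibration in file; using default "
            f"{default_voxel_size} µm",
            stacklevel=2,
        )
        voxel = default_voxel_size
    if interval is None:
        warnings.warn(
            f"{path}: no frame interval in file; using default "
            f"{default_frame_interval_h} h",
            stacklevel=2,
        )
        interval = default_frame_interval_h
    if names is None or len(names) != data.shape[1]:
        names = [f"channel{i}" for i in range(data.shape[1])]

    return VolumeSeries(
        pixels=data,
        voxel_size=tuple(voxel),
        frame_interval_h=float(interval),
        channel_names=list(names),
    )


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------

def max_project(series: VolumeSeries, timepoint: int, channel: int) -> Projection:
    """Maximum projection along z of one (timepoint, channel) stack."""
    if not 0 <= timepoint < series.n_timepoints:
        raise IndexError(f"timepoint {timepoint} out of range")
    if not 0 <= channel < series.n_channels:
        raise IndexError(f"channel {channel} out of range")
    proj = series.pixels[timepoint, channel].max(axis=0)
    return Projection(
        pixels=proj,
        pixel_size=series.voxel_size[:2],
        timepoint_h=series.timepoint_hours(timepoint),
        channel=series.channel_names[channel],
    )


# ---------------------------------------------------------------------------
# Stitching
# ---------------------------------------------------------------------------

def _tile_layout(extent: int, n: int, overlap_fraction: float):
    """Find integer (tile, overlap) so n tiles of size `tile` overlapping
    by `overlap` pixels exactly cover `extent` pixels."""
    if n == 1:
        return extent, 0
    for tile in range(int(np.ceil(extent / n)), extent + 1):
        ov = int(round(overlap_fraction * tile))
        if tile + (n - 1) * (tile - ov) == extent and tile > ov >= 0:
            return tile, ov
    raise ValueError(
        f"no integer tiling of {extent} px into {n} tiles at overlap "
        f"{overlap_fraction}; pick a compatible image size"
    )


def split_tiles(
    projection: Projection, grid: tuple[int, int], overlap_fraction: float
) -> list[Projection]:
    """Cut a projection into a rows x cols grid of overlapping tiles
    (row-major order), the inverse of :func:`stitch_tiles`."""
    rows, cols = grid
    h, w = projection.shape
    th, ov_y = _tile_layout(h, rows, overlap_fraction)
    tw, ov_x = _tile_layout(w, cols, overlap_fraction)
    tiles = []
    for r in range(rows):
        y0 = r * (th - ov_y)
        for c in range(cols):
            x0 = c * (tw - ov_x)
            tiles.append(
                replace(projection, pixels=projection.pixels[y0 : y0 + th, x0 : x0 + tw])
            )
    return tiles


def _feather_weights(tile_len: int, overlap: int, has_before: bool, has_after: bool):
    w = np.ones(tile_len)
    if overlap > 0:
        ramp = np.arange(1, overlap + 1) / (overlap + 1)
        if has_before:
            w[:overlap] = ramp
        if has_after:
            w[-overlap:] = ramp[::-1]
    return w


def stitch_tiles(
    tiles: list[Projection], grid: tuple[int, int], overlap_fraction: float
) -> Projection:
    """Assemble a rows x cols mosaic of equally sized overlapping tiles.

    Overlap zones are blended with linear feathering, so restitching the
    output of :func:`split_tiles` reproduces the original image.
    """
    rows, cols = grid
    if rows * cols != len(tiles):
        raise ValueError(f"grid {grid} does not match {len(tiles)} tiles")
    shapes = {t.shape for t in tiles}
    sizes = {t.pixel_size for t in tiles}
    if len(shapes) != 1 or len(sizes) != 1:
        raise ValueError("tiles must share shape and calibration")
    th, tw = tiles[0].shape
    ov_y = int(round(overlap_fraction * th)) if rows > 1 else 0
    ov_x = int(round(overlap_fraction * tw)) if cols > 1 else 0
    out_h = th + (rows - 1) * (th - ov_y)
    out_w = tw + (cols - 1) * (tw - ov_x)
    acc = np.zeros((out_h, out_w))
    wacc = np.zeros((out_h, out_w))
    for r in range(rows):
        wy = _feather_weights(th, ov_y, r > 0, r < rows - 1)
        y0 = r * (th - ov_y)
        for c in range(cols):
            wx = _feather_weights(tw, ov_x, c > 0, c < cols - 1)
            x0 = c * (tw - ov_x)
            w = np.outer(wy, wx)
            acc[y0 : y0 + th, x0 : x0 + tw] += w * np.asarray(
                tiles[r * cols + c].pixels, dtype=float
            )
            wacc[y0 : y0 + th, x0 : x0 + tw] += w
    return replace(tiles[0], pixels=acc / wacc)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def register_translation(
    reference: Projection, moving: Projection
) -> tuple[float, float]:
    """Translation (shift_y, shift_x) of `moving` relative to `reference`,
    in micrometres, by phase correlation.

    Shifting `moving` by the negated values brings it into register with
    `reference`.  Constant (featureless) images register at zero shift
    with a warning.
    """
    if reference.shape != moving.shape:
        raise ValueError("images must share shape")
    if reference.pixel_size != moving.pixel_size:
        raise ValueError("images must share calibration")
    ref = np.asarray(reference.pixels, dtype=float)
    mov = np.asarray(moving.pixels, dtype=float)
    if np.ptp(ref) == 0 or np.ptp(mov) == 0:
        warnings.warn("constant image: registration degenerate, returning zero shift")
        return (0.0, 0.0)
    shift, _, _ = phase_cross_correlation(ref, mov, upsample_factor=10)
    dy, dx = -shift[0], -shift[1]
    return (dy * reference.pixel_size[1], dx * reference.pixel_size[0])


def align_series(
    projections: list[Projection],
    max_shift_fraction: float = 0.25,
) -> tuple[list[Projection], pd.DataFrame]:
    """Align a time series of projections to its first frame.

    Pairwise translations between consecutive frames are chained into
    cumulative shifts relative to timepoint 0, each frame is resampled
    accordingly, and the applied shifts are returned as a table in
    micrometres.  The microscope returns to the same stage position
    every session, so genuine inter-frame drift is small; a pairwise
    shift larger than ``max_shift_fraction`` of the smaller image
    dimension is a spurious correlation peak (e.g. on a featureless
    frame) and is treated as zero with a warning.
    """
    if not projections:
        raise ValueError("empty projection list")
    first = projections[0]
    limit_um = max_shift_fraction * min(
        first.shape[0] * first.pixel_size[1], first.shape[1] * first.pixel_size[0]
    )
    dy_um, dx_um = 0.0, 0.0
    aligned = [projections[0]]
    rows = [
        {
            "timepoint_h": projections[0].timepoint_h,
            "shift_y_um": 0.0,
            "shift_x_um": 0.0,
        }
    ]
    for prev, cur in zip(projections, projections[1:]):
        sy, sx = register_translation(prev, cur)
        if np.hypot(sy, sx) > limit_um:
            warnings.warn(
                f"registration shift ({sy:.1f}, {sx:.1f}) µm at "
                f"t={cur.timepoint_h} h exceeds {limit_um:.1f} µm; "
                "treating as registration failure (zero shift)"
            )
            sy, sx = 0.0, 0.0
        dy_um += sy
        dx_um += sx
        px = cur.pixel_size
        shifted = ndi.shift(
            np.asarray(cur.pixels, dtype=float),
            (-dy_um / px[1], -dx_um / px[0]),
            order=1,
            mode="constant",
        )
        aligned.append(replace(cur, pixels=shifted))
        rows.append(
            {"timepoint_h": cur.timepoint_h, "shift_y_um": dy_um, "shift_x_um": dx_um}
        )
    return aligned, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Overlay
# ---------------------------------------------------------------------------

def overlay_timepoints(earlier: Projection, later: Projection) -> np.ndarray:
    """Two-colour composite: earlier signal green, later signal purple.

    Returns an (H, W, 3) float RGB array in [0, 1]; co-located signal
    renders white/grey because green and magenta are complementary.
    """
    if earlier.shape != later.shape:
        raise ValueError("projections must share shape")

    def norm(img):
        img = np.asarray(img, dtype=float)
        m = img.max()
        return img / m if m > 0 else img

    g = norm(earlier.pixels)
    m = norm(later.pixels)
    return np.stack([m, g, m], axis=-1)
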