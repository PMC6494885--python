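"""Ground-truthed synthetic data for every pipeline stage.

The generators emulate the statistical structure of longitudinal
slice-culture imaging: sparsely labelled cells with bright somata and
thin neurites, slow linear fluorophore accumulation in live cells,
abrupt loss of all fluorescence at death, occasional motile somata,
Poisson arrivals of newly labelled cells and Poisson cell divisions,
and sub-cellular reporter puncta.  Four entry points:

- :func:`simulate_movie` renders a full two-channel 5-D movie plus a
  ground-truth table;
- :func:`simulate_detection_series` produces the equivalent
  perfect-segmentation detection tables without rendering pixels;
- :func:`simulate_survival` draws grouped censored event times with a
  known hazard ratio;
- :func:`simulate_traces` draws linear-drift intensity traces;
- :func:`simulate_step_decline_tracks` builds random-walk tracks whose
  step length declines linearly in time.

Everything is driven by a single integer seed: identical configuration
and seed give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line

from .imgio import DEFAULT_VOXEL_SIZE, VolumeSeries
from .segment import Detection
from .survival import SurvivalRecord
from .track import Track

CHANNELS = ["morphology", "reporter"]


@dataclass
class SimConfig:
    """Generator configuration; defaults mirror the imaging conditions
    the pipeline targets (0.3225 x 0.3225 x 0.5 µm voxels, 24-h frame
    interval, ~8 µm soma radius, 0.7 a.u./h fluorophore drift).

    Rates are per the unit in the field name; all rates and sizes must
    be non-negative.  ``disease_fraction`` assigns that fraction of
    cells to a "disease" group whose death hazard is multiplied by
    ``exp(group_log_hr)``.
    """

    seed: int = 0
    image_shape: tuple[int, int, int] = (5, 512, 512)  # (n_z, n_y, n_x)
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE  # (dx, dy, dz) µm
    n_timepoints: int = 15
    frame_interval_h: float = 24.0
    t0_h: float = 24.0
    n_cells: int = 10
    soma_radius_um: float = 8.0
    neurite_count: int = 3
    neurite_length_um: float = 20.0
    neurite_intensity_fraction: float = 0.15
    soma_intensity_au: float = 100.0
    reporter_intensity_fraction: float = 0.8
    intensity_drift_au_per_h: float = 0.7
    background_au: float = 5.0
    noise_sd_au: float = 2.0
    motile_fraction: float = 0.01
    motile_step_um: float = 2.0
    division_rate_per_day: float = 0.0
    arrival_rate_per_day: float = 0.0
    death_hazard_per_h: float = 0.0
    group_log_hr: float = 0.0
    disease_fraction: float = 0.0
    death_fade_rate: float = 0.0  # 0 = hard step to background at death
    puncta_rate_per_h: float = 0.0
    puncta_area_log_mean: float = 3.0  # lognormal over µm²
    puncta_area_log_sd: float = 0.7
    puncta_intensity_au: float = 150.0

    def __post_init__(self) -> None:
        nonneg = [
            self.n_timepoints, self.n_cells, self.soma_radius_um,
            self.intensity_drift_au_per_h, self.background_au,
            self.noise_sd_au, self.motile_step_um, self.division_rate_per_day,
            self.arrival_rate_per_day, self.death_hazard_per_h,
            self.puncta_rate_per_h,
        ]
        if any(v < 0 for v in nonneg):
            raise ValueError("rates, counts and sizes must be non-negative")
        if not 0 <= self.motile_fraction <= 1:
            raise ValueError("motile_fraction must be a probability")
        if not 0 <= self.disease_fraction <= 1:
            raise ValueError("disease_fraction must be a probability")
        if self.frame_interval_h <= 0:
            raise ValueError("frame_interval_h must be positive")

    @property
    def timepoints_h(self) -> np.ndarray:
        return self.t0_h + self.frame_interval_h * np.arange(self.n_timepoints)

    @property
    def field_um(self) -> tuple[float, float]:
        """(width, height) of the field in µm."""
        _, ny, nx = self.image_shape
        return (nx * self.voxel_size[0], ny * self.voxel_size[1])


@dataclass
class GroundTruth:
    """Per-cell fates, per-timepoint true positions, and puncta.

    ``cells`` columns: cell_id, birth_time_h, death_time_h (NaN when the
    cell survives the movie), censored, group, motile, parent_id.
    ``positions`` columns: cell_id, timepoint_h, x_um, y_um, area_um2.
    ``puncta`` columns: cell_id, appear_time_h, area_um2, x_um, y_um.
    """

    cells: pd.DataFrame = field(default_factory=pd.DataFrame)
    positions: pd.DataFrame = field(default_factory=pd.DataFrame)
    puncta: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


# ---------------------------------------------------------------------------
# Event-level simulation (shared by movie and detection-series generators)
# ---------------------------------------------------------------------------

def _place_soma(rng, existing, width, height, margin, min_sep, retries=100):
    for _ in range(retries):
        x = rng.uniform(margin, width - margin)
        y = rng.uniform(margin, height - margin)
        if all((x - ex) ** 2 + (y - ey) ** 2 >= min_sep**2 for ex, ey in existing):
            return x, y
    raise ValueError(
        "could not place a soma without overlap after "
        f"{retries} retries: field too crowded for this configuration"
    )


def _simulate_ground_truth(config: SimConfig, rng: np.random.Generator) -> GroundTruth:
    width, height = config.field_um
    margin = config.soma_radius_um + 1.0
    # two somata at exactly 2r would abut and blur into one component;
    # leave a PSF-scaled gap so rendered cells stay separable
    min_sep = 2.0 * config.soma_radius_um + 5.0 * max(config.voxel_size[:2])
    times = config.timepoints_h
    t_end = times[-1]
    area = np.pi * config.soma_radius_um**2

    cells = []  # dicts; positions filled later
    occupied: list[tuple[float, float]] = []

    def death_time(birth, group):
        rate = config.death_hazard_per_h * (
            np.exp(config.group_log_hr) if group == "disease" else 1.0
        )
        if rate <= 0:
            return np.inf
        return birth + rng.exponential(1.0 / rate)

    def new_cell(birth, group, parent_id, pos):
        cid = len(cells)
        cells.append(
            {
                "cell_id": cid,
                "birth_time_h": birth,
                "death_time_h": death_time(birth, group),
                "group": group,
                "motile": bool(rng.random() < config.motile_fraction),
                "parent_id": parent_id,
                "_pos0": pos,
            }
        )
        occupied.append(pos)
        return cid

    def pick_group():
        return "disease" if rng.random() < config.disease_fraction else "control"

    for _ in range(config.n_cells):
        pos = _place_soma(rng, occupied, width, height, margin, min_sep)
        new_cell(times[0], pick_group(), -1, pos)

    # Poisson arrivals of newly labelled cells over the imaging span
    duration_days = (t_end - times[0]) / 24.0
    n_arrivals = rng.poisson(config.arrival_rate_per_day * duration_days)
    arrival_times = np.sort(
        rng.uniform(times[0], t_end, size=n_arrivals)
    )
    for at in arrival_times:
        pos = _place_soma(rng, occupied, width, height, margin, min_sep)
        new_cell(float(at), pick_group(), -1, pos)

    # walk positions frame by frame; spawn divisions along the way
    pos_rows = []
    i = 0
    while i < len(cells):
        # process cells in creation order so divisions append deterministically
        c = cells[i]
        i += 1
        cid = c["cell_id"]
        x, y = c["_pos0"]
        born, dead = c["birth_time_h"], c["death_time_h"]
        div_rate_h = config.division_rate_per_day / 24.0
        next_div = (
            born + rng.exponential(1.0 / div_rate_h) if div_rate_h > 0 else np.inf
        )
        for t in times:
            if t < born or t >= dead:
                continue
            if next_div <= t:
                # daughter displaced one soma diameter along a random direction
                theta = rng.uniform(0, 2 * np.pi)
                dxy = 2 * config.soma_radius_um
                cx = float(np.clip(x + dxy * np.cos(theta), margin, width - margin))
                cy = float(np.clip(y + dxy * np.sin(theta), margin, height - margin))
                new_cell(float(next_div), c["group"], cid, (cx, cy))
                next_div = np.inf
            pos_rows.append(
                {
                    "cell_id": cid,
                    "timepoint_h": float(t),
                    "x_um": x,
                    "y_um": y,
                    "area_um2": area,
                }
            )
            if c["motile"] and config.motile_step_um > 0:
                theta = rng.uniform(0, 2 * np.pi)
                x = float(np.clip(x + config.motile_step_um * np.cos(theta), margin, width - margin))
                y = float(np.clip(y + config.motile_step_um * np.sin(theta), margin, height - margin))

    # puncta: Poisson per live-cell-hour, appearing in the reporter channel
    punc_rows = []
    if config.puncta_rate_per_h > 0:
        for c in cells:
            exposure = min(c["death_time_h"], t_end) - c["birth_time_h"]
            if exposure <= 0:
                continue
            for _ in range(rng.poisson(config.puncta_rate_per_h * exposure)):
                at = rng.uniform(c["birth_time_h"], c["birth_time_h"] + exposure)
                a = float(
                    np.exp(rng.normal(config.puncta_area_log_mean, config.puncta_area_log_sd))
                )
                r = rng.uniform(0, 0.6 * config.soma_radius_um)
                th = rng.uniform(0, 2 * np.pi)
                punc_rows.append(
                    {
                        "cell_id": c["cell_id"],
                        "appear_time_h": float(at),
                        "area_um2": a,
                        "x_um": c["_pos0"][0] + r * np.cos(th),
                        "y_um": c["_pos0"][1] + r * np.sin(th),
                    }
                )

    cell_df = pd.DataFrame(
        [
            {
                "cell_id": c["cell_id"],
                "birth_time_h": c["birth_time_h"],
                "death_time_h": c["death_time_h"] if c["death_time_h"] <= t_end else np.nan,
                "censored": c["death_time_h"] > t_end,
                "group": c["group"],
                "motile": c["motile"],
                "parent_id": c["parent_id"],
            }
            for c in cells
        ],
        columns=[
            "cell_id", "birth_time_h", "death_time_h", "censored",
            "group", "motile", "parent_id",
        ],
    )
    pos_df = pd.DataFrame(
        pos_rows,
        columns=["cell_id", "timepoint_h", "x_um", "y_um", "area_um2"],
    )
    punc_df = pd.DataFrame(
        punc_rows,
        columns=["cell_id", "appear_time_h", "area_um2", "x_um", "y_um"],
    )
    return GroundTruth(cells=cell_df, positions=pos_df, puncta=punc_df)


def _cell_intensity(config: SimConfig, birth_h: float, t_h: float) -> float:
    return config.soma_intensity_au + config.intensity_drift_au_per_h * (t_h - birth_h)


# ---------------------------------------------------------------------------
# Detection-series generator (perfect segmentation, no pixels)
# ---------------------------------------------------------------------------

def simulate_detection_series(
    config: SimConfig,
) -> tuple[list[list[Detection]], GroundTruth]:
    """Per-timepoint Detection lists equivalent to perfect segmentation
    of :func:`simulate_movie`, without rendering any pixels."""
    rng = np.random.default_rng(config.seed)
    gt = _simulate_ground_truth(config, rng)
    birth = dict(zip(gt.cells["cell_id"], gt.cells["birth_time_h"]))
    frames: list[list[Detection]] = []
    for t in config.timepoints_h:
        sub = gt.positions[gt.positions["timepoint_h"] == t]
        dets = []
        for k, row in enumerate(sub.itertuples()):
            inten = _cell_intensity(config, birth[row.cell_id], t)
            dets.append(
                Detection(
                    timepoint_h=float(t),
                    label=k + 1,
                    centroid_um=(row.x_um, row.y_um),
                    area_um2=row.area_um2,
                    mean_intensity={
                        "morphology": inten,
                        "reporter": inten * config.reporter_intensity_fraction,
                    },
                )
            )
        frames.append(dets)
    return frames, gt


# ---------------------------------------------------------------------------
# Movie rendering
# ---------------------------------------------------------------------------

def _render_cell(frame_c, config, x_um, y_um, intensity, rng_neurites):
    """Draw one cell (soma disk + point-symmetric neurite strokes) into a
    (z, y, x) stack, before blurring.  Point symmetry keeps the rendered
    intensity-weighted centroid on the ground-truth centroid."""
    nz, ny, nx = frame_c.shape
    dx, dy = config.voxel_size[0], config.voxel_size[1]
    cx, cy = x_um / dx, y_um / dy
    r_px = config.soma_radius_um / dx
    zc = nz // 2
    rr, cc = draw_disk((cy, cx), r_px, shape=(ny, nx))
    zlo, zhi = max(0, zc - 1), min(nz, zc + 2)
    for z in range(zlo, zhi):
        frame_c[z, rr, cc] += intensity
    # neurites run from the soma boundary outward, as opposite-ray pairs;
    # drawn dimmer than the soma so segmentation stays soma-centric
    n_len_px = (config.neurite_length_um + config.soma_radius_um) / dx
    for theta in rng_neurites:
        for sgn in (1.0, -1.0):
            sy = cy + sgn * r_px * np.sin(theta)
            sx = cx + sgn * r_px * np.cos(theta)
            ty = cy + sgn * n_len_px * np.sin(theta)
            tx = cx + sgn * n_len_px * np.cos(theta)
            rr, cc = draw_line(
                int(round(sy)), int(round(sx)), int(round(ty)), int(round(tx))
            )
            keep = (rr >= 0) & (rr < ny) & (cc >= 0) & (cc < nx)
            frame_c[zc, rr[keep], cc[keep]] += (
                intensity * config.neurite_intensity_fraction
            )


def simulate_movie(config: SimConfig) -> tuple[VolumeSeries, GroundTruth]:
    """Render a two-channel (morphology, reporter) 5-D movie.

    Cells are soma disks convolved with a Gaussian point-spread proxy
    (sigma 1 px) plus 1-px neurite strokes; live-cell intensity rises at
    ``intensity_drift_au_per_h``; a dead cell's fluorescence is
    background-only from the first frame after its death time (abrupt
    loss); Gaussian noise is added everywhere.  The same seed and
    configuration give a bit-identical movie and ground truth.
    """
    rng = np.random.default_rng(config.seed)
    gt = _simulate_ground_truth(config, rng)
    nz, ny, nx = config.image_shape
    T = config.n_timepoints
    movie = np.zeros((T, 2, nz, ny, nx), dtype=np.float32)
    birth = dict(zip(gt.cells["cell_id"], gt.cells["birth_time_h"]))
    neurite_angles = {
        int(cid): np.random.default_rng(config.seed + 7919 + int(cid)).uniform(
            0, np.pi, size=config.neurite_count
        )
        for cid in gt.cells["cell_id"]
    }
    dx, dy = config.voxel_size[0], config.voxel_size[1]
    for ti, t in enumerate(config.timepoints_h):
        sub = gt.positions[gt.positions["timepoint_h"] == t]
        frame = np.zeros((2, nz, ny, nx), dtype=float)
        for row in sub.itertuples():
            inten = _cell_intensity(config, birth[row.cell_id], t)
            _render_cell(
                frame[0], config, row.x_um, row.y_um, inten,
                neurite_angles[int(row.cell_id)],
            )
            _render_cell(
                frame[1], config, row.x_um, row.y_um,
                inten * config.reporter_intensity_fraction,
                neurite_angles[int(row.cell_id)],
            )
            owned = gt.puncta[
                (gt.puncta["cell_id"] == row.cell_id)
                & (gt.puncta["appear_time_h"] <= t)
            ]
            zc = nz // 2
            for p in owned.itertuples():
                pr = np.sqrt(p.area_um2 / np.pi) / dx
                rr, cc = draw_disk((p.y_um / dy, p.x_um / dx), pr, shape=(ny, nx))
                frame[1, zc, rr, cc] += config.puncta_intensity_au
        for c in range(2):
            for z in range(nz):
                frame[c, z] = ndi.gaussian_filter(frame[c, z], sigma=1.0)
        frame += config.background_au
        frame += rng.normal(0.0, config.noise_sd_au, size=frame.shape)
        movie[ti] = np.clip(frame, 0.0, None)
    series = VolumeSeries(
        pixels=movie,
        voxel_size=config.voxel_size,
        frame_interval_h=config.frame_interval_h,
        channel_names=list(CHANNELS),
        t0_h=config.t0_h,
    )
    return series, gt


# ---------------------------------------------------------------------------
# Survival and trace generators
# ---------------------------------------------------------------------------

def simulate_survival(
    n_control: int,
    n_disease: int,
    log_hr: float,
    baseline_rate_per_h: float,
    censor_time_h: float,
    frame_interval_h: float,
    seed: int,
    group_names: tuple[str, str] = ("control", "disease"),
) -> list[SurvivalRecord]:
    """Two-group exponential event times on a sampling grid.

    Disease hazard = baseline x exp(log_hr).  Raw event times are
    discretised upward to the next frame (death is observed at the first
    session after it happens); times beyond ``censor_time_h`` are
    censored there.
    """
    if n_control <= 0 or n_disease <= 0:
        raise ValueError("group sizes must be positive")
    if baseline_rate_per_h <= 0 or frame_interval_h <= 0:
        raise ValueError("rates must be positive")
    rng = np.random.default_rng(seed)
    records = []
    cid = 0
    for name, n, rate in (
        (group_names[0], n_control, baseline_rate_per_h),
        (group_names[1], n_disease, baseline_rate_per_h * np.exp(log_hr)),
    ):
        raw = rng.exponential(1.0 / rate, size=n)
        for t in raw:
            if t > censor_time_h:
                records.append(SurvivalRecord(cid, name, censor_time_h, 0))
            else:
                grid = float(np.ceil(t / frame_interval_h) * frame_interval_h)
                records.append(SurvivalRecord(cid, name, min(grid, censor_time_h), 1))
            cid += 1
    return records


def simulate_traces(
    n_traces: int,
    slope_au_per_h: float,
    duration_h: float,
    frame_interval_h: float,
    noise_sd: float,
    seed: int,
    n_background: int | None = None,
    intercept_au: tuple[float, float] = (80.0, 120.0),
    background_au: float = 5.0,
) -> pd.DataFrame:
    """Linear-drift intensity traces plus flat background traces.

    Returns a long table (trace_id, timepoint_h, intensity,
    is_background): cell traces are intercept + slope*t + N(0, noise_sd)
    sampled every ``frame_interval_h`` from 0 to ``duration_h``
    inclusive; background traces have slope 0 around ``background_au``.
    """
    if duration_h % frame_interval_h != 0:
        raise ValueError("duration_h must be divisible by frame_interval_h")
    if n_background is None:
        n_background = n_traces
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_h + frame_interval_h / 2, frame_interval_h)
    rows = []
    for i in range(n_traces):
        b = rng.uniform(*intercept_au)
        y = b + slope_au_per_h * t + rng.normal(0, noise_sd, size=t.size)
        rows.extend(
            {"trace_id": i, "timepoint_h": tt, "intensity": yy, "is_background": False}
            for tt, yy in zip(t, y)
        )
    for j in range(n_background):
        y = background_au + rng.normal(0, noise_sd, size=t.size)
        rows.extend(
            {
                "trace_id": n_traces + j,
                "timepoint_h": tt,
                "intensity": yy,
                "is_background": True,
            }
            for tt, yy in zip(t, y)
        )
    return pd.DataFrame(rows)


def simulate_step_decline_tracks(
    n_tracks: int,
    n_timepoints: int,
    frame_interval_h: float,
    step_start_um: float,
    step_decline_um_per_day: float,
    jitter_sd_um: float,
    seed: int,
    soma_area_um2: float = 200.0,
) -> list[Track]:
    """Random-walk tracks whose per-interval step length declines
    linearly in time — the regime of cells settling into a slice.

    The step taken over the interval ending on day d has mean
    ``step_start_um - step_decline_um_per_day * (d - 1)`` (clipped at
    zero) with Gaussian jitter; directions are isotropic.
    """
    rng = np.random.default_rng(seed)
    times = frame_interval_h * np.arange(n_timepoints)
    tracks = []
    for i in range(n_tracks):
        x, y = rng.uniform(0, 2000, size=2)
        tr = Track(cell_id=i)
        for k, t in enumerate(times):
            tr.add(
                Detection(
                    timepoint_h=float(t),
                    label=i + 1,
                    centroid_um=(x, y),
                    area_um2=soma_area_um2,
                    mean_intensity={"morphology": 100.0},
                )
            )
            if k + 1 < n_timepoints:
                day_end = times[k + 1] / 24.0
                mean_step = max(
                    0.0, step_start_um - step_decline_um_per_day * (day_end - 1.0)
                )
                step = max(0.0, rng.normal(mean_step, jitter_sd_um))
                theta = rng.uniform(0, 2 * np.pi)
                x += step * np.cos(theta)
                y += step * np.sin(theta)
        tracks.append(tr)
    return tracks
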