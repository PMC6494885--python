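"""Per-track and population quantification.

Kinematics (step distances, net displacement, velocity), the
two-somata-lengths motility rule, pooled intensity-trend regression with
ANCOVA against background, cumulative cell-count rates, and the
mean-travel-distance trend with per-timepoint ANOVA / Tukey comparisons.

Trace tables used throughout have columns ``trace_id``, ``timepoint_h``
and ``intensity`` (or a ``value`` column for generic series).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .track import Track, count_tracked


@dataclass
class MotilityConfig:
    """Motility call: a cell is motile when its maximum centroid
    separation over the whole track exceeds ``soma_lengths_threshold``
    soma lengths (strictly — "more than").  Soma length is the
    equivalent-circle diameter of the track's median detection area,
    which is robust to frame-to-frame neurite-driven area swings."""

    soma_lengths_threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.soma_lengths_threshold <= 0:
            raise ValueError("threshold must be positive")


@dataclass
class TrendResult:
    """A fitted linear trend plus optional group-comparison statistics."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    units: str = ""
    stat_name: str = ""
    statistic: float = np.nan
    p_value: float = np.nan
    extra: dict = field(default_factory=dict)


@dataclass
class Kinematics:
    """Per-track motion summary; ``valid`` is False for single-detection
    tracks, whose kinematics are undefined rather than erroneous."""

    valid: bool
    step_um: np.ndarray
    step_end_h: np.ndarray
    path_length_um: float
    net_displacement_um: float
    mean_velocity_um_per_h: float
    max_separation_um: float


def track_kinematics(track: Track) -> Kinematics:
    """Step distances, path length, net displacement and mean velocity.

    Steps are Euclidean centroid distances between consecutive
    detections; velocity is path length over elapsed time.
    """
    times = np.array(track.timepoints, dtype=float)
    if len(times) < 2:
        return Kinematics(
            valid=False,
            step_um=np.array([]),
            step_end_h=np.array([]),
            path_length_um=np.nan,
            net_displacement_um=np.nan,
            mean_velocity_um_per_h=np.nan,
            max_separation_um=0.0,
        )
    xy = track.centroids_um()
    steps = np.hypot(*(np.diff(xy, axis=0).T))
    path = float(steps.sum())
    net = float(np.hypot(*(xy[-1] - xy[0])))
    elapsed = times[-1] - times[0]
    diff = xy[:, None, :] - xy[None, :, :]
    sep = np.hypot(diff[..., 0], diff[..., 1])
    return Kinematics(
        valid=True,
        step_um=steps,
        step_end_h=times[1:],
        path_length_um=path,
        net_displacement_um=net,
        mean_velocity_um_per_h=path / elapsed if elapsed > 0 else np.nan,
        max_separation_um=float(sep.max()),
    )


def soma_length_um(track: Track) -> float:
    """Equivalent-circle diameter of the track's median detection area."""
    areas = np.array([d.area_um2 for d in track.detections.values()])
    return float(2.0 * np.sqrt(np.median(areas) / np.pi))


def classify_motile(track: Track, config: MotilityConfig | None = None) -> bool:
    """True when max centroid separation strictly exceeds the threshold
    number of soma lengths; single-detection tracks are not motile."""
    if config is None:
        config = MotilityConfig()
    kin = track_kinematics(track)
    if not kin.valid:
        return False
    return kin.max_separation_um > config.soma_lengths_threshold * soma_length_um(track)


# ---------------------------------------------------------------------------
# Trend regressions
# ---------------------------------------------------------------------------

def _pooled_ols(time_h: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    X = sm.add_constant(time_h)
    fit = sm.OLS(y, X).fit()
    return float(fit.params[1]), float(fit.params[0]), float(fit.rsquared)


def intensity_trend(
    cell_traces: pd.DataFrame,
    background_traces: pd.DataFrame | None = None,
    units: str = "a.u./h",
) -> TrendResult:
    """Pooled intensity-versus-time regression, with ANCOVA vs background.

    ``cell_traces`` (and optionally ``background_traces``) are long
    tables with columns trace_id, timepoint_h, intensity.  The slope is
    the pooled OLS fit over all cell observations; when background
    traces are given, the slope difference is tested with an ANCOVA —
    the F-test on the group x time interaction in
    ``intensity ~ time * group``.
    """
    t = cell_traces["timepoint_h"].to_numpy(dtype=float)
    y = cell_traces["intensity"].to_numpy(dtype=float)
    if len(np.unique(t)) < 3:
        raise ValueError("need >= 3 timepoints for a trend")
    slope, intercept, r2 = _pooled_ols(t, y)
    res = TrendResult(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        n=int(cell_traces["trace_id"].nunique()),
        units=units,
    )
    if background_traces is not None and len(background_traces):
        f, p = compare_slopes_ancova(cell_traces, background_traces)
        res.stat_name = "ANCOVA interaction F"
        res.statistic = f
        res.p_value = p
    return res


def compare_slopes_ancova(
    group_a: pd.DataFrame, group_b: pd.DataFrame
) -> tuple[float, float]:
    """ANCOVA slope comparison between two groups of time series.

    Fits ``y ~ time * group`` over the pooled observations and returns
    the F statistic and p-value of the group x time interaction — the
    standard test for unequal slopes.
    """
    if group_a["trace_id"].nunique() < 2 or group_b["trace_id"].nunique() < 2:
        raise ValueError("each group needs >= 2 series")
    df = pd.concat(
        [group_a.assign(group="a"), group_b.assign(group="b")], ignore_index=True
    )
    ycol = "intensity" if "intensity" in df.columns else "value"
    fit = smf.ols(f"{ycol} ~ timepoint_h * C(group)", data=df).fit()
    test = fit.f_test("timepoint_h:C(group)[T.b]")
    return float(test.fvalue), float(test.pvalue)


def cell_count_rate(counts: pd.DataFrame, column: str = "n_cumulative") -> TrendResult:
    """OLS slope of cumulative tracked-cell count versus time, in
    cells/day.  ``counts`` is the table from
    :func:`slicetrack.track.count_tracked`."""
    if len(counts) < 3:
        raise ValueError("need >= 3 timepoints")
    days = counts["timepoint_h"].to_numpy(dtype=float) / 24.0
    y = counts[column].to_numpy(dtype=float)
    slope, intercept, r2 = _pooled_ols(days, y)
    return TrendResult(
        slope=slope, intercept=intercept, r_squared=r2, n=len(counts),
        units="cells/day",
    )


def mean_distance_trend(tracks: list[Track]) -> TrendResult:
    """Trend of mean per-interval travel distance over time, in nm/day.

    For every timepoint the step distances of all tracks whose interval
    ends there are averaged; the per-timepoint means are regressed on
    time (OLS, slope reported in nm/day), and the per-timepoint step
    distributions are compared by one-way ANOVA with Tukey HSD pairwise
    p-values (in ``extra``).  "Distance travelled" is the per-interval
    step, not the cumulative path, so a declining trend is meaningful.
    """
    rows = []
    for tr in tracks:
        kin = track_kinematics(tr)
        if not kin.valid:
            continue
        for t, s in zip(kin.step_end_h, kin.step_um):
            rows.append({"timepoint_h": t, "step_um": s})
    if not rows:
        raise ValueError("no multi-detection tracks")
    df = pd.DataFrame(rows)
    per_t = df.groupby("timepoint_h")["step_um"].mean().reset_index()
    if len(per_t) < 3:
        raise ValueError("need >= 3 timepoints")
    days = per_t["timepoint_h"].to_numpy(dtype=float) / 24.0
    mean_nm = per_t["step_um"].to_numpy(dtype=float) * 1000.0
    slope, intercept, r2 = _pooled_ols(days, mean_nm)
    res = TrendResult(
        slope=slope, intercept=intercept, r_squared=r2, n=len(per_t),
        units="nm/day",
    )
    groups = [g["step_um"].to_numpy() for _, g in df.groupby("timepoint_h")]
    if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
        f, p = stats.f_oneway(*groups)
        res.stat_name = "ANOVA F"
        res.statistic = float(f)
        res.p_value = float(p)
        tk = pairwise_tukeyhsd(
            df["step_um"].to_numpy(), df["timepoint_h"].astype(str).to_numpy()
        )
        res.extra["tukey"] = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0]
        )
    return res


def feature_table(tracks: list[Track]) -> pd.DataFrame:
    """Per-track summary: span, kinematics, soma length, motility flag."""
    rows = []
    for tr in tracks:
        kin = track_kinematics(tr)
        rows.append(
            {
                "cell_id": tr.cell_id,
                "first_seen_h": tr.first_seen_h,
                "last_seen_h": tr.last_seen_h,
                "n_detections": len(tr),
                "path_length_um": kin.path_length_um,
                "net_displacement_um": kin.net_displacement_um,
                "mean_velocity_um_per_h": kin.mean_velocity_um_per_h,
                "max_separation_um": kin.max_separation_um,
                "soma_length_um": soma_length_um(tr),
                "motile": classify_motile(tr),
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "MotilityConfig",
    "TrendResult",
    "Kinematics",
    "track_kinematics",
    "soma_length_um",
    "classify_motile",
    "intensity_trend",
    "compare_slopes_ancova",
    "cell_count_rate",
    "mean_distance_trend",
    "feature_table",
    "count_tracked",
]
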