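"""Single-cell survival analysis.

Death is called from the morphology-channel intensity trace of each
tracked cell: an abrupt, sustained drop to background marks membrane
rupture.  The resulting censored event times feed a Kaplan-Meier
product-limit estimator, the Gehan-Breslow-Wilcoxon weighted log-rank
test, a Cox proportional-hazards fit (Efron tie handling; hazard ratio
with Wald 95% CI), Nelson-Aalen cumulative hazards and a
hazard-linearity test.  Event times are measured in hours from the
first imaging session; an event observed on a 24-h grid is recorded at
the first frame at which the loss is seen.

Manual death annotations, when available, take precedence over the
automated caller (see :func:`apply_manual_annotations`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter, NelsonAalenFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy import optimize, stats

from .track import Track


@dataclass
class DeathCallConfig:
    """Automated death-call parameters.

    A cell is scored dead at the first timepoint where its morphology
    mean intensity falls to within ``drop_to_background_k`` background
    standard deviations of the background mean, sustained for
    ``persistence_frames`` consecutive frames; a track that simply
    terminates before the end of the movie is likewise scored dead at
    its first missing frame.
    """

    drop_to_background_k: float = 3.0
    persistence_frames: int = 2
    channel: str = "morphology"

    def __post_init__(self) -> None:
        if self.drop_to_background_k <= 0:
            raise ValueError("drop_to_background_k must be positive")
        if self.persistence_frames < 1:
            raise ValueError("persistence_frames must be >= 1")


@dataclass
class SurvivalRecord:
    """One cell's event datum: time (h) and whether death was observed."""

    cell_id: int
    group: str
    time_h: float
    event: int  # 1 = death observed, 0 = censored

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValueError("time_h must be >= 0")
        if self.event not in (0, 1):
            raise ValueError("event flag must be 0 or 1")


@dataclass
class SurvivalFit:
    """Cox proportional-hazards result plus the nonparametric curves."""

    hazard_ratio: float
    ci_low: float
    ci_high: float
    coef: float
    se: float
    wald_z: float
    wald_p: float
    lr_statistic: float
    lr_p: float
    n: int
    n_events: int
    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    cumulative_hazards: dict[str, pd.DataFrame] = field(default_factory=dict)
    linearity_chi2: float = np.nan
    linearity_p: float = np.nan


def records_to_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"cell_id": r.cell_id, "group": r.group, "time_h": r.time_h, "event": r.event}
            for r in records
        ]
    )


def frame_to_records(df: pd.DataFrame) -> list[SurvivalRecord]:
    return [
        SurvivalRecord(
            cell_id=int(row.cell_id),
            group=str(row.group),
            time_h=float(row.time_h),
            event=int(row.event),
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Death calling
# ---------------------------------------------------------------------------

def call_death(
    track: Track,
    background_mean: float,
    background_sd: float,
    movie_end_h: float,
    config: DeathCallConfig | None = None,
    group: str = "",
    time_origin_h: float | None = None,
) -> SurvivalRecord:
    """Score one track's fate from its morphology intensity trace.

    The event time is the first timepoint at which the mean intensity is
    <= background_mean + k*background_sd, sustained for the configured
    number of consecutive frames (or through the end of the trace), or —
    failing that — the track's termination before ``movie_end_h``.
    Otherwise the cell is censored at its last observation.  Times are
    reported relative to ``time_origin_h`` (default: the track's first
    timepoint).
    """
    if config is None:
        config = DeathCallConfig()
    if not np.isfinite(background_mean) or not np.isfinite(background_sd):
        raise ValueError("missing background estimate")
    origin = track.first_seen_h if time_origin_h is None else time_origin_h
    times = track.timepoints
    trace = np.array(
        [track.detections[t].mean_intensity[config.channel] for t in times]
    )
    cutoff = background_mean + config.drop_to_background_k * background_sd
    low = trace <= cutoff
    for i in range(len(times)):
        run = low[i : i + config.persistence_frames]
        if low[i] and (len(run) == config.persistence_frames or i + len(run) == len(times)) and run.all():
            return SurvivalRecord(track.cell_id, group, times[i] - origin, 1)
    if track.last_seen_h < movie_end_h:
        return SurvivalRecord(track.cell_id, group, track.last_seen_h - origin, 1)
    return SurvivalRecord(track.cell_id, group, track.last_seen_h - origin, 0)


def apply_manual_annotations(
    records: list[SurvivalRecord], annotations: pd.DataFrame
) -> list[SurvivalRecord]:
    """Override automated calls with a manual-annotation table
    (columns ``cell_id``, ``death_time_h``)."""
    manual = {int(r.cell_id): float(r.death_time_h) for r in annotations.itertuples()}
    out = []
    for r in records:
        if r.cell_id in manual:
            out.append(SurvivalRecord(r.cell_id, r.group, manual[r.cell_id], 1))
        else:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# Estimators and tests
# ---------------------------------------------------------------------------

def km_curve(records: list[SurvivalRecord]) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit curves, one per group.

    Each curve is a DataFrame with columns ``time_h`` and ``survival``
    (right-continuous step function starting at 1; censored records
    shrink the risk set without producing steps).
    """
    if not records:
        raise ValueError("no records")
    df = records_to_frame(records)
    curves = {}
    for g, sub in df.groupby("group"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_h"], event_observed=sub["event"])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time_h", "survival"]
        curves[str(g)] = sf
    return curves


def gbw_test(records: list[SurvivalRecord]) -> tuple[float, float]:
    """Gehan-Breslow-Wilcoxon test between exactly two groups.

    A weighted log-rank test with weights equal to the number at risk,
    emphasising early events.  Returns (chi-square statistic, p).
    """
    df = records_to_frame(records)
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups; got {groups}")
    a = df[df["group"] == groups[0]]
    b = df[df["group"] == groups[1]]
    if a.empty or b.empty:
        raise ValueError("a group is empty")
    res = logrank_test(
        a["time_h"], b["time_h"],
        event_observed_A=a["event"], event_observed_B=b["event"],
        weightings="wilcoxon",
    )
    return float(res.test_statistic), float(res.p_value)


def cph_fit(
    records: list[SurvivalRecord],
    reference_group: str | None = None,
    linearity: bool = True,
    frame_interval_h: float | None = None,
) -> SurvivalFit:
    """Cox proportional-hazards fit with group as the sole covariate.

    Uses Efron's approximation for tied event times (a 24-h sampling
    grid produces heavy ties).  The hazard ratio is exp(coef) for the
    non-reference group, with a Wald 95% CI.  Complete separation is
    reported as an infinite hazard ratio with a warning rather than an
    exception.  KM and Nelson-Aalen curves per group are attached, and
    (by default) the hazard-linearity statistic from
    :func:`hazard_linearity`.
    """
    df = records_to_frame(records)
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups; got {groups}")
    if reference_group is None:
        reference_group = groups[0]
    other = [g for g in groups if g != reference_group][0]
    df["x"] = (df["group"] == other).astype(float)

    cph = CoxPHFitter()
    try:
        cph.fit(df[["time_h", "event", "x"]], duration_col="time_h", event_col="event")
        coef = float(cph.params_["x"])
        se = float(cph.standard_errors_["x"])
        hr = float(np.exp(coef))
        ci_low, ci_high = float(np.exp(coef - 1.96 * se)), float(np.exp(coef + 1.96 * se))
        z = coef / se
        lr = float(cph.log_likelihood_ratio_test().test_statistic)
        lr_p = float(cph.log_likelihood_ratio_test().p_value)
    except ConvergenceError:
        warnings.warn("complete separation: hazard ratio is infinite")
        coef, se, hr = np.inf, np.inf, np.inf
        ci_low, ci_high, z, lr, lr_p = np.nan, np.inf, np.inf, np.nan, np.nan

    fit = SurvivalFit(
        hazard_ratio=hr,
        ci_low=ci_low,
        ci_high=ci_high,
        coef=coef,
        se=se,
        wald_z=float(z),
        wald_p=float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0,
        lr_statistic=lr,
        lr_p=lr_p,
        n=len(df),
        n_events=int(df["event"].sum()),
        km_curves=km_curve(records),
    )
    fit.cumulative_hazards = {
        g: _nelson_aalen(df[df["group"] == g]) for g in groups
    }
    if linearity and df["event"].sum() >= 5:
        chi2, p, _ = hazard_linearity(records, frame_interval_h=frame_interval_h)
        fit.linearity_chi2 = chi2
        fit.linearity_p = p
    return fit


def _nelson_aalen(sub: pd.DataFrame) -> pd.DataFrame:
    naf = NelsonAalenFitter()
    naf.fit(sub["time_h"], event_observed=sub["event"])
    ch = naf.cumulative_hazard_.reset_index()
    ch.columns = ["time_h", "cumulative_hazard"]
    return ch


def _weibull_group_loglik(shape, times, events, interval) -> float:
    """Max (over the rate) Weibull log-likelihood for one group at fixed
    shape k, hazard h(t) = lam*k*t^(k-1).

    With ``interval`` set, event times sit on a sampling grid and each
    event contributes the interval-censored mass S(t - interval) - S(t)
    instead of the density (deaths are only known to the session at
    which they were first seen)."""
    t = np.maximum(times, 1e-9)
    d = events.astype(bool)
    tk = t**shape
    if d.sum() == 0:
        return 0.0
    if not interval:
        # closed-form profile rate
        lam = d.sum() / tk.sum()
        return float(
            d.sum() * (np.log(lam) + np.log(shape))
            + (shape - 1) * np.log(t[d]).sum()
            - lam * tk.sum()
        )
    lo_k = np.maximum(t - interval, 0.0) ** shape

    def negll(loglam):
        lam = np.exp(loglam)
        mass = np.exp(-lam * lo_k[d]) - np.exp(-lam * tk[d])
        return -(np.log(np.maximum(mass, 1e-300)).sum() - lam * tk[~d].sum())

    opt = optimize.minimize_scalar(negll, bounds=(-25.0, 5.0), method="bounded")
    return float(-opt.fun)


def hazard_linearity(
    records: list[SurvivalRecord],
    frame_interval_h: float | None = None,
) -> tuple[float, float, dict[str, pd.DataFrame]]:
    """Test whether the cumulative hazard increases linearly in time.

    A constant hazard (exponential event times) makes the cumulative
    hazard a straight line through the origin.  The test embeds the
    exponential model in a Weibull family sharing one shape parameter
    across groups with a free rate per group, and compares the profile
    likelihood at the fitted shape against shape = 1 (likelihood-ratio
    chi-square, 1 df).  Pass ``frame_interval_h`` when event times were
    discretised to a sampling grid so the likelihood treats them as
    interval-censored; otherwise coarse rounding alone mimics an
    increasing hazard.  Returns (chi2, p, Nelson-Aalen cumulative
    hazard per group).  Refuses datasets with fewer than 5 events.
    """
    df = records_to_frame(records)
    if df["event"].sum() < 5:
        raise ValueError("too few events (< 5) for a linearity test")
    times = df["time_h"].to_numpy(dtype=float)
    events = df["event"].to_numpy(dtype=int)
    groups = df["group"].to_numpy()

    def loglik(shape):
        return sum(
            _weibull_group_loglik(
                shape, times[groups == g], events[groups == g], frame_interval_h
            )
            for g in np.unique(groups)
        )

    opt = optimize.minimize_scalar(
        lambda logk: -loglik(np.exp(logk)), bounds=(-3.0, 3.0), method="bounded"
    )
    chi2 = max(0.0, 2.0 * (-opt.fun - loglik(1.0)))
    p = float(stats.chi2.sf(chi2, df=1))
    curves = {str(g): _nelson_aalen(df[df["group"] == g]) for g in np.unique(groups)}
    return float(chi2), p, curves
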