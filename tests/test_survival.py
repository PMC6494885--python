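"""Death calling, Kaplan-Meier, Gehan-Breslow-Wilcoxon, Cox PH."""

import numpy as np
import pytest

from conftest import make_detection
from slicetrack.simulate import simulate_survival
from slicetrack.survival import (
    DeathCallConfig,
    SurvivalRecord,
    apply_manual_annotations,
    call_death,
    cph_fit,
    gbw_test,
    hazard_linearity,
    km_curve,
    records_to_frame,
)
from slicetrack.track import Track

import pandas as pd


def _track_from_trace(trace, interval=24.0, cell_id=0):
    tr = Track(cell_id=cell_id)
    for k, v in enumerate(trace):
        tr.add(
            make_detection(
                0, 0, t=k * interval, label=cell_id + 1,
                intensity={"morphology": float(v)},
            )
        )
    return tr


class TestCallDeath:
    def test_sustained_drop_scored_at_first_low_frame(self):
        tr = _track_from_trace([100, 102, 98, 6, 5])
        rec = call_death(tr, 5.0, 1.0, movie_end_h=96.0,
                         config=DeathCallConfig(drop_to_background_k=3, persistence_frames=2))
        assert rec.event == 1
        assert rec.time_h == 72.0  # 4th timepoint, origin at first frame

    def test_transient_dip_not_scored(self):
        tr = _track_from_trace([100, 6, 98, 97, 99])
        rec = call_death(tr, 5.0, 1.0, movie_end_h=96.0,
                         config=DeathCallConfig(persistence_frames=2))
        assert rec.event == 0

    def test_bright_to_end_censored_at_last_timepoint(self):
        tr = _track_from_trace([100, 101, 99, 100])
        rec = call_death(tr, 5.0, 1.0, movie_end_h=72.0)
        assert rec.event == 0 and rec.time_h == 72.0

    def test_track_termination_scored_as_death(self):
        tr = _track_from_trace([100, 101])  # movie continues to 96 h
        rec = call_death(tr, 5.0, 1.0, movie_end_h=96.0)
        assert rec.event == 1 and rec.time_h == 24.0

    def test_missing_background_rejected(self):
        tr = _track_from_trace([100, 100])
        with pytest.raises(ValueError):
            call_death(tr, float("nan"), 1.0, movie_end_h=24.0)

    def test_manual_annotations_override(self):
        recs = [SurvivalRecord(0, "g", 96.0, 0), SurvivalRecord(1, "g", 96.0, 0)]
        ann = pd.DataFrame({"cell_id": [1], "death_time_h": [48.0]})
        out = apply_manual_annotations(recs, ann)
        assert out[0].event == 0
        assert out[1].event == 1 and out[1].time_h == 48.0


class TestKaplanMeier:
    def _hand_example(self):
        return [
            SurvivalRecord(0, "g", 24.0, 1),
            SurvivalRecord(1, "g", 48.0, 1),
            SurvivalRecord(2, "g", 72.0, 0),
            SurvivalRecord(3, "g", 72.0, 0),
        ]

    def test_hand_product_limit_values(self):
        curve = km_curve(self._hand_example())["g"]
        s = dict(zip(curve["time_h"], curve["survival"]))
        assert s[24.0] == pytest.approx(0.75)
        assert s[48.0] == pytest.approx(0.50)

    def test_all_censored_curve_stays_at_one(self):
        recs = [SurvivalRecord(i, "g", 72.0, 0) for i in range(5)]
        assert (km_curve(recs)["g"]["survival"] == 1.0).all()

    def test_duplication_invariance(self):
        recs = self._hand_example()
        doubled = recs + [
            SurvivalRecord(r.cell_id + 10, r.group, r.time_h, r.event) for r in recs
        ]
        a = km_curve(recs)["g"]
        b = km_curve(doubled)["g"]
        np.testing.assert_allclose(a["survival"], b["survival"])

    def test_nonincreasing_from_one(self):
        recs = simulate_survival(50, 50, 0.5, 0.004, 336, 24, seed=2)
        for curve in km_curve(recs).values():
            s = curve["survival"].to_numpy()
            assert s[0] <= 1.0 + 1e-12
            assert (np.diff(s) <= 1e-12).all()


def _gehan_oracle(records):
    """Exhaustive Gehan-Breslow-Wilcoxon chi-square: weighted log-rank
    with weights = number at risk, computed from first principles."""
    df = records_to_frame(records)
    groups = sorted(df["group"].unique())
    u, var = 0.0, 0.0
    for t in sorted(df[df["event"] == 1]["time_h"].unique()):
        at_risk = df[df["time_h"] >= t]
        n = len(at_risk)
        n1 = (at_risk["group"] == groups[0]).sum()
        d = ((df["time_h"] == t) & (df["event"] == 1)).sum()
        d1 = (
            (df["time_h"] == t) & (df["event"] == 1) & (df["group"] == groups[0])
        ).sum()
        u += n * (d1 - d * n1 / n)
        if n > 1:
            var += n**2 * d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return u**2 / var


class TestGBW:
    def test_identical_groups_statistic_zero(self):
        recs = [SurvivalRecord(i, "a", t, 1) for i, t in enumerate([24, 48, 72])]
        recs += [SurvivalRecord(i + 3, "b", t, 1) for i, t in enumerate([24, 48, 72])]
        stat, p = gbw_test(recs)
        assert stat == pytest.approx(0.0, abs=1e-9)

    def test_matches_first_principles_oracle_on_small_fixture(self):
        recs = [
            SurvivalRecord(0, "a", 24.0, 1),
            SurvivalRecord(1, "a", 72.0, 1),
            SurvivalRecord(2, "a", 96.0, 0),
            SurvivalRecord(3, "b", 24.0, 1),
            SurvivalRecord(4, "b", 48.0, 1),
            SurvivalRecord(5, "b", 60.0, 1),
        ]
        stat, _ = gbw_test(recs)
        assert stat == pytest.approx(_gehan_oracle(recs), rel=1e-6)

    def test_extreme_separation_significant(self):
        recs = [SurvivalRecord(i, "a", 24.0 + i, 1) for i in range(15)]
        recs += [SurvivalRecord(100 + i, "b", 200.0 + i, 1) for i in range(15)]
        _, p = gbw_test(recs)
        assert p < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            gbw_test([SurvivalRecord(0, "a", 24.0, 1)])


class TestCoxPH:
    def test_identical_event_multisets_hr_one(self):
        times = [24.0, 48.0, 72.0, 96.0, 120.0, 144.0]
        recs = [SurvivalRecord(i, "a", t, 1) for i, t in enumerate(times)]
        recs += [SurvivalRecord(10 + i, "b", t, 1) for i, t in enumerate(times)]
        fit = cph_fit(recs, linearity=False)
        assert fit.hazard_ratio == pytest.approx(1.0, abs=0.01)

    def test_large_sample_consistency_rate_ratio_two(self):
        recs = simulate_survival(
            5000, 5000, np.log(2.0), 0.005, 336.0, 0.01, seed=42
        )
        fit = cph_fit(recs, linearity=False)
        assert fit.hazard_ratio == pytest.approx(2.0, rel=0.05)
        assert fit.ci_low < 2.0 < fit.ci_high

    def test_duplication_invariance(self):
        recs = simulate_survival(60, 60, 0.5, 0.004, 336, 24, seed=3)
        doubled = recs + [
            SurvivalRecord(1000 + r.cell_id, r.group, r.time_h, r.event) for r in recs
        ]
        a = cph_fit(recs, linearity=False)
        b = cph_fit(doubled, linearity=False)
        # Efron's tie correction is only asymptotically replication-
        # invariant (tie multiplicities double), hence the loose bound
        assert b.hazard_ratio == pytest.approx(a.hazard_ratio, rel=0.01)

    def test_record_order_invariance(self, rng):
        recs = simulate_survival(40, 40, 0.4, 0.004, 336, 24, seed=5)
        shuffled = [recs[i] for i in rng.permutation(len(recs))]
        assert cph_fit(shuffled, linearity=False).hazard_ratio == pytest.approx(
            cph_fit(recs, linearity=False).hazard_ratio
        )


class TestHazardLinearity:
    def test_too_few_events_refused(self):
        recs = [SurvivalRecord(i, "g", 24.0 * (i + 1), int(i < 3)) for i in range(10)]
        with pytest.raises(ValueError):
            hazard_linearity(recs)

    def test_constant_hazard_not_flagged(self):
        flags = 0
        for s in range(10):
            recs = simulate_survival(161, 180, np.log(1.9), 0.0027, 336, 24, seed=s)
            _, p, _ = hazard_linearity(recs, frame_interval_h=24.0)
            flags += p < 0.05
        assert flags <= 1

    def test_increasing_weibull_hazard_flagged(self):
        rng = np.random.default_rng(0)
        recs = []
        for i in range(300):
            t = 200.0 * rng.weibull(2.0)
            g = "a" if i < 150 else "b"
            recs.append(
                SurvivalRecord(i, g, min(t, 336.0), int(t <= 336.0))
            )
        chi2, p, curves = hazard_linearity(recs)
        assert p < 0.05
        for ch in curves.values():
            h = ch["cumulative_hazard"].to_numpy()
            assert (np.diff(h) >= -1e-12).all() and h[0] >= 0

    def test_cumulative_hazard_of_constant_rate_near_straight_line(self):
        recs = simulate_survival(4000, 4000, 0.0, 0.004, 400.0, 0.01, seed=1)
        _, _, curves = hazard_linearity(recs)
        ch = curves["control"]
        t = ch["time_h"].to_numpy()
        h = ch["cumulative_hazard"].to_numpy()
        keep = t < 300  # tail is noisy as the risk set empties
        np.testing.assert_allclose(h[keep], 0.004 * t[keep], rtol=0.15, atol=0.01)


def test_record_validation():
    with pytest.raises(ValueError):
        SurvivalRecord(0, "g", -1.0, 1)
    with pytest.raises(ValueError):
        SurvivalRecord(0, "g", 10.0, 2)
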