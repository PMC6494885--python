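"""Generator contracts: determinism, conservation, rendering fidelity,
statistical targets of the event processes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from slicetrack import imgio, segment
from slicetrack.simulate import (
    SimConfig,
    simulate_detection_series,
    simulate_movie,
    simulate_survival,
    simulate_traces,
)


class TestConfig:
    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(death_hazard_per_h=-1)
        with pytest.raises(ValueError):
            SimConfig(motile_fraction=1.5)

    def test_overcrowded_field_rejected(self):
        cfg = SimConfig(
            n_cells=200, image_shape=(1, 64, 64), voxel_size=(1.0, 1.0, 0.5),
            n_timepoints=2,
        )
        with pytest.raises(ValueError):
            simulate_detection_series(cfg)


class TestDeterminism:
    def test_movie_bit_identical_across_calls(self, small_movie_config):
        s1, g1 = simulate_movie(small_movie_config)
        s2, g2 = simulate_movie(small_movie_config)
        np.testing.assert_array_equal(s1.pixels, s2.pixels)
        pd.testing.assert_frame_equal(g1.cells, g2.cells)
        pd.testing.assert_frame_equal(g1.positions, g2.positions)

    def test_different_seeds_differ(self, small_movie_config):
        import dataclasses

        s1, _ = simulate_movie(small_movie_config)
        s2, _ = simulate_movie(dataclasses.replace(small_movie_config, seed=99))
        assert not np.array_equal(s1.pixels, s2.pixels)


class TestMovie:
    def test_empty_movie_is_background_noise_only(self):
        cfg = SimConfig(
            seed=1, n_cells=0, n_timepoints=3, image_shape=(2, 64, 64),
            voxel_size=(1.0, 1.0, 0.5), background_au=5.0, noise_sd_au=1.0,
        )
        series, gt = simulate_movie(cfg)
        assert gt.n_cells == 0 and gt.positions.empty
        assert abs(series.pixels.mean() - 5.0) < 0.5

    def test_deaths_visible_as_fluorescence_loss(self):
        """Brute-force pixel inspection: ground-truth death rows equal the
        count of cells whose rendered reporter signal falls to background."""
        cfg = SimConfig(
            seed=21, n_cells=10, n_timepoints=10, image_shape=(3, 256, 256),
            voxel_size=(1.0, 1.0, 0.5), death_hazard_per_h=0.004,
            background_au=5.0, noise_sd_au=1.0,
        )
        series, gt = simulate_movie(cfg)
        last = series.pixels[-1, 1].max(axis=0)  # reporter channel, final frame
        r = int(cfg.soma_radius_um)
        died_by_pixels = 0
        for row in gt.cells.itertuples():
            first = gt.positions[gt.positions.cell_id == row.cell_id].iloc[0]
            y, x = int(first.y_um), int(first.x_um)
            patch = last[max(0, y - r) : y + r, max(0, x - r) : x + r]
            if patch.mean() < cfg.background_au + 5 * cfg.noise_sd_au:
                died_by_pixels += 1
        assert died_by_pixels == int(gt.cells.death_time_h.notna().sum())

    def test_rendered_centroids_within_one_pixel_of_truth(self, small_movie_config):
        series, gt = simulate_movie(small_movie_config)
        proj = imgio.max_project(series, 0, 0)
        dets = segment.segment_cells(proj, segment.SegmentConfig(min_area_um2=20))
        truth = gt.positions[gt.positions.timepoint_h == proj.timepoint_h]
        assert len(dets) == len(truth)
        for d in dets:
            err = np.min(np.hypot(truth.x_um - d.x_um, truth.y_um - d.y_um))
            assert err < 1.0  # 1 px at 1 um/px

    def test_intensity_drift_rendered(self):
        cfg = SimConfig(
            seed=2, n_cells=1, n_timepoints=6, image_shape=(3, 96, 96),
            voxel_size=(1.0, 1.0, 0.5), intensity_drift_au_per_h=0.7,
            noise_sd_au=0.5,
        )
        series, gt = simulate_movie(cfg)
        x = gt.positions.iloc[0].x_um
        y = gt.positions.iloc[0].y_um
        peaks = [
            series.pixels[t, 0].max(axis=0)[int(y) - 2 : int(y) + 3,
                                            int(x) - 2 : int(x) + 3].mean()
            for t in range(6)
        ]
        slope = np.polyfit(24.0 * np.arange(6), peaks, 1)[0]
        assert slope == pytest.approx(0.7, rel=0.15)


class TestDetectionSeries:
    def test_matches_movie_event_structure(self, small_movie_config):
        frames, gt = simulate_detection_series(small_movie_config)
        assert len(frames) == small_movie_config.n_timepoints
        assert sum(len(f) for f in frames) == len(gt.positions)

    def test_no_detections_after_death(self):
        cfg = SimConfig(
            seed=3, n_cells=20, n_timepoints=12, death_hazard_per_h=0.006,
            image_shape=(1, 1000, 1000), voxel_size=(1.0, 1.0, 0.5),
        )
        _, gt = simulate_detection_series(cfg)
        dead = gt.cells.dropna(subset=["death_time_h"])
        assert len(dead) > 0
        merged = gt.positions.merge(dead[["cell_id", "death_time_h"]], on="cell_id")
        assert (merged.timepoint_h < merged.death_time_h).all()

    def test_poisson_arrival_count_within_three_sigma(self):
        cfg = SimConfig(
            seed=8, n_cells=10, n_timepoints=20, arrival_rate_per_day=10.0,
            image_shape=(1, 3000, 3000), voxel_size=(1.0, 1.0, 0.5),
        )
        _, gt = simulate_detection_series(cfg)
        expected = 10.0 * 19.0  # rate x days spanned by 20 daily frames
        arrivals = gt.n_cells - cfg.n_cells
        assert abs(arrivals - expected) <= 3 * np.sqrt(expected)

    def test_conservation_initial_plus_arrivals_plus_children(self):
        cfg = SimConfig(
            seed=4, n_cells=15, n_timepoints=10, arrival_rate_per_day=3.0,
            division_rate_per_day=0.05,
            image_shape=(1, 2000, 2000), voxel_size=(1.0, 1.0, 0.5),
        )
        _, gt = simulate_detection_series(cfg)
        children = (gt.cells.parent_id >= 0).sum()
        arrivals = (
            (gt.cells.parent_id < 0)
            & (gt.cells.birth_time_h > gt.cells.birth_time_h.min())
        ).sum()
        assert gt.n_cells == cfg.n_cells + arrivals + children
        # children born at their parent's division time, one diameter away
        for row in gt.cells[gt.cells.parent_id >= 0].itertuples():
            assert row.birth_time_h >= gt.cells.iloc[row.parent_id].birth_time_h

    def test_immobile_cells_never_move(self):
        cfg = SimConfig(
            seed=5, n_cells=12, n_timepoints=8, motile_fraction=0.0,
            image_shape=(1, 800, 800), voxel_size=(1.0, 1.0, 0.5),
        )
        _, gt = simulate_detection_series(cfg)
        spread = gt.positions.groupby("cell_id")[["x_um", "y_um"]].agg(np.ptp)
        assert (spread.to_numpy() == 0).all()

    def test_motile_steps_have_configured_length(self):
        cfg = SimConfig(
            seed=6, n_cells=10, n_timepoints=8, motile_fraction=1.0,
            motile_step_um=5.0, image_shape=(1, 1500, 1500),
            voxel_size=(1.0, 1.0, 0.5),
        )
        _, gt = simulate_detection_series(cfg)
        for _, sub in gt.positions.groupby("cell_id"):
            xy = sub[["x_um", "y_um"]].to_numpy()
            steps = np.hypot(*np.diff(xy, axis=0).T)
            np.testing.assert_allclose(steps, 5.0, rtol=1e-9)


class TestSurvivalGenerator:
    def test_null_groups_exchangeable(self):
        recs = simulate_survival(3000, 3000, 0.0, 0.004, 1e9, 0.01, seed=1)
        a = [r.time_h for r in recs if r.group == "control"]
        b = [r.time_h for r in recs if r.group == "disease"]
        assert stats.ks_2samp(a, b).pvalue > 0.01

    def test_zero_censor_time_censors_everything(self):
        recs = simulate_survival(10, 10, 0.5, 0.01, 0.0, 24.0, seed=2)
        assert all(r.event == 0 and r.time_h == 0.0 for r in recs)

    def test_event_rate_ratio_matches_log_hr(self):
        recs = simulate_survival(10000, 10000, np.log(2.0), 0.005, 336, 0.01, seed=3)
        df = pd.DataFrame([(r.group, r.time_h, r.event) for r in recs],
                          columns=["group", "time_h", "event"])
        rate = df.groupby("group").apply(
            lambda g: g.event.sum() / g.time_h.sum(), include_groups=False
        )
        assert rate["disease"] / rate["control"] == pytest.approx(2.0, rel=0.05)

    def test_times_on_frame_grid(self):
        recs = simulate_survival(200, 200, 0.3, 0.004, 336, 24.0, seed=4)
        events = [r.time_h for r in recs if r.event == 1]
        assert all(t % 24.0 == 0 and t > 0 for t in events)


class TestTraces:
    def test_noiseless_traces_exactly_linear(self):
        traces = simulate_traces(3, 0.7, 96, 24, noise_sd=0.0, seed=0)
        for _, sub in traces[~traces.is_background].groupby("trace_id"):
            slopes = np.diff(sub.intensity) / np.diff(sub.timepoint_h)
            np.testing.assert_allclose(slopes, 0.7)

    def test_background_traces_flat(self):
        traces = simulate_traces(3, 0.7, 96, 24, noise_sd=0.0, seed=0)
        bg = traces[traces.is_background]
        assert bg.groupby("trace_id").intensity.std().max() == 0.0

    def test_indivisible_duration_rejected(self):
        with pytest.raises(ValueError):
            simulate_traces(3, 0.7, 100, 24, noise_sd=0.0, seed=0)
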