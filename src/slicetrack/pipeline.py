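"""End-to-end orchestration: movie -> projections -> alignment ->
segmentation -> tracking -> quantification -> puncta -> survival.

A run is driven by a :class:`PipelineConfig` (YAML-loadable) naming
either an input OME-TIFF or a simulator configuration, plus per-stage
configs.  Outputs are plain CSV/JSON files in the output directory with
the seed and configuration echoed for provenance; the same config and
seed reproduce identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import imgio, puncta, quantify, segment, survival, track
from .simulate import CHANNELS, SimConfig, simulate_movie

log = logging.getLogger("slicetrack")


@dataclass
class PipelineConfig:
    """Full-run configuration.

    Exactly one of ``input_path`` (an OME-TIFF series) or ``simulate``
    (a :class:`SimConfig`) must be given.  ``seed`` overrides the
    simulator seed and is recorded in every output.
    """

    input_path: str | None = None
    simulate: SimConfig | None = None
    out_dir: str = "slicetrack_out"
    seed: int = 0
    log_level: str = "INFO"
    well: str = "well0"
    segment: segment.SegmentConfig = field(default_factory=segment.SegmentConfig)
    tracker: track.TrackerConfig = field(default_factory=track.TrackerConfig)
    motility: quantify.MotilityConfig = field(default_factory=quantify.MotilityConfig)
    puncta: puncta.PunctaConfig = field(default_factory=puncta.PunctaConfig)
    death: survival.DeathCallConfig = field(default_factory=survival.DeathCallConfig)
    manual_annotations: str | None = None

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise ValueError("exactly one of input_path / simulate must be set")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kw = dict(raw)
        for key, sub in (
            ("simulate", SimConfig),
            ("segment", segment.SegmentConfig),
            ("tracker", track.TrackerConfig),
            ("motility", quantify.MotilityConfig),
            ("puncta", puncta.PunctaConfig),
            ("death", survival.DeathCallConfig),
        ):
            if key in kw and isinstance(kw[key], dict):
                d = kw[key]
                for f in ("image_shape", "voxel_size", "threshold_range"):
                    if f in d and isinstance(d[f], list):
                        d[f] = tuple(d[f])
                kw[key] = sub(**d)
        return cls(**kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _background_stats(proj: imgio.Projection, cfg: segment.SegmentConfig):
    """Mean and SD of off-cell pixels, for death calling."""
    labels, mask = segment.label_mask(proj, cfg)
    bg = np.asarray(proj.pixels, dtype=float)[~mask]
    if bg.size == 0:
        return float("nan"), float("nan")
    return float(bg.mean()), float(bg.std())


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the output bundle.

    Returns a dict with the in-memory results (tracks, tables, report).
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- imgio ------------------------------------------------------------
    ground_truth = None
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        log.info("simulating movie (seed=%d)", config.seed)
        series, ground_truth = simulate_movie(sim)
    else:
        log.info("reading %s", config.input_path)
        series = imgio.read_series(config.input_path)

    n_t = series.n_timepoints
    morph_ch = 0
    rep_ch = 1 if series.n_channels > 1 else 0
    morph = [imgio.max_project(series, t, morph_ch) for t in range(n_t)]
    rep = [imgio.max_project(series, t, rep_ch) for t in range(n_t)]
    morph, shifts = imgio.align_series(morph)
    shifts.to_csv(out / "shifts.csv", index=False)

    # --- segment ----------------------------------------------------------
    frames = []
    for t in range(n_t):
        dets = segment.segment_cells(
            morph[t],
            config.segment,
            extra_channels={series.channel_names[rep_ch]: np.asarray(rep[t].pixels)},
            well=config.well,
        )
        frames.append(dets)
    log.info("segmented %d detections", sum(len(f) for f in frames))

    # --- track ------------------------------------------------------------
    tracks = track.build_tracks(frames, config.tracker)
    track_table = track.tracks_to_table(tracks)
    track_table.to_csv(out / "tracks.csv", index=False)
    counts = track.count_tracked(tracks)
    counts.to_csv(out / "counts.csv", index=False)
    log.info("built %d tracks", len(tracks))

    # --- quantify ---------------------------------------------------------
    features = quantify.feature_table(tracks) if tracks else pd.DataFrame()
    features.to_csv(out / "features.csv", index=False)
    report: dict = {"seed": config.seed, "n_tracks": len(tracks)}
    try:
        rate = quantify.cell_count_rate(counts)
        report["cell_count_rate_per_day"] = rate.slope
    except ValueError as e:
        log.info("cell-count rate skipped: %s", e)
    try:
        md = quantify.mean_distance_trend(tracks)
        report["mean_distance_slope_nm_per_day"] = md.slope
    except ValueError as e:
        log.info("mean-distance trend skipped: %s", e)

    # --- puncta -----------------------------------------------------------
    morph_name = series.channel_names[morph_ch]
    all_puncta = []
    rep_lo = min(float(np.min(r.pixels)) for r in rep)
    rep_hi = max(float(np.max(r.pixels)) for r in rep)
    for t in range(n_t):
        t_h = morph[t].timepoint_h
        label_to_cell = {}
        for tr in tracks:
            det = tr.detections.get(t_h)
            if det is not None:
                label_to_cell[det.label] = tr.cell_id
        mask, label_map = puncta.neuron_mask(
            morph[t], config.segment, detections=frames[t], cell_ids=label_to_cell
        )
        all_puncta.extend(
            puncta.detect_puncta(
                rep[t], mask, config.puncta, label_map=label_map,
                slice_id=config.well, rescale_range=(rep_lo, rep_hi),
            )
        )
    ptable = puncta.puncta_table(all_puncta)
    ptable = puncta.assign_puncta_ids(ptable, config.puncta) if len(ptable) else ptable
    ptable.to_csv(out / "puncta.csv", index=False)
    report["n_puncta_detections"] = len(ptable)

    # --- survival ---------------------------------------------------------
    bg_mean, bg_sd = _background_stats(morph[0], config.segment)
    movie_end_h = series.timepoint_hours(n_t - 1)
    records = []
    for tr in tracks:
        if len(tr) == 0:
            continue
        records.append(
            survival.call_death(
                tr, bg_mean, bg_sd, movie_end_h, config.death,
                time_origin_h=series.t0_h,
                group=config.well,
            )
        )
    if config.manual_annotations:
        ann = pd.read_csv(config.manual_annotations)
        records = survival.apply_manual_annotations(records, ann)
    rec_df = survival.records_to_frame(records)
    rec_df.to_csv(out / "survival_records.csv", index=False)
    report["n_events"] = int(rec_df["event"].sum()) if len(rec_df) else 0
    report["n_censored"] = int((1 - rec_df["event"]).sum()) if len(rec_df) else 0

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)
    log.info("wrote outputs to %s", out)
    return {
        "series": series,
        "ground_truth": ground_truth,
        "tracks": tracks,
        "track_table": track_table,
        "counts": counts,
        "features": features,
        "puncta": ptable,
        "records": records,
        "report": report,
    }
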