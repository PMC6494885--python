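"""Proximity-based longitudinal cell tracking.

Objects at the first timepoint receive unique IDs.  At every subsequent
timepoint each object is matched to the closest object of the previous
frame (Euclidean distance between 2-D max-projection centroids, with the
closest-distance search initialised to the longest image dimension);
if the closest distance is within a hard cutoff the previous ID is
inherited, otherwise a fresh ID is issued.  The cutoff defaults to
64.5 µm — further than a cell travels between 24-h sessions.  There is
no gap closing, motion model or lineage linking: a cell that jumps the
cutoff, reappears, or divides simply spawns a new ID.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segment import Detection

#: Sentinel assignment for detections that start a new track.
NEW = -1


@dataclass
class TrackerConfig:
    """Tracking parameters.

    d_max_um
        Hard distance cutoff: a next-frame object farther than this from
        every previous-frame object gets a fresh ID.  The boundary is
        inclusive (a displacement of exactly ``d_max_um`` still links).
    one_to_one
        With this on (default), two next-frame objects may not inherit
        the same previous ID: competing claims are resolved in ascending
        distance order and losers get fresh IDs.  Off reproduces the
        plain per-object closest-predecessor rule, which oracle tests
        compare against an exhaustive all-pairs search.
    initial_closest_distance_um
        Starting value for the closest-distance search; defaults to the
        longest image dimension when built from a projection, and to
        infinity otherwise.  Any value larger than the true minimum
        distance yields the same assignment.
    """

    d_max_um: float = 64.5
    one_to_one: bool = True
    initial_closest_distance_um: float = np.inf

    def __post_init__(self) -> None:
        if self.d_max_um <= 0:
            raise ValueError("d_max_um must be positive")


@dataclass
class Track:
    """One cell identity over time: an ordered map timepoint -> Detection."""

    cell_id: int
    detections: dict[float, Detection] = field(default_factory=dict)

    def add(self, det: Detection) -> None:
        if det.timepoint_h in self.detections:
            raise ValueError(
                f"track {self.cell_id} already has a detection at {det.timepoint_h} h"
            )
        self.detections[det.timepoint_h] = det

    @property
    def timepoints(self) -> list[float]:
        return sorted(self.detections)

    @property
    def first_seen_h(self) -> float:
        return min(self.detections)

    @property
    def last_seen_h(self) -> float:
        return max(self.detections)

    def __len__(self) -> int:
        return len(self.detections)

    def centroids_um(self) -> np.ndarray:
        """(n, 2) array of (x, y) centroids in timepoint order."""
        return np.array(
            [self.detections[t].centroid_um for t in self.timepoints], dtype=float
        )

    def intensity_trace(self, channel: str) -> pd.DataFrame:
        rows = [
            {
                "timepoint_h": t,
                "intensity": self.detections[t].mean_intensity[channel],
            }
            for t in self.timepoints
        ]
        return pd.DataFrame(rows)


def link_frames(
    prev: list[Detection],
    next: list[Detection],
    config: TrackerConfig | None = None,
) -> list[int]:
    """Assign each next-frame detection to a previous-frame index or NEW.

    Returns a list parallel to ``next``: the index into ``prev`` whose
    ID the detection inherits, or :data:`NEW` (-1).  For each
    next-detection the closest prev-detection is found by scanning with
    a closest-distance variable initialised to
    ``initial_closest_distance_um`` and updated whenever a closer object
    is found; the ID is inherited only when that closest distance is
    within ``d_max_um``.  Exact ties go to the lowest previous-frame
    label, which keeps assignments independent of input order.
    """
    if config is None:
        config = TrackerConfig()
    if not prev:
        return [NEW] * len(next)

    order = sorted(range(len(prev)), key=lambda i: prev[i].label)
    claims: list[tuple[float, int, int]] = []  # (distance, next_idx, prev_idx)
    for j, det in enumerate(next):
        closest = config.initial_closest_distance_um
        best = None
        for i in order:
            d = det.distance_to(prev[i])
            if d < closest:
                closest = d
                best = i
        if best is not None and closest <= config.d_max_um:
            claims.append((closest, j, best))

    assignment = [NEW] * len(next)
    if config.one_to_one:
        taken: set[int] = set()
        for d, j, i in sorted(
            claims, key=lambda c: (c[0], prev[c[2]].label, next[c[1]].label)
        ):
            if i not in taken:
                assignment[j] = i
                taken.add(i)
    else:
        for _, j, i in claims:
            assignment[j] = i
    return assignment


def build_tracks(
    detections_by_timepoint: dict[float, list[Detection]]
    | list[list[Detection]],
    config: TrackerConfig | None = None,
) -> list[Track]:
    """Chain :func:`link_frames` over a sorted timepoint sequence.

    Accepts either a mapping timepoint -> detections or a plain list of
    per-timepoint detection lists (timepoints then taken from the
    detections).  A track closes when no next-frame detection claims its
    ID; reappearing objects start new tracks.
    """
    if config is None:
        config = TrackerConfig()
    if isinstance(detections_by_timepoint, dict):
        times = sorted(detections_by_timepoint)
        frames = [detections_by_timepoint[t] for t in times]
    else:
        frames = list(detections_by_timepoint)
        times = []
        for f in frames:
            ts = {d.timepoint_h for d in f}
            if len(ts) > 1:
                raise ValueError(f"mixed timepoints within one frame: {sorted(ts)}")
            times.append(ts.pop() if ts else (times[-1] + 1 if times else 0.0))
    if len(set(times)) != len(times):
        raise ValueError(f"duplicate timepoints: {times}")

    tracks: list[Track] = []
    next_id = 0
    prev_frame: list[Detection] = []
    prev_track_of: list[Track] = []
    for frame in frames:
        assignment = link_frames(prev_frame, frame, config)
        cur_track_of: list[Track] = []
        for det, a in zip(frame, assignment):
            if a == NEW:
                tr = Track(cell_id=next_id)
                next_id += 1
                tracks.append(tr)
            else:
                tr = prev_track_of[a]
            tr.add(det)
            cur_track_of.append(tr)
        prev_frame = frame
        prev_track_of = cur_track_of
    return tracks


def count_tracked(tracks: list[Track]) -> pd.DataFrame:
    """Per-timepoint active-track count and cumulative distinct-ID count.

    A track is active at a timepoint when it has a detection there; the
    cumulative count is the number of distinct IDs first seen at or
    before the timepoint.  This is the series whose regression slope
    estimates the rate at which newly labelled cells appear.
    """
    times = sorted({t for tr in tracks for t in tr.timepoints})
    rows = []
    for t in times:
        active = sum(1 for tr in tracks if t in tr.detections)
        cumulative = sum(1 for tr in tracks if tr.first_seen_h <= t)
        rows.append(
            {"timepoint_h": t, "n_active": active, "n_cumulative": cumulative}
        )
    return pd.DataFrame(rows)


def tracks_to_table(tracks: list[Track]) -> pd.DataFrame:
    """Long-format track table (one row per detection) for CSV export."""
    rows = []
    for tr in tracks:
        for t in tr.timepoints:
            det = tr.detections[t]
            row = {
                "cell_id": tr.cell_id,
                "timepoint_h": t,
                "x_um": det.x_um,
                "y_um": det.y_um,
                "area_um2": det.area_um2,
                "well": det.well,
            }
            for ch, v in det.mean_intensity.items():
                row[f"intensity_{ch}"] = v
            rows.append(row)
    return pd.DataFrame(rows)
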