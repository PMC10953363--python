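"""Centroid linking and motility statistics for time-lapse objects.

Frame-to-frame linking solves a linear assignment problem in the Jaqaman
style: the cost of linking two detections is their squared centroid
distance, links beyond ``max_link_distance`` are forbidden, and every
detection may instead start or end a track at the alternative cost
``max_link_distance**2``.  Cells and clusters are linked in separate
pools (cross-class links forbidden).  Tracks observed for fewer than
``min_length`` frames are discarded before any statistics are computed.

Motility statistics follow the start-to-end convention used for
macrophage imaging fields: per-track mean speed (mean step displacement
per frame interval), total path length, and Euclidean start-to-end
distance; per-field values are arithmetic means over retained tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .segmentation import CELL, CLUSTER

__all__ = [
    "Track",
    "TrackSet",
    "MotilitySummary",
    "link_tracks",
    "track_metrics",
    "field_summary",
    "evaluate_against_truth",
]

_FORBIDDEN = 1e12


@dataclass
class Track:
    track_id: int
    cls: str
    frames: np.ndarray  # strictly increasing frame indices
    xy: np.ndarray  # (n, 2) centroid coordinates, px

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        if len(self.frames) != len(self.xy):
            raise ValueError("frames and coordinates differ in length")
        if len(self.frames) > 1 and not (np.diff(self.frames) > 0).all():
            raise ValueError("track frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class TrackSet:
    tracks: list = field(default_factory=list)
    frame_interval: float = 20.0  # minutes
    min_length: int = 5
    max_link_distance: float = 50.0

    def __len__(self) -> int:
        return len(self.tracks)

    def by_class(self, cls: str) -> list:
        return [t for t in self.tracks if t.cls == cls]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.tracks:
            for f, (x, y) in zip(t.frames, t.xy):
                rows.append(
                    {"track_id": t.track_id, "class": t.cls, "frame": int(f), "x": x, "y": y}
                )
        return pd.DataFrame(rows, columns=["track_id", "class", "frame", "x", "y"])


@dataclass
class MotilitySummary:
    per_track: pd.DataFrame
    per_field: pd.DataFrame


def _pair_cost_matrix(prev_xy: np.ndarray, curr_xy: np.ndarray, max_dist: float):
    """Augmented LAP cost matrix: links, deaths, births, and a slack block."""
    n, m = len(prev_xy), len(curr_xy)
    d2 = cdist(prev_xy, curr_xy, metric="sqeuclidean")
    link = np.where(d2 <= max_dist**2, d2, _FORBIDDEN)
    b = max_dist**2  # alternative (birth/death) cost
    top_right = np.full((n, n), _FORBIDDEN)
    np.fill_diagonal(top_right, b)
    bottom_left = np.full((m, m), _FORBIDDEN)
    np.fill_diagonal(bottom_left, b)
    bottom_right = np.where(link.T < _FORBIDDEN, 0.0, 0.0)
    return np.block([[link, top_right], [bottom_left, bottom_right]]), d2


def _link_pair(prev_xy: np.ndarray, curr_xy: np.ndarray, max_dist: float) -> list:
    """Optimal one-to-one links (prev_idx, curr_idx) between two frames."""
    n, m = len(prev_xy), len(curr_xy)
    if n == 0 or m == 0:
        return []
    cost, d2 = _pair_cost_matrix(prev_xy, curr_xy, max_dist)
    rows, cols = linear_sum_assignment(cost)
    links = []
    for r, c in zip(rows, cols):
        if r < n and c < m and d2[r, c] <= max_dist**2:
            links.append((int(r), int(c)))
    return links


def _link_pool(
    detections: pd.DataFrame,
    cls: str,
    max_link_distance: float,
    gap_closing: bool,
    start_id: int,
) -> tuple[list, int]:
    """Link one class pool across frames; returns (tracks, next track id)."""
    pool = detections[detections["class"] == cls].sort_values(["frame", "label"])
    if pool.empty:
        return [], start_id
    frames = sorted(pool["frame"].unique())
    # active: list of dicts with frames/xy lists and last-seen frame
    active: list[dict] = []
    finished: list[dict] = []
    next_id = start_id
    for f in frames:
        det = pool[pool["frame"] == f]
        xy = det[["x", "y"]].to_numpy(dtype=float)
        max_gap = 2 if gap_closing else 1
        candidates = [a for a in active if f - a["frames"][-1] <= max_gap]
        expired = [a for a in active if f - a["frames"][-1] > max_gap]
        finished.extend(expired)
        matched_curr: set[int] = set()
        if candidates:
            prev_xy = np.array([a["xy"][-1] for a in candidates])
            for r, c in _link_pair(prev_xy, xy, max_link_distance):
                candidates[r]["frames"].append(int(f))
                candidates[r]["xy"].append(tuple(xy[c]))
                matched_curr.add(c)
        for c in range(len(xy)):
            if c not in matched_curr:
                candidates.append({"frames": [int(f)], "xy": [tuple(xy[c])]})
        active = candidates
    finished.extend(active)
    finished.sort(key=lambda a: (a["frames"][0], a["xy"][0]))
    tracks = []
    for a in finished:
        tracks.append(
            Track(track_id=next_id, cls=cls, frames=np.array(a["frames"]), xy=np.array(a["xy"]))
        )
        next_id += 1
    return tracks, next_id


def link_tracks(
    detections: pd.DataFrame,
    max_link_distance: float = 50.0,
    min_length: int = 5,
    frame_interval: float = 20.0,
    gap_closing: bool = False,
) -> TrackSet:
    """Link per-frame detections into tracks; drop tracks below ``min_length``.

    ``detections`` needs columns frame, x, y, class (the segmentation
    object table).  Cells and clusters are linked independently.
    """
    required = {"frame", "x", "y", "class"}
    if detections.empty:
        return TrackSet(
            tracks=[],
            frame_interval=frame_interval,
            min_length=min_length,
            max_link_distance=max_link_distance,
        )
    missing = required - set(detections.columns)
    if missing:
        raise ValueError(f"detection table missing columns: {sorted(missing)}")
    det = detections.copy()
    if "label" not in det.columns:
        det["label"] = np.arange(len(det))
    tracks: list = []
    next_id = 0
    for cls in (CELL, CLUSTER):
        cls_tracks, next_id = _link_pool(
            det, cls, max_link_distance, gap_closing, next_id
        )
        tracks.extend(cls_tracks)
    tracks = [t for t in tracks if len(t) >= min_length]
    for new_id, t in enumerate(tracks):
        t.track_id = new_id
    return TrackSet(
        tracks=tracks,
        frame_interval=frame_interval,
        min_length=min_length,
        max_link_distance=max_link_distance,
    )


def track_metrics(track: Track, frame_interval: float = 20.0) -> dict:
    """Per-track motion statistics.

    mean_speed is the mean consecutive-step displacement in px per frame
    interval (divide by ``frame_interval`` for px/min); euclidean_distance
    is start-to-end; path_length the summed steps.
    """
    if len(track) < 2:
        raise ValueError("track metrics require at least 2 detections")
    steps = np.linalg.norm(np.diff(track.xy, axis=0), axis=1)
    return {
        "track_id": track.track_id,
        "class": track.cls,
        "mean_speed": float(steps.mean()),
        "speed_px_per_min": float(steps.mean() / frame_interval),
        "euclidean_distance": float(np.linalg.norm(track.xy[-1] - track.xy[0])),
        "path_length": float(steps.sum()),
        "n_frames": len(track),
    }


def field_summary(
    trackset: TrackSet,
    field_assignments: dict | None = None,
    include_clusters: bool = False,
) -> MotilitySummary:
    """Per-field arithmetic means of per-track speed and Euclidean distance.

    ``field_assignments`` maps track_id -> field id (default: one field,
    0).  Cluster tracks are excluded from field means unless requested.
    Fields with no retained tracks appear with missing (NaN) means.
    """
    records = [track_metrics(t, trackset.frame_interval) for t in trackset.tracks]
    per_track = pd.DataFrame(
        records,
        columns=[
            "track_id",
            "class",
            "mean_speed",
            "speed_px_per_min",
            "euclidean_distance",
            "path_length",
            "n_frames",
        ],
    )
    if field_assignments is None:
        field_assignments = {t.track_id: 0 for t in trackset.tracks}
    per_track["field"] = per_track["track_id"].map(field_assignments)
    pool = per_track if include_clusters else per_track[per_track["class"] == CELL]
    all_fields = sorted(set(field_assignments.values())) if field_assignments else []
    grouped = pool.groupby("field").agg(
        mean_speed=("mean_speed", "mean"),
        mean_euclidean_distance=("euclidean_distance", "mean"),
        n_tracks=("track_id", "size"),
    )
    per_field = grouped.reindex(all_fields)
    per_field["n_tracks"] = per_field["n_tracks"].fillna(0).astype(int)
    per_field = per_field.reset_index(names="field")
    return MotilitySummary(per_track=per_track, per_field=per_field)


def evaluate_against_truth(trackset: TrackSet, truth, match_radius: float) -> dict:
    """Score recovered tracks against ground-truth trajectories.

    Each recovered detection is matched greedily to the nearest true cell
    position in the same frame, within ``match_radius``.  Purity is the fraction of matched detections belonging to each
    track's majority true cell, averaged over links; recall the fraction
    of true positions matched; speed_bias the relative error of the mean
    recovered speed against the planted per-cell mean speed.
    """
    truth_df = truth.to_frame() if hasattr(truth, "to_frame") else pd.DataFrame(truth)
    if truth_df.empty:
        raise ValueError("no ground truth provided")
    truth_by_frame = {f: g for f, g in truth_df.groupby("frame")}
    matched_true = 0
    majority_links = 0
    total_links = 0
    for t in trackset.tracks:
        assigned = []
        for f, (x, y) in zip(t.frames, t.xy):
            g = truth_by_frame.get(int(f))
            if g is None:
                continue
            d = np.hypot(g["x"].to_numpy() - x, g["y"].to_numpy() - y)
            j = int(np.argmin(d))
            if d[j] <= match_radius:
                assigned.append(int(g["cell_id"].to_numpy()[j]))
        if assigned:
            counts = pd.Series(assigned).value_counts()
            majority_links += int(counts.iloc[0])
            total_links += len(assigned)
            matched_true += len(assigned)
    purity = majority_links / total_links if total_links else float("nan")
    recall = matched_true / len(truth_df) if len(truth_df) else float("nan")
    rec_speeds = [
        track_metrics(t, trackset.frame_interval)["mean_speed"]
        for t in trackset.tracks
        if len(t) >= 2
    ]
    true_speeds = (
        truth_df.sort_values(["cell_id", "frame"])
        .groupby("cell_id")[["x", "y"]]
        .apply(lambda g: float(np.linalg.norm(np.diff(g.to_numpy(), axis=0), axis=1).mean()))
    )
    planted = float(true_speeds.mean()) if len(true_speeds) else float("nan")
    recovered = float(np.mean(rec_speeds)) if rec_speeds else float("nan")
    bias = (recovered - planted) / planted if planted and planted > 0 else float("nan")
    return {
        "purity": purity,
        "recall": recall,
        "speed_bias": bias,
        "recovered_mean_speed": recovered,
        "planted_mean_speed": planted,
        "n_tracks": len(trackset),
    }
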