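"""SORT-style multi-object tracking over per-frame pose detections.

Tracking-by-detection re-associates per-frame cow poses into per-animal
tracks so features can be aggregated over time for each individual.  Each
track runs a constant-velocity Kalman filter over the bounding box
``(centre_x, centre_y, area, aspect)`` of the visible key-points; frame-to-
frame association minimises ``1 - IoU`` cost with the Hungarian algorithm,
rejecting pairs below an IoU gate.  Tracks are confirmed after a minimum
number of hits and retired after a run of misses.

The walkway constrains cows to single file (they cannot pass each other),
which is why plain geometric SORT — no appearance model — suffices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .pose import BBox, CowPose, FrameSet, TrackedCow, bbox_from_pose


@dataclass
class TrackerConfig:
    iou_threshold: float = 0.3
    max_misses: int = 5
    min_hits_to_confirm: int = 3
    process_noise_scale: float = 1.0
    measurement_noise_scale: float = 1.0
    trust_input_ids: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.iou_threshold < 1.0):
            raise ValueError("iou_threshold must be in (0, 1)")


def iou(a: BBox, b: BBox) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def _bbox_to_z(box: BBox) -> np.ndarray:
    w = box.x_max - box.x_min
    h = box.y_max - box.y_min
    return np.array([box.x_min + w / 2, box.y_min + h / 2, w * h, w / h])


def _x_to_bbox(x: np.ndarray) -> BBox:
    s = max(float(x[2]), 1e-6)
    r = max(float(x[3]), 1e-6)
    w = np.sqrt(s * r)
    h = s / w
    return BBox(float(x[0] - w / 2), float(x[1] - h / 2),
                float(x[0] + w / 2), float(x[1] + h / 2))


class TrackState:
    """One track's Kalman state ``(cx, cy, area, aspect, vcx, vcy, varea)``
    plus bookkeeping counters (hits, misses, age)."""

    # constant-velocity model on (cx, cy, area); aspect ratio constant
    _F = np.eye(7)
    _F[0, 4] = _F[1, 5] = _F[2, 6] = 1.0
    _H = np.eye(4, 7)

    def __init__(self, track_id: int, box: BBox, config: TrackerConfig):
        self.track_id = track_id
        self.hits = 1
        self.misses = 0
        self.age = 0
        self._config = config
        self.x = np.zeros(7)
        self.x[:4] = _bbox_to_z(box)
        self.P = np.diag([10.0, 10.0, 10.0, 10.0, 1e4, 1e4, 1e4])
        self.Q = np.diag([1, 1, 1, 1, 0.01, 0.01, 1e-4]) * config.process_noise_scale
        self.R = np.diag([1.0, 1.0, 10.0, 10.0]) * config.measurement_noise_scale

    def predict(self) -> BBox:
        # keep predicted area positive
        if self.x[2] + self.x[6] <= 0:
            self.x[6] = 0.0
        self.x = self._F @ self.x
        self.P = self._F @ self.P @ self._F.T + self.Q
        self.age += 1
        return _x_to_bbox(self.x)

    def update(self, box: BBox) -> None:
        z = _bbox_to_z(box)
        y = z - self._H @ self.x
        S = self._H @ self.P @ self._H.T + self.R
        K = self.P @ self._H.T @ np.linalg.inv(S)
        self.x = self.x + K @ y
        self.P = (np.eye(7) - K @ self._H) @ self.P
        self.hits += 1
        self.misses = 0

    @property
    def confirmed(self) -> bool:
        return self.hits >= self._config.min_hits_to_confirm

    @property
    def bbox(self) -> BBox:
        return _x_to_bbox(self.x)


def step_tracker(
    states: list[TrackState],
    detections: list[CowPose],
    config: TrackerConfig,
    next_id: int = 0,
) -> tuple[list[TrackState], dict[int, int], int]:
    """Advance the tracker one frame.

    Kalman-predicts every live track, associates detections one-to-one by
    Hungarian assignment on ``1 - IoU`` (pairs under the IoU gate rejected),
    updates matched tracks, spawns tentative tracks for unmatched detections
    and retires tracks whose miss run exceeds ``max_misses``.

    Returns ``(live states, {detection index: track_id}, next free id)``.
    """
    predicted = [st.predict() for st in states]
    det_boxes = [bbox_from_pose(d) for d in detections]

    assignment: dict[int, int] = {}
    matched_tracks: set[int] = set()
    if states and det_boxes:
        cost = np.ones((len(det_boxes), len(states)))
        for i, db in enumerate(det_boxes):
            for j, pb in enumerate(predicted):
                cost[i, j] = 1.0 - iou(db, pb)
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if 1.0 - cost[i, j] >= config.iou_threshold:
                states[j].update(det_boxes[i])
                assignment[i] = states[j].track_id
                matched_tracks.add(j)

    for j, st in enumerate(states):
        if j not in matched_tracks:
            st.misses += 1

    for i, db in enumerate(det_boxes):
        if i not in assignment:
            st = TrackState(next_id, db, config)
            states.append(st)
            assignment[i] = next_id
            next_id += 1

    live = [st for st in states if st.misses <= config.max_misses]
    return live, assignment, next_id


@dataclass
class TrackingResult:
    """Confirmed tracks plus the raw per-frame assignment (for diagnostics)."""

    tracks: list[TrackedCow]
    # frame position -> {detection index: track_id}
    assignments: list[dict[int, int]] = field(default_factory=list)


def run_tracker(frame_set: FrameSet, config: TrackerConfig | None = None) -> TrackingResult:
    """Track every frame of a sequence; returns confirmed tracks only.

    Each output :class:`TrackedCow` holds the ordered poses matched to one
    track id; the id is unique within the sequence and never reused.  With
    ``trust_input_ids`` set and ids present in the input, tracking is
    bypassed and the input ids are taken as ground truth.
    """
    config = config or TrackerConfig()

    if config.trust_input_ids and any(
        p.track_id is not None for _, poses in frame_set.frames for p in poses
    ):
        by_id: dict[int, tuple[list[int], list[CowPose]]] = {}
        assignments = []
        for f_idx, poses in frame_set.frames:
            frame_assign = {}
            for d_idx, pose in enumerate(poses):
                if pose.track_id is None:
                    continue
                fi, ps = by_id.setdefault(pose.track_id, ([], []))
                fi.append(f_idx)
                ps.append(pose)
                frame_assign[d_idx] = pose.track_id
            assignments.append(frame_assign)
        tracks = [
            TrackedCow(tid, frame_set.fps, fi, ps, frame_set.sequence_id)
            for tid, (fi, ps) in sorted(by_id.items())
        ]
        return TrackingResult(tracks, assignments)

    states: list[TrackState] = []
    next_id = 0
    collected: dict[int, tuple[list[int], list[CowPose]]] = {}
    hits_by_id: dict[int, int] = {}
    assignments: list[dict[int, int]] = []
    for f_idx, poses in frame_set.frames:
        states, assignment, next_id = step_tracker(states, poses, config, next_id)
        assignments.append(assignment)
        for d_idx, tid in assignment.items():
            fi, ps = collected.setdefault(tid, ([], []))
            fi.append(f_idx)
            pose = poses[d_idx]
            pose.track_id = tid
            ps.append(pose)
        for st in states:
            hits_by_id[st.track_id] = st.hits

    tracks = [
        TrackedCow(tid, frame_set.fps, fi, ps, frame_set.sequence_id)
        for tid, (fi, ps) in sorted(collected.items())
        if hits_by_id.get(tid, 0) >= config.min_hits_to_confirm
    ]
    return TrackingResult(tracks, assignments)


def match_tracks_to_cows(result: TrackingResult, truth_assignment: list[list[int]],
                         cow_index_to_id: dict[int, str]) -> dict[str, TrackedCow]:
    """Assign each recovered track to its majority ground-truth cow id.

    When several tracks claim the same cow, the one covering more frames
    wins (fragments are dropped).  Used to join tracker output to score
    records on simulated data.
    """
    votes: dict[int, list[int]] = {}
    for frame_assign, truth_row in zip(result.assignments, truth_assignment):
        for d_idx, tid in frame_assign.items():
            votes.setdefault(tid, []).append(truth_row[d_idx])
    best: dict[str, TrackedCow] = {}
    for track in result.tracks:
        cows = votes.get(track.track_id)
        if not cows:
            continue
        cow_idx = int(np.bincount(cows).argmax())
        cow_id = cow_index_to_id[cow_idx]
        if cow_id not in best or track.n_frames > best[cow_id].n_frames:
            best[cow_id] = track
    return best


def tracking_metrics(result: TrackingResult, truth_assignment: list[list[int]]
                     ) -> dict[str, float]:
    """Identity switches and track purity against a ground-truth assignment.

    ``truth_assignment[frame_pos][detection_idx]`` gives the true cow index.
    Purity of a track is the fraction of its detections belonging to its
    majority cow; switches count frames where the track following a given
    cow changes.
    """
    # per ground-truth cow: time-ordered list of the track id that claimed it
    per_cow: dict[int, list[int]] = {}
    per_track: dict[int, list[int]] = {}
    for frame_assign, truth_row in zip(result.assignments, truth_assignment):
        for d_idx, tid in frame_assign.items():
            cow = truth_row[d_idx]
            per_cow.setdefault(cow, []).append(tid)
            per_track.setdefault(tid, []).append(cow)
    switches = sum(
        sum(1 for a, b in zip(tids, tids[1:]) if a != b)
        for tids in per_cow.values()
    )
    purities = []
    for cows in per_track.values():
        counts = np.bincount(cows)
        purities.append(counts.max() / len(cows))
    return {
        "identity_switches": float(switches),
        "min_purity": float(min(purities)) if purities else 1.0,
        "mean_purity": float(np.mean(purities)) if purities else 1.0,
        "n_tracks": float(len(per_track)),
    }
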