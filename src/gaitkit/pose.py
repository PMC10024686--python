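"""Domain types and I/O for cattle pose key-point sequences and mobility scores.

A cow's pose is 15 named anatomical key-points in image coordinates (origin
top-left, y increases downward).  Five of them — tail setting, hook bone,
back centre, withers and scapula (lower neck) — form the dorsal *topline*
used by every back-posture feature.  Sequences are stored in a small JSON
dialect (one file, many sequences, COCO-style ``[x, y, v]`` triples);
mobility scores travel as a plain CSV with one row per cow and up to three
rater columns.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: Canonical key-point order; stable across every reader/writer path.
KEYPOINT_NAMES: tuple[str, ...] = (
    "nose",
    "head",
    "scapula",
    "withers",
    "back_centre",
    "hook_bone",
    "tail_setting",
    "knee_front_left",
    "knee_front_right",
    "knee_hind_left",
    "knee_hind_right",
    "hoof_front_left",
    "hoof_front_right",
    "hoof_hind_left",
    "hoof_hind_right",
)

#: The five dorsal topline points, ordered rear (tail) to front (scapula).
BACK_KEYPOINTS: tuple[str, ...] = (
    "tail_setting",
    "hook_bone",
    "back_centre",
    "withers",
    "scapula",
)

#: Maximum animals the walkway admits per frame.
DEFAULT_MAX_COWS_PER_FRAME = 3


class Visibility(IntEnum):
    """COCO visibility convention: 0 absent, 1 occluded, 2 visible."""

    ABSENT = 0
    OCCLUDED = 1
    VISIBLE = 2


class PoseValidationError(ValueError):
    """A pose, frame set or score record violates the format contract."""


@dataclass(frozen=True)
class BBox:
    """Axis-aligned pixel bounding box, ``x_min < x_max`` and ``y_min < y_max``."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise PoseValidationError(
                f"degenerate bbox ({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)


@dataclass
class CowPose:
    """One animal's 15 key-points in one frame.

    ``points`` maps key-point name to ``(x, y)`` pixels; a point marked
    :attr:`Visibility.ABSENT` carries no coordinate and is not in ``points``.
    """

    points: dict[str, tuple[float, float]]
    visibility: dict[str, Visibility]
    frame_index: int = 0
    track_id: int | None = None

    def __post_init__(self) -> None:
        if set(self.visibility) != set(KEYPOINT_NAMES):
            missing = set(KEYPOINT_NAMES) - set(self.visibility)
            extra = set(self.visibility) - set(KEYPOINT_NAMES)
            raise PoseValidationError(
                f"pose must carry all 15 key-points (missing={sorted(missing)}, "
                f"unknown={sorted(extra)})"
            )
        for name, vis in self.visibility.items():
            if vis is Visibility.ABSENT:
                if name in self.points:
                    raise PoseValidationError(
                        f"key-point {name!r} marked absent but carries a coordinate"
                    )
            else:
                if name not in self.points:
                    raise PoseValidationError(
                        f"key-point {name!r} marked {vis.name} but has no coordinate"
                    )
                x, y = self.points[name]
                if not (math.isfinite(x) and math.isfinite(y)):
                    raise PoseValidationError(f"non-finite coordinate for {name!r}")
        if self.frame_index < 0:
            raise PoseValidationError("frame_index must be >= 0")

    def is_visible(self, name: str) -> bool:
        return self.visibility[name] is Visibility.VISIBLE

    def visible_points(self) -> dict[str, tuple[float, float]]:
        return {n: p for n, p in self.points.items() if self.is_visible(n)}

    def xy(self, name: str) -> tuple[float, float]:
        return self.points[name]


@dataclass
class FrameSet:
    """One camera pass: time-ordered frames, each with 0..max_cows poses."""

    sequence_id: str
    fps: float
    frames: list[tuple[int, list[CowPose]]] = field(default_factory=list)
    max_cows_per_frame: int = DEFAULT_MAX_COWS_PER_FRAME

    def __post_init__(self) -> None:
        if not self.fps > 0:
            raise PoseValidationError("fps must be positive")
        indices = [idx for idx, _ in self.frames]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise PoseValidationError(
                f"frame indices must be strictly increasing in sequence {self.sequence_id!r}"
            )
        for idx, poses in self.frames:
            if len(poses) > self.max_cows_per_frame:
                raise PoseValidationError(
                    f"frame {idx} of sequence {self.sequence_id!r} has {len(poses)} "
                    f"animals (max {self.max_cows_per_frame})"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class TrackedCow:
    """Time-ordered pose sequence for one track ID."""

    track_id: int
    fps: float
    frame_indices: list[int]
    poses: list[CowPose]
    sequence_id: str = ""

    def __post_init__(self) -> None:
        if len(self.frame_indices) != len(self.poses):
            raise PoseValidationError("frame_indices and poses must align")

    @property
    def n_frames(self) -> int:
        return len(self.poses)


@dataclass
class ScoreRecord:
    """Per-cow mobility scores from one or more raters (AHDB 0-3 scale)."""

    cow_id: str
    rater_scores: tuple[int, ...]
    consolidated: int | None = None

    def __post_init__(self) -> None:
        if not self.rater_scores:
            raise PoseValidationError(f"cow {self.cow_id!r}: at least one rater score required")
        for s in self.rater_scores:
            if s not in (0, 1, 2, 3):
                raise PoseValidationError(f"cow {self.cow_id!r}: score {s} outside 0-3")
        if self.consolidated is not None and self.consolidated not in (0, 1, 2, 3):
            raise PoseValidationError(
                f"cow {self.cow_id!r}: consolidated score {self.consolidated} outside 0-3"
            )


def bbox_from_pose(pose: CowPose) -> BBox:
    """Tight axis-aligned box over the pose's *visible* points.

    Raises :class:`PoseValidationError` if fewer than two points are visible
    (a box cannot be formed from a single point).
    """
    pts = list(pose.visible_points().values())
    if len(pts) < 2:
        raise PoseValidationError(
            f"frame {pose.frame_index}: need >= 2 visible points for a bbox, got {len(pts)}"
        )
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    return BBox(min(xs), min(ys), max(xs), max(ys))


# ---------------------------------------------------------------------------
# Key-point JSON dialect
# ---------------------------------------------------------------------------

def _pose_from_triples(
    triples: Sequence[Sequence[float]], frame_index: int, track_id: int | None,
    where: str,
) -> CowPose:
    if len(triples) != len(KEYPOINT_NAMES):
        raise PoseValidationError(
            f"{where}: keypoints array has {len(triples)} triples, expected 15"
        )
    points: dict[str, tuple[float, float]] = {}
    visibility: dict[str, Visibility] = {}
    for name, triple in zip(KEYPOINT_NAMES, triples):
        if len(triple) != 3:
            raise PoseValidationError(f"{where}: key-point {name!r} is not an [x, y, v] triple")
        x, y, v = triple
        try:
            vis = Visibility(int(v))
        except ValueError:
            raise PoseValidationError(f"{where}: bad visibility flag {v!r} for {name!r}") from None
        visibility[name] = vis
        if vis is not Visibility.ABSENT:
            points[name] = (float(x), float(y))
    return CowPose(points=points, visibility=visibility, frame_index=frame_index,
                   track_id=track_id)


def read_keypoint_sequences(path: str | Path) -> list[FrameSet]:
    """Read a key-point JSON file into validated :class:`FrameSet` objects.

    Malformed JSON raises :class:`PoseValidationError` naming the byte offset;
    schema violations name the sequence, frame and animal.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise PoseValidationError(
            f"{path}: malformed JSON at byte offset {exc.pos}: {exc.msg}"
        ) from exc

    if not isinstance(payload, dict) or "sequences" not in payload:
        raise PoseValidationError(f"{path}: top-level object must contain 'sequences'")

    out: list[FrameSet] = []
    for seq in payload["sequences"]:
        seq_id = seq.get("sequence_id", "")
        names = seq.get("keypoint_names")
        if names is not None and tuple(names) != KEYPOINT_NAMES:
            raise PoseValidationError(
                f"sequence {seq_id!r}: keypoint_names differ from the canonical order"
            )
        frames: list[tuple[int, list[CowPose]]] = []
        for frame in seq.get("frames", []):
            idx = int(frame["frame_index"])
            poses = []
            for ai, animal in enumerate(frame.get("animals", [])):
                tid = animal.get("track_id")
                poses.append(
                    _pose_from_triples(
                        animal["keypoints"], idx,
                        int(tid) if tid is not None else None,
                        where=f"sequence {seq_id!r} frame {idx} animal {ai}",
                    )
                )
            frames.append((idx, poses))
        out.append(
            FrameSet(
                sequence_id=str(seq_id),
                fps=float(seq["fps"]),
                frames=frames,
                max_cows_per_frame=max(
                    DEFAULT_MAX_COWS_PER_FRAME,
                    max((len(p) for _, p in frames), default=0),
                ),
            )
        )
    return out


def write_keypoint_sequences(data: Iterable[FrameSet], path: str | Path) -> None:
    """Write frame sets to the key-point JSON dialect at full decimal precision."""
    sequences = []
    for fs in data:
        frames = []
        for idx, poses in fs.frames:
            animals = []
            for pose in poses:
                triples = []
                for name in KEYPOINT_NAMES:
                    vis = pose.visibility[name]
                    if vis is Visibility.ABSENT:
                        triples.append([0.0, 0.0, 0])
                    else:
                        x, y = pose.points[name]
                        triples.append([x, y, int(vis)])
                animals.append({"track_id": pose.track_id, "keypoints": triples})
            frames.append({"frame_index": idx, "animals": animals})
        sequences.append(
            {
                "sequence_id": fs.sequence_id,
                "fps": fs.fps,
                "keypoint_names": list(KEYPOINT_NAMES),
                "frames": frames,
            }
        )
    Path(path).write_text(json.dumps({"sequences": sequences}), encoding="utf-8")


# ---------------------------------------------------------------------------
# Scores CSV
# ---------------------------------------------------------------------------

_SCORE_COLUMNS = ("scorer_1", "scorer_2", "scorer_3")


def read_scores(path: str | Path) -> list[ScoreRecord]:
    """Read a mobility-score CSV (``cow_id,scorer_1,scorer_2,scorer_3,consolidated``).

    Trailing rater columns and the consolidated column may be empty or missing.
    """
    df = pd.read_csv(path, dtype={"cow_id": str})
    if "cow_id" not in df.columns:
        raise PoseValidationError(f"{path}: missing 'cow_id' column")
    records: list[ScoreRecord] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        row_d = row._asdict()
        raters = []
        for col in _SCORE_COLUMNS:
            val = row_d.get(col)
            if val is None or (isinstance(val, float) and math.isnan(val)):
                continue
            score = int(val)
            if score != float(val) or score not in (0, 1, 2, 3):
                raise PoseValidationError(f"{path} row {row_no}: score {val!r} outside 0-3")
            raters.append(score)
        cons_val = row_d.get("consolidated")
        consolidated: int | None = None
        if cons_val is not None and not (isinstance(cons_val, float) and math.isnan(cons_val)):
            consolidated = int(cons_val)
            if consolidated not in (0, 1, 2, 3):
                raise PoseValidationError(
                    f"{path} row {row_no}: consolidated score {cons_val!r} outside 0-3"
                )
        try:
            records.append(
                ScoreRecord(str(row_d["cow_id"]), tuple(raters), consolidated)
            )
        except PoseValidationError as exc:
            raise PoseValidationError(f"{path} row {row_no}: {exc}") from exc
    return records


def write_scores(records: Iterable[ScoreRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        row: dict[str, object] = {"cow_id": rec.cow_id}
        for i, col in enumerate(_SCORE_COLUMNS):
            row[col] = rec.rater_scores[i] if i < len(rec.rater_scores) else None
        row["consolidated"] = rec.consolidated
        rows.append(row)
    pd.DataFrame(rows, columns=["cow_id", *_SCORE_COLUMNS, "consolidated"]).to_csv(
        path, index=False
    )
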