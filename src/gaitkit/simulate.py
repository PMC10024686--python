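"""Synthetic gait simulator: key-point trajectories with score-dependent posture.

The simulator emulates the scene the analysis pipeline assumes: single-file
cows walking through a fixed side-on camera view, scored 0-3 on the AHDB
mobility scale.  A cow's lameness score modulates five effects, each a
documented free parameter:

* static back arch (parabolic topline peak height),
* stride-locked spine flexing (sinusoidal arch modulation),
* mean head elevation relative to the back line (drops as lameness rises),
* head bob amplitude,
* walking speed (lame cows are slower).

Every coordinate receives i.i.d. Gaussian jitter emulating pose-estimation
noise.  Three simulated raters report the true score independently
perturbed by ±1 with a configurable error probability.  The generator makes
no claim to biomechanical realism — it reproduces the correlational
structure the downstream statistics and classifier exploit, with margins
well above the injected noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .pose import (
    BACK_KEYPOINTS,
    KEYPOINT_NAMES,
    CowPose,
    FrameSet,
    ScoreRecord,
    TrackedCow,
    Visibility,
)

#: Mobility-score class frequencies observed in a 250-cow commercial herd.
HERD_CLASS_PROBS: tuple[float, ...] = (0.252, 0.432, 0.256, 0.060)


@dataclass(frozen=True)
class GaitParams:
    """Tunable simulator parameters; per-score arrays are indexed by score 0-3.

    Vertical amplitudes are pixels; ``baseline_height`` is the image row of
    the tail/neck line (y grows downward, so arching *reduces* y).
    ``head_drop_by_score`` is the mean head elevation above the back line —
    positive means head held high, negative head hung low.
    """

    body_length: float = 400.0
    baseline_height: float = 300.0
    arch_amplitude_by_score: tuple[float, ...] = (0.0, 3.0, 7.0, 12.0)
    flex_amplitude_by_score: tuple[float, ...] = (0.5, 1.5, 3.0, 6.0)
    head_drop_by_score: tuple[float, ...] = (25.0, 10.0, -5.0, -25.0)
    head_bob_amplitude_by_score: tuple[float, ...] = (1.0, 3.0, 7.0, 14.0)
    speed_by_score: tuple[float, ...] = (6.0, 5.0, 4.0, 2.5)
    stride_frequency: float = 1.2
    keypoint_noise_sd: float = 1.0
    fps: float = 30.0
    rater_error_prob: float = 0.15
    rater_bias: tuple[float, ...] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("arch_amplitude_by_score", "flex_amplitude_by_score",
                     "head_bob_amplitude_by_score"):
            if any(v < 0 for v in getattr(self, name)):
                raise ValueError(f"{name} must be non-negative")
        if any(v <= 0 for v in self.speed_by_score):
            raise ValueError("speeds must be positive")
        if not (0 <= self.rater_error_prob <= 1):
            raise ValueError("rater_error_prob must be a probability")

    def scale_effects(self, k: float) -> "GaitParams":
        """Interpolate every score-dependent effect toward its score-0 value.

        ``k = 1`` returns the parameters unchanged; ``k = 0`` removes all
        score information (every score walks like a sound cow), giving the
        chance-level baseline for parameter-recovery checks.
        """

        def interp(vals: tuple[float, ...]) -> tuple[float, ...]:
            base = vals[0]
            return tuple(base + k * (v - base) for v in vals)

        return dataclasses.replace(
            self,
            arch_amplitude_by_score=interp(self.arch_amplitude_by_score),
            flex_amplitude_by_score=interp(self.flex_amplitude_by_score),
            head_drop_by_score=interp(self.head_drop_by_score),
            head_bob_amplitude_by_score=interp(self.head_bob_amplitude_by_score),
            speed_by_score=interp(self.speed_by_score),
        )


@dataclass
class SimulatedSequence:
    """A frame set plus the ground-truth detection-to-cow assignment.

    ``truth_assignment[frame_pos][animal_pos]`` is the cohort-level cow index
    of that detection; per-frame poses deliberately carry no track id, so a
    tracker must recover the association.
    """

    frame_set: FrameSet
    truth_assignment: list[list[int]]
    cow_ids: list[str]


@dataclass
class SimulatedCohort:
    """Cohort of simulated cows with ground truth and simulated rater scores."""

    frame_sets: list[FrameSet]
    sequences: list[SimulatedSequence]
    truth: dict[str, int]
    rater_table: list[ScoreRecord]
    tracks: dict[str, TrackedCow]
    params: GaitParams
    seed: int


# fixed body-plan offsets (fractions of body length ahead of the scapula,
# vertical pixel offsets below the baseline)
_HEAD_AHEAD = 0.20
_NOSE_AHEAD = 0.33
_NOSE_BELOW_HEAD = 14.0
_KNEE_DEPTH = 90.0
_HOOF_DEPTH = 160.0
_LEG_X_FRACTIONS = {  # fraction along the tail->scapula chord
    "knee_hind_left": 0.10, "knee_hind_right": 0.16,
    "knee_front_left": 0.84, "knee_front_right": 0.90,
    "hoof_hind_left": 0.08, "hoof_hind_right": 0.18,
    "hoof_front_left": 0.82, "hoof_front_right": 0.92,
}


def _pose_at(params: GaitParams, score: int, t: int, tail_x: float,
             phase: float, rng: np.random.Generator) -> CowPose:
    """Noiseless body plan at frame ``t`` plus Gaussian key-point jitter."""
    L = params.body_length
    base_y = params.baseline_height
    omega = 2.0 * np.pi * params.stride_frequency / params.fps
    arch = (params.arch_amplitude_by_score[score]
            + params.flex_amplitude_by_score[score] * np.sin(omega * t + phase))
    points: dict[str, tuple[float, float]] = {}
    # topline: parabola through the chord endpoints, peak `arch` at the centre
    for name, u in zip(BACK_KEYPOINTS, (0.0, 0.25, 0.5, 0.75, 1.0)):
        x = tail_x + u * L
        y = base_y - arch * 4.0 * u * (1.0 - u)
        points[name] = (x, y)
    head_y = base_y - (params.head_drop_by_score[score]
                       + params.head_bob_amplitude_by_score[score]
                       * np.sin(omega * t + phase + np.pi / 3))
    points["head"] = (tail_x + (1.0 + _HEAD_AHEAD) * L, head_y)
    points["nose"] = (tail_x + (1.0 + _NOSE_AHEAD) * L, head_y + _NOSE_BELOW_HEAD)
    for name, u in _LEG_X_FRACTIONS.items():
        depth = _KNEE_DEPTH if name.startswith("knee") else _HOOF_DEPTH
        points[name] = (tail_x + u * L, base_y + depth)
    if params.keypoint_noise_sd > 0:
        noise = rng.normal(0.0, params.keypoint_noise_sd, size=(len(KEYPOINT_NAMES), 2))
        points = {
            n: (points[n][0] + noise[i, 0], points[n][1] + noise[i, 1])
            for i, n in enumerate(KEYPOINT_NAMES)
        }
    return CowPose(
        points=points,
        visibility={n: Visibility.VISIBLE for n in KEYPOINT_NAMES},
        frame_index=t,
    )


def simulate_cow_track(params: GaitParams, score: int, seed: int,
                       start_x: float = 0.0, n_frames: int = 60,
                       track_id: int | None = None) -> TrackedCow:
    """Simulate one cow walking toward +x for ``n_frames`` frames.

    Deterministic given ``seed``.  The chord endpoints (tail setting,
    scapula) sit on the baseline; arch height follows
    ``arch_amplitude + flex_amplitude * sin(2*pi*stride_frequency*t)``.
    """
    if score not in (0, 1, 2, 3):
        raise ValueError(f"score must be 0-3, got {score}")
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    speed = params.speed_by_score[score]
    poses = [
        _pose_at(params, score, t, start_x + speed * t, phase, rng)
        for t in range(n_frames)
    ]
    for p in poses:
        p.track_id = track_id
    return TrackedCow(
        track_id=track_id if track_id is not None else 0,
        fps=params.fps,
        frame_indices=list(range(n_frames)),
        poses=poses,
    )


#: minimum clear distance between one cow's nose and the next cow's tail
_MIN_GAP_FRACTION = 0.35


def simulate_sequence(params: GaitParams, scores: list[int], seed: int,
                      n_frames: int = 60, sequence_id: str = "seq",
                      cow_ids: list[str] | None = None) -> SimulatedSequence:
    """Simulate 0-10 single-file cows crossing the view together.

    Cows enter staggered, the fastest in front; a following cow slows to
    hold a minimum gap behind its leader, so bodies never overlap in x by
    more than ~20% of a body length.  Ground truth is retained separately;
    the emitted poses carry no track id.
    """
    if len(scores) > 10:
        raise ValueError(f"at most 10 cows per sequence, got {len(scores)}")
    for s in scores:
        if s not in (0, 1, 2, 3):
            raise ValueError(f"score must be 0-3, got {s}")
    if cow_ids is None:
        cow_ids = [f"cow_{i}" for i in range(len(scores))]
    rng = np.random.default_rng(seed)
    n = len(scores)
    L = params.body_length
    extent = (1.0 + _NOSE_AHEAD) * L          # tail to nose
    min_gap = _MIN_GAP_FRACTION * L

    # front-to-back order: fastest first so gaps only grow; followers still
    # clamp to the leader each frame as a guarantee.
    order = sorted(range(n), key=lambda i: -params.speed_by_score[scores[i]])
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n)
    sub_rngs = [np.random.default_rng(rng.integers(0, 2**31)) for _ in range(n)]

    tail_x = np.zeros(n)
    x0 = 0.0
    for rank, i in enumerate(order):
        tail_x[i] = x0 - rank * (extent + min_gap)

    frames: list[tuple[int, list[CowPose]]] = []
    truth_assignment: list[list[int]] = []
    for t in range(n_frames):
        poses: list[CowPose] = []
        assign: list[int] = []
        leader_tail = np.inf
        for i in order:
            if t > 0:
                proposed = tail_x[i] + params.speed_by_score[scores[i]]
                # follow rule: nose must stay min_gap behind the leader's tail
                tail_x[i] = min(proposed, leader_tail - min_gap - extent)
            leader_tail = tail_x[i]
            poses.append(_pose_at(params, scores[i], t, tail_x[i], phases[i], sub_rngs[i]))
            assign.append(i)
        frames.append((t, poses))
        truth_assignment.append(assign)
    fs = FrameSet(sequence_id=sequence_id, fps=params.fps, frames=frames,
                  max_cows_per_frame=max(n, 3))
    return SimulatedSequence(frame_set=fs, truth_assignment=truth_assignment,
                             cow_ids=list(cow_ids))


def simulate_raters(truth: list[int], params: GaitParams,
                    rng: np.random.Generator) -> list[tuple[int, ...]]:
    """Three independent raters: truth perturbed ±1 with ``rater_error_prob``,
    clamped to 0-3; optional per-rater bias shifts the perturbation odds."""
    out = []
    for score in truth:
        raters = []
        for bias in params.rater_bias:
            s = score
            if rng.random() < params.rater_error_prob:
                if bias > 0:
                    step = 1
                elif bias < 0:
                    step = -1
                else:
                    step = 1 if rng.random() < 0.5 else -1
                s = min(3, max(0, s + step))
            raters.append(s)
        out.append(tuple(raters))
    return out


def simulate_cohort(params: GaitParams, n_cows: int,
                    class_probs: tuple[float, ...] = HERD_CLASS_PROBS,
                    seed: int = 0, n_frames: int = 60,
                    cows_per_sequence: int = 10) -> SimulatedCohort:
    """Simulate a scored cohort: sequences of single-file cows plus raters.

    True scores are drawn i.i.d. from ``class_probs`` (defaults to the
    observed herd distribution); cows are grouped into sequences of up to
    ``cows_per_sequence``.  Ground-truth per-cow tracks are retained so
    downstream stages can be exercised with or without the tracker.
    """
    probs = np.asarray(class_probs, dtype=float)
    if probs.shape != (4,) or abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
        raise ValueError("class_probs must be 4 non-negative numbers summing to 1")
    rng = np.random.default_rng(seed)
    truth_scores = rng.choice(4, size=n_cows, p=probs).tolist()
    cow_ids = [f"cow_{i:03d}" for i in range(n_cows)]
    truth = dict(zip(cow_ids, truth_scores))

    sequences: list[SimulatedSequence] = []
    tracks: dict[str, TrackedCow] = {}
    for s_start in range(0, n_cows, cows_per_sequence):
        idx = list(range(s_start, min(s_start + cows_per_sequence, n_cows)))
        seq_seed = int(rng.integers(0, 2**31))
        seq = simulate_sequence(
            params, [truth_scores[i] for i in idx], seed=seq_seed,
            n_frames=n_frames, sequence_id=f"seq_{s_start // cows_per_sequence:02d}",
            cow_ids=[cow_ids[i] for i in idx],
        )
        # remap local cow positions to cohort indices
        seq.truth_assignment = [[idx[j] for j in row] for row in seq.truth_assignment]
        sequences.append(seq)
        # ground-truth tracks, read straight off the simulated frames
        per_cow: dict[int, list[CowPose]] = {i: [] for i in idx}
        for (f_idx, poses), assign in zip(seq.frame_set.frames, seq.truth_assignment):
            for pose, cow_idx in zip(poses, assign):
                per_cow[cow_idx].append(pose)
        for cow_idx, poses in per_cow.items():
            tracks[cow_ids[cow_idx]] = TrackedCow(
                track_id=cow_idx, fps=params.fps,
                frame_indices=[p.frame_index for p in poses], poses=poses,
                sequence_id=seq.frame_set.sequence_id,
            )

    rater_scores = simulate_raters(truth_scores, params, rng)
    from .aggregate import consolidate_scores

    rater_table = [
        ScoreRecord(cid, rs, consolidate_scores(rs))
        for cid, rs in zip(cow_ids, rater_scores)
    ]
    return SimulatedCohort(
        frame_sets=[s.frame_set for s in sequences],
        sequences=sequences, truth=truth, rater_table=rater_table,
        tracks=tracks, params=params, seed=seed,
    )
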