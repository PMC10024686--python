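"""Per-frame kinematic features from a single cow pose.

Four families of features quantify the posture cues mobility scorers look
for in lame cattle:

* **Back curvature** — ordinary least squares line through the five dorsal
  topline points; the RMSE of the vertical residuals rises as the back
  arches.
* **Back area** — the area enclosed between the topline and the chord
  joining tail setting to scapula, split into three named sections
  (hip-to-centre, shoulder-to-centre, neck-to-shoulder) via trapezoids in
  the baseline coordinate.
* **Head position** — the back regression line extended forward past the
  head; the squared vertical distance of head and nose from that line,
  signed negative when the head hangs below it (head drop is a classic
  lameness sign).
* **Neck angle** — angle between the withers-to-scapula and
  scapula-to-head line segments, from their gradients.

All coordinates are image pixels (y increases downward).  Signed
conventions are stated per function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .pose import BACK_KEYPOINTS, CowPose


class GeometryError(ValueError):
    """Degenerate geometry (vertical segment, zero-length baseline...)."""


@dataclass(frozen=True)
class BackFit:
    """OLS line through the topline and its residual diagnostics.

    ``residuals`` are signed vertical offsets ``y_keypoint - y_line`` in
    tail-to-scapula order; ``rmse = sqrt(mean(residuals**2))``.
    """

    slope: float
    intercept: float
    residuals: tuple[float, ...]
    rmse: float
    n: int

    def y_at(self, x: float) -> float:
        return self.slope * x + self.intercept


@dataclass(frozen=True)
class AreaSections:
    """Back area split into the three named sections (pixels squared)."""

    back_hip_to_centre: float
    front_shoulder_to_centre: float
    neck_to_shoulder: float
    total: float


@dataclass(frozen=True)
class HeadElevation:
    """Signed squared elevation of head and nose relative to the back line.

    Positive above the line (head held high), negative below, zero on it.
    ``combined`` is the mean of the two.
    """

    head_pos: float
    nose_pos: float
    combined: float


@dataclass(frozen=True)
class NeckGeometry:
    """Gradients of back-of-neck and neck segments and the angle between them."""

    m1: float
    m2: float
    angle: float


@dataclass
class FrameFeatures:
    """All per-frame kinematic scalars; a field is None when its key-points
    are not all visible."""

    frame_index: int
    back_rmse: float | None = None
    area_hip_centre: float | None = None
    area_shoulder_centre: float | None = None
    area_neck_shoulder: float | None = None
    area_total: float | None = None
    head_nose_pos: float | None = None
    neck_angle: float | None = None

    FIELDS = (
        "back_rmse",
        "area_hip_centre",
        "area_shoulder_centre",
        "area_neck_shoulder",
        "area_total",
        "head_nose_pos",
        "neck_angle",
    )


def fit_back_line(back_points: np.ndarray) -> BackFit:
    """Least-squares line of best fit through the five topline points.

    Parameters
    ----------
    back_points
        ``(5, 2)`` array of ``(x, y)`` pixels in tail-to-scapula order.

    Ordinary least squares of y on x; residuals are vertical.  A topline
    with no x spread has no function-form line and raises
    :class:`GeometryError`.
    """
    pts = np.asarray(back_points, dtype=float)
    if pts.shape != (5, 2):
        raise GeometryError(f"expected 5 (x, y) points, got shape {pts.shape}")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise GeometryError("all back points share one x: vertical topline cannot be fit")
    slope, intercept = np.polyfit(x, y, 1)
    residuals = y - (slope * x + intercept)
    rmse = float(np.sqrt(np.mean(residuals**2)))
    return BackFit(float(slope), float(intercept), tuple(residuals), rmse, len(pts))


def _signed_heights(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Baseline-coordinate positions and signed perpendicular heights.

    The baseline is the tail-to-scapula chord.  Heights are signed so the
    side on which the back centre lies is positive — an arched back scores
    positive area in image or mathematical orientation alike, and a
    sway-backed (opposite side) segment contributes negatively.  Falls back
    to the largest-magnitude height when the centre sits on the baseline.
    """
    p0, p4 = pts[0], pts[4]
    chord = p4 - p0
    length = float(np.hypot(*chord))
    if length == 0:
        raise GeometryError("zero-length baseline (tail setting equals scapula)")
    unit = chord / length
    rel = pts - p0
    along = rel @ unit
    # perpendicular component via the 2-D cross product
    heights = rel[:, 0] * unit[1] - rel[:, 1] * unit[0]
    ref = heights[2] if heights[2] != 0 else heights[np.argmax(np.abs(heights))]
    if ref < 0:
        heights = -heights
    return along, heights


def back_areas(back_points: np.ndarray) -> AreaSections:
    """Area between the topline and the tail-to-scapula baseline.

    Intermediate points are projected onto the baseline; the area is the
    trapezoid sum of the signed perpendicular heights along the baseline
    coordinate (equivalent to the triangle-and-rectangle decomposition,
    since both end heights are zero).  Sections:

    * ``back_hip_to_centre``   — tail setting → hook bone → back centre
    * ``front_shoulder_to_centre`` — back centre → withers
    * ``neck_to_shoulder``     — withers → scapula
    """
    pts = np.asarray(back_points, dtype=float)
    if pts.shape != (5, 2):
        raise GeometryError(f"expected 5 (x, y) points, got shape {pts.shape}")
    along, h = _signed_heights(pts)
    trap = 0.5 * (h[:-1] + h[1:]) * np.diff(along)
    rear = float(trap[0] + trap[1])
    front = float(trap[2])
    neck = float(trap[3])
    return AreaSections(rear, front, neck, rear + front + neck)


def head_nose_pos(fit: BackFit, head: tuple[float, float],
                  nose: tuple[float, float]) -> HeadElevation:
    """Signed squared elevation of head and nose above the extended back line.

    For each point the regression line is evaluated at the point's x; the
    value is ``(y_line - y_point)**2``, multiplied by -1 when the line lies
    above the point (``y_line < y_point`` in image coordinates, i.e. the
    head hangs below the back line).
    """

    def pos(pt: tuple[float, float]) -> float:
        y_line = fit.y_at(pt[0])
        d = y_line - pt[1]
        return d * d if d >= 0 else -(d * d)

    hp, np_ = pos(head), pos(nose)
    return HeadElevation(hp, np_, (hp + np_) / 2.0)


def neck_angle(withers: tuple[float, float], scapula: tuple[float, float],
               head: tuple[float, float]) -> NeckGeometry:
    """Angle of the neck relative to the back, from segment gradients.

    ``m1`` is the gradient withers → scapula, ``m2`` scapula → head;
    ``angle = atan((m1 - m2) / (1 + m1*m2))`` radians, with the
    perpendicular case ``1 + m1*m2 = 0`` resolved to ±π/2 by the sign of
    ``m1 - m2``.  Vertical segments have no finite gradient and raise
    :class:`GeometryError` naming the offending segment.
    """
    if withers[0] == scapula[0]:
        raise GeometryError("withers-scapula segment is vertical: gradient undefined")
    if scapula[0] == head[0]:
        raise GeometryError("scapula-head segment is vertical: gradient undefined")
    m1 = (scapula[1] - withers[1]) / (scapula[0] - withers[0])
    m2 = (head[1] - scapula[1]) / (head[0] - scapula[0])
    denom = 1.0 + m1 * m2
    if denom == 0.0:
        angle = math.copysign(math.pi / 2, m1 - m2)
    else:
        angle = math.atan((m1 - m2) / denom)
    return NeckGeometry(m1, m2, angle)


def back_points_array(pose: CowPose) -> np.ndarray:
    """The five topline coordinates in tail-to-scapula order."""
    return np.array([pose.xy(n) for n in BACK_KEYPOINTS], dtype=float)


def frame_features(pose: CowPose) -> FrameFeatures:
    """Compute every per-frame feature whose required key-points are visible.

    Missing or occluded key-points leave the corresponding features unset;
    degenerate geometry likewise yields unset features rather than raising.
    """
    ff = FrameFeatures(frame_index=pose.frame_index)
    back_ok = all(pose.is_visible(n) for n in BACK_KEYPOINTS)
    fit: BackFit | None = None
    if back_ok:
        pts = back_points_array(pose)
        try:
            fit = fit_back_line(pts)
            ff.back_rmse = fit.rmse
        except GeometryError:
            fit = None
        try:
            areas = back_areas(pts)
        except GeometryError:
            areas = None
        if areas is not None:
            ff.area_hip_centre = areas.back_hip_to_centre
            ff.area_shoulder_centre = areas.front_shoulder_to_centre
            ff.area_neck_shoulder = areas.neck_to_shoulder
            ff.area_total = areas.total
    if fit is not None and pose.is_visible("head") and pose.is_visible("nose"):
        ff.head_nose_pos = head_nose_pos(fit, pose.xy("head"), pose.xy("nose")).combined
    if all(pose.is_visible(n) for n in ("withers", "scapula", "head")):
        try:
            ff.neck_angle = neck_angle(
                pose.xy("withers"), pose.xy("scapula"), pose.xy("head")
            ).angle
        except GeometryError:
            pass
    return ff
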