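"""Per-cow aggregation of frame features and the statistical screening step.

Each per-frame kinematic series is collapsed to seven summary statistics
(min, max, mean, median, standard deviation, skew, kurtosis), producing a
48-column feature table (the per-frame head/nose elevation median is
excluded from the default table; ``full_stats`` restores it).  Screening is
plain Pearson correlation of each feature against the consolidated mobility
score, with the usual significance bands.  Inter-rater agreement uses the
tie-corrected Kendall coefficient of concordance, and rater scores are
consolidated by arithmetic mean rounded to the nearest whole score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .kinematics import FrameFeatures, frame_features
from .pose import ScoreRecord, TrackedCow

SUMMARY_STATS = ("min", "max", "mean", "median", "std", "skew", "kurtosis")

FEATURE_SERIES = (
    "back_rmse",
    "area_hip_centre",
    "area_shoulder_centre",
    "area_neck_shoulder",
    "area_total",
    "head_nose_pos",
    "neck_angle",
)


def feature_columns(full_stats: bool = False) -> list[str]:
    """The default 48 aggregated column names (49 with ``full_stats``)."""
    cols = []
    for feat in FEATURE_SERIES:
        for stat in SUMMARY_STATS:
            if not full_stats and feat == "head_nose_pos" and stat == "median":
                continue
            cols.append(f"{feat}_{stat}")
    return cols


@dataclass(frozen=True)
class SummaryStats:
    """Seven summary statistics of one per-frame series.

    ``std`` uses one delta degree of freedom; ``skew`` and ``kurtosis`` are
    the biased (population) estimators, kurtosis as excess (Fisher).  A
    constant series has skew and kurtosis defined as 0 rather than NaN so
    downstream tables stay numeric.
    """

    min: float
    max: float
    mean: float
    median: float
    std: float
    skew: float
    kurtosis: float

    def as_dict(self) -> dict[str, float]:
        return {s: getattr(self, s) for s in SUMMARY_STATS}


def summarize(series) -> SummaryStats:
    """Summary statistics of a per-frame feature series (length >= 1)."""
    arr = np.asarray(series, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty series")
    if np.ptp(arr) == 0:
        sk = ku = 0.0
    else:
        sk = float(stats.skew(arr, bias=True))
        ku = float(stats.kurtosis(arr, fisher=True, bias=True))
        # numerically constant series (second moment underflows): treat as constant
        if not math.isfinite(sk):
            sk = 0.0
        if not math.isfinite(ku):
            ku = 0.0
    return SummaryStats(
        min=float(arr.min()),
        max=float(arr.max()),
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        std=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        skew=sk,
        kurtosis=ku,
    )


def consolidate_scores(rater_scores) -> int:
    """Arithmetic mean of the rater scores, rounded half away from zero."""
    scores = list(rater_scores)
    if not scores:
        raise ValueError("at least one rater score required")
    for s in scores:
        if s not in (0, 1, 2, 3):
            raise ValueError(f"score {s} outside 0-3")
    mean = sum(scores) / len(scores)
    return int(math.floor(mean + 0.5))


def cow_feature_row(track: TrackedCow, min_frames: int = 10,
                    full_stats: bool = False) -> dict[str, float] | None:
    """Aggregate one cow's frames to a feature row; None when any series has
    fewer than ``min_frames`` valid frames."""
    per_frame: list[FrameFeatures] = [frame_features(p) for p in track.poses]
    row: dict[str, float] = {}
    for feat in FEATURE_SERIES:
        series = [getattr(ff, feat) for ff in per_frame if getattr(ff, feat) is not None]
        if len(series) < min_frames:
            return None
        summary = summarize(series).as_dict()
        for stat in SUMMARY_STATS:
            if not full_stats and feat == "head_nose_pos" and stat == "median":
                continue
            row[f"{feat}_{stat}"] = summary[stat]
    return row


def build_feature_table(cows: dict[str, TrackedCow], scores: list[ScoreRecord],
                        min_frames: int = 10, full_stats: bool = False) -> pd.DataFrame:
    """One row per cow: aggregated kinematic features plus scores.

    ``cows`` maps cow id to its track.  Every cow must have a score record;
    the consolidated score is taken from the record or computed from the
    rater scores.  Cows with fewer than ``min_frames`` valid frames in any
    series are excluded with a warning.
    """
    by_id = {rec.cow_id: rec for rec in scores}
    missing = sorted(set(cows) - set(by_id))
    if missing:
        raise ValueError(f"cows without score records: {missing}")
    rows = []
    for cow_id, track in cows.items():
        row = cow_feature_row(track, min_frames=min_frames, full_stats=full_stats)
        if row is None:
            warnings.warn(
                f"cow {cow_id!r} excluded: fewer than {min_frames} valid frames",
                stacklevel=2,
            )
            continue
        rec = by_id[cow_id]
        row["cow_id"] = cow_id
        cons = rec.consolidated
        if cons is None:
            cons = consolidate_scores(rec.rater_scores)
        row["consolidated"] = cons
        for i, s in enumerate(rec.rater_scores, start=1):
            row[f"scorer_{i}"] = s
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=[*feature_columns(full_stats), "consolidated"])
    df = pd.DataFrame(rows).set_index("cow_id").sort_index()
    ordered = [c for c in feature_columns(full_stats) if c in df.columns]
    extra = [c for c in df.columns if c not in ordered]
    return df[ordered + extra]


def frame_feature_frame(tracks: dict[str, TrackedCow]) -> pd.DataFrame:
    """Long per-frame feature table: one row per (cow, frame).

    Unset features are NaN, with a boolean ``<feature>_valid`` flag per
    column; this is the on-disk interchange form between the feature and
    aggregation stages.
    """
    rows = []
    for cow_id, track in tracks.items():
        for pose in track.poses:
            ff = frame_features(pose)
            row: dict[str, object] = {
                "cow_id": cow_id,
                "sequence_id": track.sequence_id,
                "track_id": track.track_id,
                "frame_index": pose.frame_index,
            }
            for feat in FEATURE_SERIES:
                val = getattr(ff, feat)
                row[feat] = np.nan if val is None else val
                row[f"{feat}_valid"] = val is not None
            rows.append(row)
    return pd.DataFrame(rows)


def aggregate_frame_table(frame_df: pd.DataFrame, scores: list[ScoreRecord],
                          min_frames: int = 10, full_stats: bool = False
                          ) -> pd.DataFrame:
    """Aggregate a long per-frame feature table to the per-cow feature table.

    Equivalent to :func:`build_feature_table` but consuming the CSV
    interchange form produced by :func:`frame_feature_frame`.
    """
    by_id = {rec.cow_id: rec for rec in scores}
    missing = sorted(set(frame_df["cow_id"].unique()) - set(by_id))
    if missing:
        raise ValueError(f"cows without score records: {missing}")
    rows = []
    for cow_id, group in frame_df.groupby("cow_id"):
        row: dict[str, float] = {}
        ok = True
        for feat in FEATURE_SERIES:
            series = group[feat].dropna().to_numpy()
            if len(series) < min_frames:
                ok = False
                break
            summary = summarize(series).as_dict()
            for stat in SUMMARY_STATS:
                if not full_stats and feat == "head_nose_pos" and stat == "median":
                    continue
                row[f"{feat}_{stat}"] = summary[stat]
        if not ok:
            warnings.warn(
                f"cow {cow_id!r} excluded: fewer than {min_frames} valid frames",
                stacklevel=2,
            )
            continue
        rec = by_id[cow_id]
        row["cow_id"] = cow_id
        cons = rec.consolidated
        if cons is None:
            cons = consolidate_scores(rec.rater_scores)
        row["consolidated"] = cons
        for i, s in enumerate(rec.rater_scores, start=1):
            row[f"scorer_{i}"] = s
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=[*feature_columns(full_stats), "consolidated"])
    df = pd.DataFrame(rows).set_index("cow_id").sort_index()
    ordered = [c for c in feature_columns(full_stats) if c in df.columns]
    extra = [c for c in df.columns if c not in ordered]
    return df[ordered + extra]


# significance bands, smallest threshold met wins
_BANDS = ((0.001, "****"), (0.01, "**"), (0.05, "*"), (0.10, "†"))


def significance_band(p: float) -> str:
    for thresh, band in _BANDS:
        if p < thresh:
            return band
    return ""


def pearson_screen(table: pd.DataFrame, target: str = "consolidated",
                   columns: list[str] | None = None) -> pd.DataFrame:
    """Pearson correlation of each feature column against the mobility score.

    Returns a DataFrame indexed by feature with ``rho``, ``p_value`` and the
    significance ``band``.  A zero-variance feature has undefined rho and is
    reported with NaN.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows for a correlation screen")
    y = table[target].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("target score has zero variance")
    if columns is None:
        columns = [c for c in feature_columns(full_stats=True) if c in table.columns]
    out = []
    for col in columns:
        x = table[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            out.append({"feature": col, "rho": np.nan, "p_value": np.nan, "band": ""})
            continue
        rho, p = stats.pearsonr(x, y)
        out.append({"feature": col, "rho": float(rho), "p_value": float(p),
                    "band": significance_band(float(p))})
    return pd.DataFrame(out).set_index("feature")


def kendalls_w(scores: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Kendall coefficient of concordance.

    Parameters
    ----------
    scores
        ``(m raters, n items)`` matrix of scores; within-rater ties get
        average ranks and the standard tie correction (integer mobility
        scores are heavily tied).

    Returns ``(W, p)`` with the p-value from the chi-square approximation
    ``chi2 = m (n - 1) W`` on ``n - 1`` degrees of freedom.  Raises
    :class:`ValueError` when every rater scores every item identically
    (zero denominator, W undefined).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 2 or scores.shape[1] < 3:
        raise ValueError("need an (m >= 2 raters, n >= 3 items) score matrix")
    m, n = scores.shape
    ranks = np.vstack([stats.rankdata(row) for row in scores])
    rank_sums = ranks.sum(axis=0)
    s = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    tie_term = 0.0
    for row in scores:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float((counts**3 - counts).sum())
    denom = m**2 * (n**3 - n) - m * tie_term
    if denom <= 0:
        raise ValueError("all raters scored all items identically: W undefined")
    w = 12.0 * s / denom
    chi2 = m * (n - 1) * w
    p = float(stats.chi2.sf(chi2, n - 1))
    return w, p
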