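"""Lameness classification and its evaluation protocol.

A gradient-boosted decision-tree classifier is trained on the aggregated
per-cow feature table under four label permutations of the 0-3 mobility
score:

* ``all_classes``    — the four scores as-is;
* ``sound_vs_lame``  — 0 vs {1, 2, 3};
* ``clear_lame``     — {0, 1} vs {2, 3};
* ``severe_lame``    — {0, 1, 2} vs 3.

Evaluation is "threefold" repeated hold-out: three *independent* stratified
80/20 shuffle-splits (not disjoint k-fold partitions), each training with
early stopping on a 20% validation carve-out of the training portion; the
three hold-out accuracies are averaged.  The report carries the pooled
confusion matrix, Cohen's kappa with its large-sample standard error and
95% CI, macro precision/recall, and normalized + cumulative feature
importances.  Recursive feature elimination iteratively drops the
lowest-importance feature, recording the validation-error curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import StratifiedShuffleSplit

from .aggregate import feature_columns

#: score -> label mapping per scheme (total over {0, 1, 2, 3})
LABEL_SCHEMES: dict[str, tuple[int, int, int, int]] = {
    "all_classes": (0, 1, 2, 3),
    "sound_vs_lame": (0, 1, 1, 1),
    "clear_lame": (0, 0, 1, 1),
    "severe_lame": (0, 0, 0, 1),
}


def make_labels(scores, scheme: str) -> np.ndarray:
    """Map mobility scores 0-3 to labels under one of the four schemes."""
    mapping = LABEL_SCHEMES[scheme]
    scores = np.asarray(scores, dtype=int)
    if ((scores < 0) | (scores > 3)).any():
        raise ValueError("scores must be 0-3")
    return np.asarray(mapping)[scores]


@dataclass
class CVConfig:
    n_folds: int = 3
    holdout_fraction: float = 0.20
    seed: int = 0
    early_stopping_patience: int = 20
    stratify: bool = True
    learner_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.holdout_fraction < 1.0):
            raise ValueError("holdout_fraction must be in (0, 1)")


_LEARNER_DEFAULTS = dict(n_estimators=300, learning_rate=0.1, max_depth=3)


def _make_learner(config: CVConfig, random_state: int,
                  y_train: np.ndarray | None = None) -> GradientBoostingClassifier:
    params = {**_LEARNER_DEFAULTS, **config.learner_params}
    # early stopping carves a stratified 20% validation set out of the
    # training portion; skip it when that carve-out cannot hold every class
    early: dict = {"n_iter_no_change": config.early_stopping_patience,
                   "validation_fraction": 0.20}
    if y_train is not None:
        counts = np.unique(y_train, return_counts=True)[1]
        carve = int(np.ceil(0.20 * len(y_train)))
        if carve < max(2, len(counts)) or counts.min() < 2:
            early = {}
    return GradientBoostingClassifier(random_state=random_state, **early, **params)


def cohens_kappa(cm: np.ndarray) -> dict[str, float]:
    """Cohen's kappa from a confusion matrix, with its asymptotic standard
    error (large-sample form under the alternative), 95% CI, and the z test
    of kappa = 0 computed from the null-hypothesis variance.
    """
    cm = np.asarray(cm, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    n = cm.sum()
    if n <= 0:
        raise ValueError("confusion matrix must have positive total")
    p = cm / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = float(np.trace(p))
    pe = float(row @ col)
    if pe >= 1.0:
        # all mass in one row+column: agreement beyond chance is undefined
        nan = float("nan")
        return {"kappa": nan, "ase": nan, "ci_low": nan, "ci_high": nan,
                "z_kappa_zero": nan, "undefined": True}
    kappa = (po - pe) / (1.0 - pe)

    # large-sample variance under the alternative
    diag = np.diag(p)
    term1 = float(np.sum(diag * ((1 - pe) - (row + col) * (1 - po)) ** 2))
    off = p.copy()
    np.fill_diagonal(off, 0.0)
    # off-diagonal cell (i, j) pairs with (p_.i + p_j.)
    term2 = float((1 - po) ** 2 * np.sum(off * np.add.outer(col, row) ** 2))
    term3 = (po * pe - 2 * pe + po) ** 2
    var = (term1 + term2 - term3) / (n * (1 - pe) ** 4)
    ase = float(np.sqrt(max(var, 0.0)))

    # variance under H0: kappa = 0
    var0 = (pe + pe**2 - float(np.sum(row * col * (row + col)))) / (n * (1 - pe) ** 2)
    z = kappa / np.sqrt(var0) if var0 > 0 else np.inf
    return {
        "kappa": float(kappa),
        "ase": ase,
        "ci_low": float(kappa - 1.96 * ase),
        "ci_high": float(kappa + 1.96 * ase),
        "z_kappa_zero": float(z),
        "undefined": False,
    }


def precision_recall(cm: np.ndarray, binary_positive: bool = False
                     ) -> tuple[float, float]:
    """Macro-averaged precision and recall from a confusion matrix
    (rows = true, columns = predicted).

    Classes with no true members or no predictions are excluded from the
    respective macro average with a warning.  With ``binary_positive`` on a
    2x2 matrix, returns the positive-class (index 1) values instead.
    """
    cm = np.asarray(cm, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    row = cm.sum(axis=1)
    col = cm.sum(axis=0)
    diag = np.diag(cm)
    if binary_positive:
        if cm.shape != (2, 2):
            raise ValueError("binary_positive requires a 2x2 matrix")
        return float(diag[1] / col[1]), float(diag[1] / row[1])
    if (row == 0).any() or (col == 0).any():
        warnings.warn("empty class excluded from macro precision/recall", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(col > 0, diag / np.where(col > 0, col, 1), np.nan)
        rec = np.where(row > 0, diag / np.where(row > 0, row, 1), np.nan)
    return float(np.nanmean(prec)), float(np.nanmean(rec))


def feature_importances(model, feature_names: list[str]) -> pd.DataFrame:
    """Normalized and cumulative importances, sorted descending.

    All-zero importances are reported uniform with ``degenerate=True`` in
    ``df.attrs`` (a tree that never split has no importance signal).
    """
    raw = np.asarray(model.feature_importances_, dtype=float)
    total = raw.sum()
    degenerate = bool(total <= 0)
    norm = np.full_like(raw, 1.0 / len(raw)) if degenerate else raw / total
    order = np.argsort(-norm, kind="stable")
    df = pd.DataFrame(
        {
            "feature": [feature_names[i] for i in order],
            "normalized_importance": norm[order],
            "cumulative_importance": np.cumsum(norm[order]),
        }
    ).set_index("feature")
    df.attrs["degenerate"] = degenerate
    return df


@dataclass
class EvalReport:
    """Cross-validated classification report for one label scheme."""

    scheme: str
    fold_accuracies: list[float]
    accuracy_mean: float
    accuracy_std: float
    labels: list[int]
    confusion: np.ndarray
    kappa: dict[str, float]
    precision: float
    recall: float
    importances: pd.DataFrame
    rfe: dict | None = None

    def to_dict(self) -> dict:
        out = {
            "scheme": self.scheme,
            "fold_accuracies": self.fold_accuracies,
            "accuracy_mean": self.accuracy_mean,
            "accuracy_std": self.accuracy_std,
            "labels": self.labels,
            "confusion": self.confusion.tolist(),
            "kappa": self.kappa,
            "precision": self.precision,
            "recall": self.recall,
            "importances": {
                "feature": list(self.importances.index),
                "normalized": self.importances["normalized_importance"].tolist(),
                "cumulative": self.importances["cumulative_importance"].tolist(),
            },
        }
        if self.rfe is not None:
            out["rfe"] = {
                "error_curve": self.rfe["error_curve"],
                "n_features": self.rfe["n_features"],
                "removal_order": self.rfe["removal_order"],
                "best_n_features": self.rfe["best_n_features"],
            }
        return out


def _feature_matrix(table: pd.DataFrame, features: list[str] | None = None
                    ) -> tuple[np.ndarray, list[str]]:
    if features is None:
        features = [c for c in feature_columns(full_stats=True) if c in table.columns]
    return table[features].to_numpy(dtype=float), list(features)


def _stratified_split(y: np.ndarray, holdout: float, seed: int, stratify: bool,
                      max_retries: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """One 80/20 shuffle-split whose training side contains every class."""
    n = len(y)
    idx = np.arange(n)
    classes = np.unique(y)
    for attempt in range(max_retries):
        rs = seed + attempt
        stratifiable = (
            stratify
            and all(np.sum(y == c) >= 2 for c in classes)
            and max(1, int(round(holdout * n))) >= len(classes)
        )
        if stratifiable:
            splitter = StratifiedShuffleSplit(n_splits=1, test_size=holdout,
                                              random_state=rs)
            try:
                train, test = next(splitter.split(idx.reshape(-1, 1), y))
            except ValueError:
                stratifiable = False
        if not stratifiable:
            rng = np.random.default_rng(rs)
            perm = rng.permutation(n)
            n_test = max(1, int(round(holdout * n)))
            test, train = perm[:n_test], perm[n_test:]
        if set(np.unique(y[train])) == set(classes):
            if attempt > 0:
                warnings.warn(
                    f"re-drew split {attempt} time(s) to keep all classes in training",
                    stacklevel=2,
                )
            return train, test
    raise ValueError("could not draw a training split containing every class")


def threefold_cv(table: pd.DataFrame, labels, config: CVConfig,
                 scheme: str = "custom", features: list[str] | None = None,
                 run_rfe: bool = False) -> EvalReport:
    """Repeated-holdout cross-validation of the gradient-boosting classifier.

    Each fold draws a fresh stratified 80/20 shuffle-split, trains with
    early stopping, and scores the hold-out; accuracies are averaged and
    the hold-out predictions pooled into one confusion matrix.  Fully
    deterministic given ``config.seed``.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes to train a classifier")
    if len(table) < 10:
        raise ValueError("need at least 10 rows")
    if len(table) != len(y):
        raise ValueError("labels must align with table rows")
    X, feat_names = _feature_matrix(table, features)

    rng = np.random.default_rng(config.seed)
    fold_seeds = [int(s) for s in rng.integers(0, 2**31 - 100, size=config.n_folds)]

    classes = np.unique(y)
    accs: list[float] = []
    cm = np.zeros((len(classes), len(classes)))
    class_pos = {c: i for i, c in enumerate(classes)}
    imp_sum = np.zeros(X.shape[1])
    last_model = None
    for fold_seed in fold_seeds:
        train, test = _stratified_split(y, config.holdout_fraction, fold_seed,
                                        config.stratify)
        model = _make_learner(config, random_state=fold_seed, y_train=y[train])
        model.fit(X[train], y[train])
        pred = model.predict(X[test])
        accs.append(float(np.mean(pred == y[test])))
        for t, pr in zip(y[test], pred):
            cm[class_pos[t], class_pos[pr]] += 1
        imp_sum += model.feature_importances_
        last_model = model

    class _Avg:
        feature_importances_ = imp_sum / config.n_folds

    report = EvalReport(
        scheme=scheme,
        fold_accuracies=accs,
        accuracy_mean=float(np.mean(accs)),
        accuracy_std=float(np.std(accs)),
        labels=[int(c) for c in classes],
        confusion=cm,
        kappa=cohens_kappa(cm),
        precision=precision_recall(cm)[0],
        recall=precision_recall(cm)[1],
        importances=feature_importances(_Avg, feat_names),
    )
    if run_rfe:
        report.rfe = recursive_feature_elimination(table, y, config, features=feat_names)
    return report


def recursive_feature_elimination(table: pd.DataFrame, labels, config: CVConfig,
                                  features: list[str] | None = None,
                                  stop_at: int = 1) -> dict:
    """Iteratively drop the lowest-importance feature, recording hold-out error.

    At each feature count from the full set down to ``stop_at`` the model is
    trained on a fresh stratified 80/20 split, the hold-out error recorded
    and the weakest feature (by impurity importance) removed.  Returns the
    error curve (aligned with ``n_features``), the removal order, and the
    feature count minimising the error.
    """
    y = np.asarray(labels, dtype=int)
    X_full, feat_names = _feature_matrix(table, features)
    if len(feat_names) < 2:
        raise ValueError("need at least 2 features for elimination")
    remaining = list(feat_names)
    rng = np.random.default_rng(config.seed)
    error_curve: list[float] = []
    n_features: list[int] = []
    removal_order: list[str] = []
    while len(remaining) >= stop_at:
        split_seed = int(rng.integers(0, 2**31 - 100))
        train, test = _stratified_split(y, config.holdout_fraction, split_seed,
                                        config.stratify)
        cols = [feat_names.index(f) for f in remaining]
        X = X_full[:, cols]
        model = _make_learner(config, random_state=split_seed, y_train=y[train])
        model.fit(X[train], y[train])
        err = 1.0 - float(np.mean(model.predict(X[test]) == y[test]))
        error_curve.append(err)
        n_features.append(len(remaining))
        if len(remaining) == stop_at:
            break
        weakest = remaining[int(np.argmin(model.feature_importances_))]
        removal_order.append(weakest)
        remaining.remove(weakest)
    best = n_features[int(np.argmin(error_curve))]
    return {
        "error_curve": error_curve,
        "n_features": n_features,
        "removal_order": removal_order,
        "best_n_features": best,
        "remaining": remaining,
    }


def per_scorer_validation(table: pd.DataFrame, config: CVConfig,
                          schemes: list[str] | None = None,
                          scorer_columns: list[str] | None = None
                          ) -> dict[str, dict[str, EvalReport]]:
    """Re-run the full CV per individual rater's scores and per label scheme.

    Checks whether the model generalises to the underlying lameness
    indicators rather than to one rater's idiosyncrasies: per-rater
    accuracies should sit close to the consolidated-score run.
    """
    if scorer_columns is None:
        scorer_columns = [c for c in table.columns if c.startswith("scorer_")]
    if len(scorer_columns) < 2:
        raise ValueError("need at least 2 rater columns")
    if schemes is None:
        schemes = list(LABEL_SCHEMES)
    out: dict[str, dict[str, EvalReport]] = {}
    for col in scorer_columns:
        scores = table[col].to_numpy(dtype=int)
        out[col] = {
            scheme: threefold_cv(table, make_labels(scores, scheme), config,
                                 scheme=scheme)
            for scheme in schemes
        }
    return out
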