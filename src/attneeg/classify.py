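"""Feature-matrix assembly, per-subject normalization, cross-validated
classification (gradient-boosted trees / SVM / random forest) and reporting.

Rows are 3-s epochs; columns are named ``<channel>.<feature>`` values plus
the metadata columns ``subject_id``, ``label``, ``trial_order`` and
``source``. Three task definitions are supported: 4-level (HA/MA/LA/RS),
3-level (HA/MA/LA) and 2-level (AS = HA+MA+LA vs RS).

Two validation schemes mirror the two ways such cohorts are evaluated:
leave-one-subject-out (every epoch of the held-out subject is test data —
the cross-subject generalization estimate) and epoch-level stratified 5-fold
pooled across subjects (epochs of one subject can appear in both train and
test folds, which is why 5-fold accuracies run far above LOOCV ones).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, LeaveOneGroupOut, StratifiedKFold
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .channels import FRONTAL_CHANNELS
from .complexity import complexity_features
from .core import Epoch
from .labeling import label_trials
from .spectral import power_ratio_features

log = logging.getLogger(__name__)

META_COLUMNS = ("subject_id", "label", "trial_order", "source")

TASK_LEVELS = {
    "4level": ("HA", "MA", "LA", "RS"),
    "3level": ("HA", "MA", "LA"),
    "2level": ("AS", "RS"),
}


def feature_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in META_COLUMNS]


def label_epochs(epochs: list[Epoch], labeled_trials: pd.DataFrame) -> list[Epoch]:
    """Attach HA/MA/LA labels to task epochs from a labeled trial table.

    Task epochs whose trial was removed (outlier / no response) keep
    ``label=None`` and are dropped at assembly. Rest epochs keep RS.
    """
    by_idx = dict(zip(labeled_trials["trial_idx"], labeled_trials["label"]))
    for ep in epochs:
        kind, idx = ep.source
        if kind == "task":
            ep.label = by_idx.get(idx)
    return epochs


def extract_features(
    epochs: list[Epoch],
    featureset: str = "complexity",
    channels: tuple[str, ...] | None = None,
    entropy_params: dict | None = None,
    index_range: tuple[int, int] = (1, 10),
) -> pd.DataFrame:
    """Per-epoch feature rows for one feature set.

    ``complexity`` -> 5 features/channel, ``classical`` -> 3, ``combined``
    -> 8. Default region is the 13-channel frontal group (65 / 39 columns);
    the combined set is conventionally run on all 32 channels (256 columns).
    Extraction is per-epoch independent, so results do not depend on
    execution order.
    """
    if featureset not in ("complexity", "classical", "combined"):
        raise ValueError("featureset must be complexity | classical | combined")
    channels = tuple(channels) if channels is not None else FRONTAL_CHANNELS
    rows = []
    for ep in epochs:
        row: dict = {
            "subject_id": ep.subject_id,
            "label": ep.label,
            "trial_order": ep.source[1],
            "source": ep.source[0],
        }
        if featureset in ("complexity", "combined"):
            row.update(complexity_features(ep, channels, entropy_params, index_range))
        if featureset in ("classical", "combined"):
            row.update(power_ratio_features(ep, channels))
        rows.append(row)
    return pd.DataFrame(rows)


def build_feature_matrix(features: pd.DataFrame, task: str = "4level") -> pd.DataFrame:
    """Map labels for ``task`` and drop unusable rows (no label / NaN features).

    4-level keeps HA/MA/LA/RS; 3-level drops rest epochs; 2-level merges the
    three attention levels into AS against RS.
    """
    if task not in TASK_LEVELS:
        raise ValueError(f"unknown task {task!r}")
    df = features.copy()
    n0 = len(df)
    df = df[df["label"].notna()]
    feat_cols = feature_columns(df)
    df = df.dropna(subset=feat_cols)
    if len(df) < n0:
        log.info("dropped %d epochs with missing labels or undefined features", n0 - len(df))
    if task == "3level":
        df = df[df["label"] != "RS"]
    elif task == "2level":
        df = df.copy()
        df.loc[df["label"].isin(("HA", "MA", "LA")), "label"] = "AS"
    return df.reset_index(drop=True)


def normalize_within_subject(mat: pd.DataFrame) -> pd.DataFrame:
    """Min-max map every feature column to [0, 1] within each subject.

    Idempotent; a within-subject constant column maps to 0.5 with a warning.
    """
    out = mat.copy()
    cols = feature_columns(mat)
    for _, idx in out.groupby("subject_id").groups.items():
        block = out.loc[idx, cols]
        lo, hi = block.min(), block.max()
        span = hi - lo
        const = span == 0
        if const.any():
            log.warning("constant feature(s) within subject mapped to 0.5: %s",
                        list(span.index[const])[:5])
        span = span.replace(0, 1.0)
        normed = (block - lo) / span
        normed.loc[:, const[const].index] = 0.5
        out.loc[idx, cols] = normed
    return out


# --- cross-validation -----------------------------------------------------

_GBT_GRID = {"max_depth": [3, 6], "learning_rate": [0.1, 0.3]}
_SVM_GRID = {"C": [1.0, 10.0]}


def _make_model(model: str, seed: int):
    if model == "gbt":
        return XGBClassifier(
            n_estimators=200, max_depth=3, learning_rate=0.3,
            tree_method="hist", n_jobs=1, random_state=seed,
            eval_metric="mlogloss", verbosity=0,
        )
    if model == "svm":
        return SVC(kernel="rbf", gamma="scale", C=1.0, random_state=seed)
    if model == "rf":
        return RandomForestClassifier(n_estimators=500, n_jobs=1, random_state=seed)
    raise ValueError(f"unknown model {model!r}")


@dataclass
class CVReport:
    """Per-fold accuracies and pooled out-of-fold predictions for one run."""

    scheme: str
    task: str
    model: str
    classes: tuple[str, ...]
    fold_accuracies: list[float]  # percent
    confusion: np.ndarray
    oof_true: np.ndarray  # class indices of rows with OOF predictions
    oof_scores: np.ndarray  # (n, k) class scores
    feature_names: list[str]
    fold_importances: list[dict] = field(default_factory=list)
    skipped_folds: int = 0

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1)) if len(self.fold_accuracies) > 1 else 0.0

    def balanced_accuracy(self) -> float:
        with np.errstate(invalid="ignore"):
            recalls = np.diag(self.confusion) / self.confusion.sum(axis=1)
        return float(np.nanmean(recalls) * 100)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "task": self.task,
            "model": self.model,
            "classes": list(self.classes),
            "fold_accuracies": self.fold_accuracies,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "confusion": self.confusion.tolist(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def run_cv(
    mat: pd.DataFrame,
    scheme: str = "kfold",
    model: str = "gbt",
    task: str = "4level",
    seed: int = 0,
    tune: bool = True,
    n_folds: int = 5,
) -> CVReport:
    """Cross-validated classification of a (normalized) feature matrix.

    ``scheme="loocv"`` holds out one subject per fold; ``scheme="kfold"``
    is an epoch-level stratified split pooled across subjects. Hyperparameter
    tuning (gbt depth/learning-rate, SVM C) uses an inner stratified 3-fold
    grid search on the training fold only. Accuracy is percent correct per
    fold; folds missing a training class are skipped with a warning.
    """
    classes = TASK_LEVELS[task]
    present = [c for c in classes if (mat["label"] == c).any()]
    if len(present) < 2:
        raise ValueError(f"task {task} is degenerate: classes present {present}")
    class_to_idx = {c: i for i, c in enumerate(classes)}

    cols = feature_columns(mat)
    X = mat[cols].to_numpy(dtype=np.float64)
    y = mat["label"].map(class_to_idx).to_numpy(dtype=int)
    groups = mat["subject_id"].to_numpy()

    if scheme == "loocv":
        if len(np.unique(groups)) < 2:
            raise ValueError("LOOCV needs at least 2 subjects")
        splits = list(LeaveOneGroupOut().split(X, y, groups))
    elif scheme == "kfold":
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = list(skf.split(X, y))
    else:
        raise ValueError("scheme must be 'loocv' or 'kfold'")

    fold_acc: list[float] = []
    importances: list[dict] = []
    oof_true, oof_scores = [], []
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    skipped = 0

    for tr, te in splits:
        if len(np.unique(y[tr])) < len(np.unique(y)):
            log.warning("fold skipped: class missing from training data")
            skipped += 1
            continue
        est = _make_model(model, seed)
        if tune and model in ("gbt", "svm"):
            grid = _GBT_GRID if model == "gbt" else _SVM_GRID
            search = GridSearchCV(
                est, grid,
                cv=StratifiedKFold(3, shuffle=True, random_state=seed),
                scoring="accuracy", n_jobs=1,
            )
            search.fit(X[tr], _compress(y[tr]))
            est = search.best_estimator_
        else:
            est.fit(X[tr], _compress(y[tr]))

        y_pred = _decompress(est.predict(X[te]), y[tr])
        fold_acc.append(float(np.mean(y_pred == y[te]) * 100))
        conf += confusion_matrix(y[te], y_pred, labels=range(len(classes)))

        scores = est.predict_proba(X[te]) if hasattr(est, "predict_proba") else est.decision_function(X[te])
        if scores.ndim == 1:  # binary decision_function
            scores = np.column_stack([-scores, scores])
        full = np.full((len(te), len(np.unique(y))), -np.inf)
        full[:, _present_positions(y[tr], y)] = scores
        oof_scores.append(full)
        oof_true.append(y[te])

        if model == "gbt":
            # total gain (gain x use count): per-split mean gain lets a
            # single lucky split on a noise feature outrank consistently
            # used informative features
            gain = est.get_booster().get_score(importance_type="total_gain")
            importances.append({cols[int(k[1:])]: v for k, v in gain.items()})
        elif model == "rf":
            importances.append(dict(zip(cols, est.feature_importances_)))

    if not fold_acc:
        raise ValueError("all folds were skipped")

    return CVReport(
        scheme=scheme, task=task, model=model, classes=classes,
        fold_accuracies=fold_acc, confusion=conf,
        oof_true=np.concatenate(oof_true),
        oof_scores=np.vstack(oof_scores),
        feature_names=cols, fold_importances=importances,
        skipped_folds=skipped,
    )


def _compress(y: np.ndarray) -> np.ndarray:
    """Map labels to 0..k-1 in sorted order (xgboost requires contiguity)."""
    _, inv = np.unique(y, return_inverse=True)
    return inv


def _decompress(pred: np.ndarray, y_train: np.ndarray) -> np.ndarray:
    return np.unique(y_train)[pred]


def _present_positions(y_train: np.ndarray, y_all: np.ndarray) -> np.ndarray:
    all_classes = np.unique(y_all)
    return np.searchsorted(all_classes, np.unique(y_train))


def roc_curves(report: CVReport) -> dict:
    """Pooled out-of-fold ROC: macro one-vs-rest AUC plus per-class curves."""
    y = report.oof_true
    s = report.oof_scores
    present = np.unique(y)
    if s.shape[1] != len(present):
        s = s[:, present]
    out: dict = {"per_class": {}}
    if len(present) == 2:
        score = s[:, 1]
        out["auc"] = float(roc_auc_score(y == present[1], score))
        fpr, tpr, _ = roc_curve(y == present[1], score)
        out["per_class"][report.classes[present[1]]] = {"fpr": fpr.tolist(), "tpr": tpr.tolist()}
    else:
        # row-normalize scores so each row is a proper score vector
        out["auc"] = float(
            roc_auc_score(y, s / s.sum(axis=1, keepdims=True), multi_class="ovr", average="macro")
        )
        for pos, ci in enumerate(present):
            fpr, tpr, _ = roc_curve(y == ci, s[:, pos])
            out["per_class"][report.classes[ci]] = {
                "fpr": fpr.tolist(),
                "tpr": tpr.tolist(),
                "auc": float(roc_auc_score(y == ci, s[:, pos])),
            }
    return out


def feature_importance(report: CVReport, top_k: int = 10) -> pd.DataFrame:
    """Mean importance (gain) across folds, descending; ties broken by name.

    Only defined for tree-based models.
    """
    if report.model not in ("gbt", "rf"):
        raise ValueError(f"feature importance unsupported for model {report.model!r}")
    agg: dict[str, list[float]] = {name: [] for name in report.feature_names}
    for fold in report.fold_importances:
        for name in report.feature_names:
            agg[name].append(fold.get(name, 0.0))
    rows = [
        {
            "feature": name,
            "channel": name.split(".")[0],
            "metric": name.split(".", 1)[1],
            "score": float(np.mean(v)),
        }
        for name, v in agg.items()
    ]
    df = pd.DataFrame(rows).sort_values(["score", "feature"], ascending=[False, True])
    return df.head(top_k).reset_index(drop=True)


def alpha_sweep(
    features: pd.DataFrame,
    trials_by_subject: dict[str, pd.DataFrame],
    alphas: tuple[float, ...] = (0.05, 0.15, 0.25, 0.35),
    scheme: str = "kfold",
    model: str = "gbt",
    task: str = "4level",
    seed: int = 0,
    tune: bool = True,
    rt_outlier_sd: float = 3.0,
) -> pd.DataFrame:
    """Accuracy as a function of the labeling quantile ``alpha``.

    Features are computed once; only the behavioral labels are re-derived
    per alpha, so the alpha=0.25 row reproduces the default pipeline run
    bit-exactly under the same seed.
    """
    rows = []
    for alpha in alphas:
        feats = features.copy()
        for sid, trials in trials_by_subject.items():
            labeled = label_trials(trials, alpha=alpha, k_sd=rt_outlier_sd)
            by_idx = dict(zip(labeled["trial_idx"], labeled["label"]))
            mask = (feats["subject_id"] == sid) & (feats["source"] == "task")
            feats.loc[mask, "label"] = feats.loc[mask, "trial_order"].map(by_idx)
        mat = normalize_within_subject(build_feature_matrix(feats, task))
        report = run_cv(mat, scheme=scheme, model=model, task=task, seed=seed, tune=tune)
        rows.append({"alpha": alpha, "accuracy": report.mean_accuracy, "sd": report.sd_accuracy})
    return pd.DataFrame(rows)
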