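"""Group statistics across attention levels and the EEG-dynamics vs
behavior correlation.

Group differences use a normality-gated test choice: if every group passes
the D'Agostino-Pearson normality test, a one-way ANOVA is used; otherwise
the non-parametric Kruskal-Wallis test. Channel-wise maps bin p-values into
the conventional three significance levels.

The dynamics analysis reduces the 13 frontal channels' per-trial feature
series to their first principal component within each subject, averages the
PC1 and calibrated-RT trajectories across subjects position-wise, and
reports their Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

from .channels import FRONTAL_CHANNELS

SIGNIFICANCE_BINS = ("ns", "(0.01,0.05]", "(0.001,0.01]", "<=0.001")

#: Minimum group size for the D'Agostino-Pearson test (its kurtosis part
#: needs n >= 8; smaller groups are treated as non-normal).
_MIN_NORMALTEST_N = 8


def significance_bin(p: float) -> str:
    if p <= 0.001:
        return "<=0.001"
    if p <= 0.01:
        return "(0.001,0.01]"
    if p <= 0.05:
        return "(0.01,0.05]"
    return "ns"


def group_difference_test(groups: dict[str, np.ndarray]) -> tuple[str, float, float]:
    """Normality-gated omnibus test over attention-level groups.

    Returns ``(test_name, statistic, p)`` where ``test_name`` is ``"anova"``
    when all groups look normal (D'Agostino-Pearson, p > 0.05 each) and
    ``"kruskal"`` otherwise.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = []
    for name, v in groups.items():
        v = np.asarray(v, dtype=np.float64)
        if len(v) < 3:
            raise ValueError(f"group {name!r} has fewer than 3 observations")
        arrays.append(v)

    def looks_normal(v: np.ndarray) -> bool:
        if len(v) < _MIN_NORMALTEST_N:
            return False
        return sst.normaltest(v).pvalue > 0.05

    if all(looks_normal(v) for v in arrays):
        res = sst.f_oneway(*arrays)
        return "anova", float(res.statistic), float(res.pvalue)
    res = sst.kruskal(*arrays)
    return "kruskal", float(res.statistic), float(res.pvalue)


def significance_map(
    features: pd.DataFrame,
    feature_name: str,
    levels: tuple[str, ...] = ("HA", "MA", "LA", "RS"),
    channels: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-channel omnibus test of ``feature_name`` across attention levels.

    ``features`` is a feature table with ``label`` metadata and
    ``<channel>.<feature_name>`` columns. Returns one row per channel with
    the chosen test, statistic, p-value and significance bin.
    """
    if channels is None:
        channels = tuple(
            sorted({c.split(".")[0] for c in features.columns if c.endswith("." + feature_name)})
        )
    rows = []
    for ch in channels:
        col = f"{ch}.{feature_name}"
        if col not in features.columns:
            raise ValueError(f"column {col} missing")
        groups = {}
        for lv in levels:
            v = features.loc[features["label"] == lv, col].dropna().to_numpy()
            if len(v) == 0:
                raise ValueError(f"level {lv!r} empty for channel {ch}")
            groups[lv] = v
        test, stat, p = group_difference_test(groups)
        rows.append(
            {"channel": ch, "feature": feature_name, "test": test,
             "statistic": stat, "p": p, "bin": significance_bin(p)}
        )
    return pd.DataFrame(rows)


def pc1_trajectory(trial_features: np.ndarray) -> tuple[np.ndarray, float]:
    """PC1 scores of a trials x channels feature matrix (column-centered).

    The sign is fixed so that PC1 correlates positively with the channel-mean
    trajectory, making results backend-independent. Returns ``(scores,
    explained_variance_ratio)``.
    """
    X = np.asarray(trial_features, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a trials x channels matrix with >= 2 trials")
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("feature matrix has rank 0 after centering")
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    scores = u[:, 0] * s[0]
    channel_mean = Xc.mean(axis=1)
    if np.dot(scores, channel_mean) < 0:
        scores = -scores
    evr = float(s[0] ** 2 / np.sum(s**2))
    return scores, evr


@dataclass
class DynamicsResult:
    """Cohort-averaged PC1 and C-RT trajectories and their rank correlation."""

    pc1_trajectory: np.ndarray
    crt_trajectory: np.ndarray
    spearman_r: float
    p_value: float
    n_positions: int
    per_subject_pc1: list[np.ndarray] | None = None


def dynamics_correlation(
    pc1_by_subject: list[np.ndarray],
    crt_by_subject: list[np.ndarray],
    min_positions: int = 10,
) -> DynamicsResult:
    """Correlate the cohort-mean EEG-dynamics trajectory with behavior.

    Each subject contributes a per-trial PC1 series and a per-trial C-RT
    series (already outlier-cleaned, so lengths differ); all are truncated
    to the shortest length, averaged position-wise across subjects, and
    compared by Spearman rank correlation over trial positions.
    """
    if len(pc1_by_subject) < 2 or len(pc1_by_subject) != len(crt_by_subject):
        raise ValueError("need aligned trajectories for >= 2 subjects")
    n = min(min(len(v) for v in pc1_by_subject), min(len(v) for v in crt_by_subject))
    if n < min_positions:
        raise ValueError(f"only {n} aligned trial positions (< {min_positions})")
    pc1 = np.mean([np.asarray(v[:n], dtype=float) for v in pc1_by_subject], axis=0)
    crt = np.mean([np.asarray(v[:n], dtype=float) for v in crt_by_subject], axis=0)
    r, p = sst.spearmanr(pc1, crt)
    return DynamicsResult(
        pc1_trajectory=pc1,
        crt_trajectory=crt,
        spearman_r=float(r),
        p_value=float(p),
        n_positions=n,
        per_subject_pc1=[np.asarray(v[:n], dtype=float) for v in pc1_by_subject],
    )


def feature_dynamics(
    features: pd.DataFrame,
    labeled_trials_by_subject: dict[str, pd.DataFrame],
    feature_name: str = "mfei",
    channels: tuple[str, ...] = FRONTAL_CHANNELS,
) -> DynamicsResult:
    """End-to-end dynamics correlation for one feature type.

    For each subject, the task-epoch rows of ``features`` are aligned to the
    surviving trials (by trial index), the 13-channel matrix is reduced to
    PC1, and C-RTs are taken from the labeled trial table.
    """
    cols = [f"{ch}.{feature_name}" for ch in channels]
    pc1s, crts = [], []
    for sid, trials in labeled_trials_by_subject.items():
        sub = features[(features["subject_id"] == sid) & (features["source"] == "task")]
        sub = sub.set_index("trial_order")
        surviving = [t for t in trials["trial_idx"] if t in sub.index]
        X = sub.loc[surviving, cols].to_numpy()
        keep = ~np.isnan(X).any(axis=1)
        X = X[keep]
        crt = trials.set_index("trial_idx").loc[np.asarray(surviving)[keep], "crt"].to_numpy()
        scores, _ = pc1_trajectory(X)
        pc1s.append(scores)
        crts.append(crt)
    return dynamics_correlation(pc1s, crts)
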