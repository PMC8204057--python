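"""Feature-matrix assembly, per-subject normalization, cross-validation
mechanics, ROC and importance reporting."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, mannwhitneyu

from attneeg.classify import (
    CVReport,
    alpha_sweep,
    build_feature_matrix,
    feature_columns,
    feature_importance,
    normalize_within_subject,
    roc_curves,
    run_cv,
)


def _matrix(rng, n_per_subject=60, n_subjects=3, n_features=6, informative=False):
    """Random feature matrix with balanced 4-level labels."""
    rows = []
    labels = np.array(["HA", "MA", "LA", "RS"])
    for s in range(n_subjects):
        y = np.tile(labels, n_per_subject // 4)
        X = rng.standard_normal((len(y), n_features))
        if informative:
            X[:, 0] += 3.0 * np.searchsorted(labels, y)
        for i, lab in enumerate(y):
            row = {"subject_id": f"S{s:02d}", "label": lab, "trial_order": i, "source": "task"}
            row.update({f"C{j}.f": X[i, j] for j in range(n_features)})
            rows.append(row)
    return pd.DataFrame(rows)


class TestNormalization:
    def test_minmax_mapping(self):
        df = pd.DataFrame(
            {"subject_id": "S00", "label": "MA", "trial_order": [0, 1, 2],
             "source": "task", "Fz.f": [2.0, 4.0, 6.0]}
        )
        out = normalize_within_subject(df)
        np.testing.assert_allclose(out["Fz.f"], [0.0, 0.5, 1.0])

    def test_subjects_normalized_independently(self):
        df = pd.DataFrame(
            {"subject_id": ["A", "A", "B", "B"], "label": "MA",
             "trial_order": [0, 1, 0, 1], "source": "task",
             "Fz.f": [0.0, 1.0, 100.0, 200.0]}
        )
        out = normalize_within_subject(df)
        np.testing.assert_allclose(out["Fz.f"], [0.0, 1.0, 0.0, 1.0])

    def test_idempotent(self, rng):
        df = _matrix(rng)
        once = normalize_within_subject(df)
        twice = normalize_within_subject(once)
        cols = feature_columns(df)
        np.testing.assert_allclose(once[cols].to_numpy(), twice[cols].to_numpy(), atol=1e-12)

    def test_constant_column_maps_to_half(self):
        df = pd.DataFrame(
            {"subject_id": "S00", "label": "MA", "trial_order": [0, 1],
             "source": "task", "Fz.f": [5.0, 5.0]}
        )
        out = normalize_within_subject(df)
        np.testing.assert_allclose(out["Fz.f"], 0.5)


class TestAssembly:
    def test_task_label_mapping(self, rng):
        df = _matrix(rng)
        assert set(build_feature_matrix(df, "4level")["label"]) == {"HA", "MA", "LA", "RS"}
        assert set(build_feature_matrix(df, "3level")["label"]) == {"HA", "MA", "LA"}
        two = build_feature_matrix(df, "2level")
        assert set(two["label"]) == {"AS", "RS"}
        assert (two["label"] == "AS").sum() == 3 * (two["label"] == "RS").sum()

    def test_rows_with_undefined_features_dropped(self, rng):
        df = _matrix(rng)
        df.loc[3, "C0.f"] = np.nan
        df.loc[5, "label"] = None
        assert len(build_feature_matrix(df, "4level")) == len(df) - 2


class TestCrossValidation:
    def test_leaked_label_feature_gives_perfect_accuracy(self, rng):
        df = _matrix(rng, n_per_subject=40, n_features=1)
        df["C0.f"] = df["label"].map({"HA": 0.0, "MA": 1.0, "LA": 2.0, "RS": 3.0})
        rep = run_cv(df, scheme="kfold", model="gbt", task="4level", seed=0, tune=False)
        assert rep.mean_accuracy == 100.0

    def test_permuted_labels_give_chance_accuracy(self, rng):
        df = _matrix(rng, n_per_subject=80, n_subjects=3)
        df["label"] = rng.permutation(df["label"].to_numpy())
        rep = run_cv(df, scheme="kfold", model="gbt", task="4level", seed=1, tune=False)
        n = int(rep.confusion.sum())
        correct = int(np.trace(rep.confusion))
        lo = binom.ppf(0.005, n, 0.25)
        hi = binom.ppf(0.995, n, 0.25)
        assert lo <= correct <= hi

    def test_loocv_folds_are_subjects(self, rng):
        df = _matrix(rng, n_subjects=4)
        rep = run_cv(df, scheme="loocv", model="gbt", task="4level", seed=0, tune=False)
        assert len(rep.fold_accuracies) == 4

    def test_fixed_seed_reproducible(self, rng):
        df = _matrix(rng, n_per_subject=40, informative=True)
        r1 = run_cv(df, scheme="kfold", model="gbt", task="4level", seed=5, tune=False)
        r2 = run_cv(df, scheme="kfold", model="gbt", task="4level", seed=5, tune=False)
        assert r1.fold_accuracies == r2.fold_accuracies

    @pytest.mark.parametrize("model", ["svm", "rf"])
    def test_alternative_models_run(self, model, rng):
        df = _matrix(rng, n_per_subject=24, informative=True)
        rep = run_cv(df, scheme="kfold", model=model, task="4level", seed=0, tune=False)
        assert 0 <= rep.mean_accuracy <= 100

    def test_degenerate_single_class_rejected(self, rng):
        df = _matrix(rng)
        df["label"] = "HA"
        with pytest.raises(ValueError):
            run_cv(df, task="4level")


class TestROC:
    def _report(self, y, scores, classes=("AS", "RS")):
        return CVReport(
            scheme="kfold", task="2level", model="gbt", classes=classes,
            fold_accuracies=[100.0], confusion=np.eye(2, dtype=int),
            oof_true=y, oof_scores=scores, feature_names=["f"],
        )

    def test_perfect_separation_gives_auc_one(self):
        y = np.array([0] * 10 + [1] * 10)
        s = np.column_stack([1.0 - y, y.astype(float)])
        assert roc_curves(self._report(y, s))["auc"] == 1.0

    def test_label_independent_scores_give_half(self, rng):
        y = rng.integers(0, 2, size=2000)
        raw = rng.random(2000)
        s = np.column_stack([1 - raw, raw])
        assert roc_curves(self._report(y, s))["auc"] == pytest.approx(0.5, abs=0.05)

    def test_binary_auc_equals_rank_statistic(self, rng):
        y = rng.integers(0, 2, size=200)
        raw = rng.random(200) + 0.3 * y
        s = np.column_stack([1 - raw, raw])
        auc = roc_curves(self._report(y, s))["auc"]
        u = mannwhitneyu(raw[y == 1], raw[y == 0], alternative="two-sided").statistic
        assert auc == pytest.approx(u / ((y == 1).sum() * (y == 0).sum()), abs=1e-12)


class TestImportance:
    def test_planted_feature_ranked_first(self, rng):
        df = _matrix(rng, n_per_subject=60, n_features=12, informative=True)
        rep = run_cv(df, scheme="kfold", model="gbt", task="4level", seed=0, tune=False)
        top = feature_importance(rep, top_k=3)
        assert top.iloc[0]["feature"] == "C0.f"

    def test_duplicated_feature_shares_importance(self, rng):
        df = _matrix(rng, n_per_subject=60, n_features=8, informative=True)
        rep0 = run_cv(df, scheme="kfold", model="gbt", task="4level", seed=0, tune=False)
        base = feature_importance(rep0, top_k=8).set_index("feature")["score"]["C0.f"]
        dup = df.copy()
        dup["C9.f"] = dup["C0.f"]
        rep1 = run_cv(dup, scheme="kfold", model="gbt", task="4level", seed=0, tune=False)
        imp = feature_importance(rep1, top_k=9).set_index("feature")["score"]
        combined = imp.get("C0.f", 0.0) + imp.get("C9.f", 0.0)
        assert combined == pytest.approx(base, rel=0.8)
        assert ("C0.f" in imp.index[:4]) or ("C9.f" in imp.index[:4])

    def test_non_tree_model_unsupported(self, rng):
        df = _matrix(rng, n_per_subject=24)
        rep = run_cv(df, scheme="kfold", model="svm", task="4level", seed=0, tune=False)
        with pytest.raises(ValueError):
            feature_importance(rep)


class TestAlphaSweep:
    def test_table_shape_and_default_consistency(self, rng):
        from attneeg.labeling import label_trials
        from attneeg.synthetic import simulate_subject

        from conftest import small_sim_config

        feats_rows = []
        trials_by_subject = {}
        for s in range(2):
            cfg = small_sim_config(n_trials=80, n_ax_trials=60, fs=150.0, rest_minutes=0.3, seed=s)
            _, trials, _ = simulate_subject(cfg, f"S{s:02d}")
            trials_by_subject[f"S{s:02d}"] = trials
            for i in range(len(trials)):
                row = {"subject_id": f"S{s:02d}", "label": None, "trial_order": i, "source": "task"}
                row.update({f"C{j}.f": rng.standard_normal() for j in range(4)})
                feats_rows.append(row)
            for b in range(6):
                row = {"subject_id": f"S{s:02d}", "label": "RS", "trial_order": b, "source": "rest"}
                row.update({f"C{j}.f": rng.standard_normal() for j in range(4)})
                feats_rows.append(row)
        feats = pd.DataFrame(feats_rows)

        alphas = (0.05, 0.15, 0.25, 0.35)
        table = alpha_sweep(feats, trials_by_subject, alphas=alphas, seed=3, tune=False)
        assert list(table["alpha"]) == list(alphas)
        assert table["accuracy"].between(0, 100).all()

        # the alpha = 0.25 row reproduces a direct default run bit-exactly
        direct = feats.copy()
        for sid, trials in trials_by_subject.items():
            labeled = label_trials(trials, alpha=0.25)
            by_idx = dict(zip(labeled["trial_idx"], labeled["label"]))
            mask = (direct["subject_id"] == sid) & (direct["source"] == "task")
            direct.loc[mask, "label"] = direct.loc[mask, "trial_order"].map(by_idx)
        mat = normalize_within_subject(build_feature_matrix(direct, "4level"))
        rep = run_cv(mat, scheme="kfold", model="gbt", task="4level", seed=3, tune=False)
        assert table.loc[table.alpha == 0.25, "accuracy"].iloc[0] == rep.mean_accuracy
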