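"""Config-driven end-to-end runs: simulate -> preprocess -> label ->
features -> classify -> stats, with a reproducibility manifest.

A single master seed fans out to per-stage seeds through
``numpy.random.SeedSequence([master, stage_tag])``, so one number
reproduces the whole run. Each stage persists its outputs under the run
directory; the manifest records config, seeds and SHA-256 checksums of
every written file. When a run is resumed, the feature stage is reloaded
from disk if its config fingerprint matches, which yields outputs identical
to an uninterrupted run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import EEG_CHANNELS, FRONTAL_CHANNELS
from .classify import (
    build_feature_matrix,
    extract_features,
    label_epochs,
    normalize_within_subject,
    roc_curves,
    run_cv,
)
from .config import DEFAULT_ENTROPY_PARAMS, EntropyParams, PipelineConfig
from .core import save_recording
from .labeling import label_trials
from .preprocess import preprocess_recording, segment_epochs
from .stats import feature_dynamics, significance_map
from .synthetic import simulate_subject, write_events_csv, write_ground_truth_csv

log = logging.getLogger(__name__)

_STAGE_TAGS = {"simulate": 1, "ica": 2, "cv": 3}


def stage_seed(master: int, stage: str, extra: int = 0) -> int:
    """Deterministic per-stage seed below 2^31."""
    ss = np.random.SeedSequence([master, _STAGE_TAGS[stage], extra])
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_fingerprint(cfg: PipelineConfig) -> str:
    # out_dir does not affect results: runs in different directories with
    # the same science config must produce identical fingerprints/manifests
    d = cfg.to_dict()
    d.pop("out_dir", None)
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()


def _entropy_params(cfg: PipelineConfig) -> dict[str, EntropyParams]:
    p = dict(DEFAULT_ENTROPY_PARAMS)
    p["mse"] = EntropyParams(m=2, r_factor=0.15, scales=cfg.mse_scales)
    p["mfe"] = EntropyParams(m=2, r_factor=0.15, n=2.0, scales=cfg.mse_scales)
    return p


def compute_cohort_features(
    cfg: PipelineConfig, out_dir: Path | None = None, save_recordings: bool = False
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Simulate, preprocess, label and feature-extract every subject.

    Returns the per-epoch feature table and the labeled trial tables by
    subject. Subjects are processed one at a time to bound memory.
    """
    channels = FRONTAL_CHANNELS if cfg.featureset in ("complexity", "classical") else EEG_CHANNELS
    params = _entropy_params(cfg)
    all_rows: list[pd.DataFrame] = []
    trials_by_subject: dict[str, pd.DataFrame] = {}
    sim = cfg.simulation
    for i in range(sim.n_subjects):
        sid = f"S{i:02d}"
        seed = int(np.random.SeedSequence([sim.seed, i]).generate_state(1)[0])
        rec, trials, truth = simulate_subject(sim, sid, seed=seed)
        if out_dir is not None:
            write_events_csv(trials, out_dir / "sim" / sid / "events.csv")
            write_ground_truth_csv(truth, out_dir / "sim" / sid / "ground_truth.csv")
            if save_recordings:
                save_recording(rec, out_dir / "sim" / sid / "recording")
        rec = preprocess_recording(
            rec,
            notch_hz=cfg.notch_hz,
            band=cfg.bandpass,
            run_ica=cfg.run_ica,
            ica_components=cfg.ica_components,
            eog_reject_threshold=cfg.eog_reject_threshold,
            seed=stage_seed(cfg.seed, "ica", i),
        )
        epochs = segment_epochs(
            rec,
            trials,
            epoch_len=sim.epoch_len,
            rest_block=(0.0, sim.rest_minutes * 60.0),
        )
        labeled = label_trials(trials, alpha=cfg.alpha, k_sd=cfg.rt_outlier_sd)
        trials_by_subject[sid] = labeled
        label_epochs(epochs, labeled)
        feats = extract_features(
            epochs,
            featureset=cfg.featureset,
            channels=channels,
            entropy_params=params if cfg.featureset != "classical" else None,
            index_range=cfg.index_scale_range,
        )
        all_rows.append(feats)
        log.info("subject %s: %d epochs featurized", sid, len(feats))
    return pd.concat(all_rows, ignore_index=True), trials_by_subject


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages and return the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fingerprint = _config_fingerprint(cfg)
    manifest: dict = {"config": cfg.to_dict(), "fingerprint": fingerprint, "stages": {}, "files": {}}

    features_csv = out / "features.csv"
    marker = out / "features.done.json"
    if features_csv.exists() and marker.exists() and json.loads(marker.read_text()) == fingerprint:
        log.info("resuming: reloading features from %s", features_csv)
        features = pd.read_csv(features_csv)
        trials_by_subject = {
            p.parent.name: pd.read_csv(p) for p in sorted(out.glob("labels/*/trials.csv"))
        }
    else:
        features, trials_by_subject = compute_cohort_features(cfg, out_dir=out)
        features.to_csv(features_csv, index=False)
        for sid, trials in trials_by_subject.items():
            p = out / "labels" / sid / "trials.csv"
            p.parent.mkdir(parents=True, exist_ok=True)
            trials.to_csv(p, index=False)
        marker.write_text(json.dumps(fingerprint))
    manifest["stages"]["features"] = {"rows": len(features), "path": str(features_csv)}

    results: dict = {}
    for task in cfg.tasks:
        for scheme in cfg.cv_schemes:
            mat = normalize_within_subject(build_feature_matrix(features, task))
            report = run_cv(
                mat,
                scheme=scheme,
                model=cfg.model,
                task=task,
                seed=stage_seed(cfg.seed, "cv"),
                tune=cfg.tune,
            )
            key = f"{task}_{scheme}"
            report.to_json(out / f"cv_{key}.json")
            results[key] = {
                "mean_accuracy": report.mean_accuracy,
                "sd_accuracy": report.sd_accuracy,
                "auc": roc_curves(report)["auc"],
            }
    manifest["stages"]["classify"] = results

    if cfg.featureset in ("complexity", "combined"):
        sig = significance_map(features, "sampen")
        sig.to_csv(out / "significance_sampen.csv", index=False)
        dyn = feature_dynamics(features, trials_by_subject, feature_name="mfei")
        dyn_out = {
            "spearman_r": dyn.spearman_r,
            "p_value": dyn.p_value,
            "n_positions": dyn.n_positions,
        }
        (out / "dynamics_mfei.json").write_text(json.dumps(dyn_out, indent=1))
        manifest["stages"]["stats"] = {"dynamics_mfei": dyn_out}

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][str(p.relative_to(out))] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
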