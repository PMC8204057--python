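"""Synthetic AX-CPT cohort generator (behavior + EEG) with known ground truth.

Each simulated session mirrors the recorded protocol: a resting block
followed by 192 AX-CPT trials (144 "AX" sequences), inter-trial intervals
drawn from {1.5, 2.0, 2.5} s, and 32 EEG + 2 EOG channels.

The subject's attention is a latent AR(1) state in [0, 1] that drifts slowly
over trials. It drives two observable consequences:

* behavior — log reaction time decreases linearly in the latent state
  (attentive = fast), on top of a subject-specific speed offset and
  log-normal trial noise;
* EEG irregularity — each channel is a pink(1/f)/white noise mixture whose
  white-noise weight rises with the latent state during task epochs and is
  lowest at rest, so sample/fuzzy entropy is ordered HA > MA > LA > RS.
  Frontal electrodes carry the full effect, the remaining electrodes half.
  An 8-13 Hz alpha oscillation is strongest during rest; optional 50 Hz line
  noise and raised-cosine blink transients (propagating from the eyes with
  decaying gain) complete the artifact model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .channels import ALL_CHANNELS, FRONTAL_CHANNELS, blink_gain, channel_role, effect_scale
from .config import SimulationConfig
from .core import Recording, save_recording

#: Baseline white-noise variance fraction (resting irregularity floor).
_P0 = 0.05
#: White-noise weight gained per unit (entropy_effect x drive x channel
#: scale). Sized so that even entropy_effect = 2 with a high-gain subject
#: stays below p ~ 0.5, the quasi-linear part of the entropy response of
#: the mixture; beyond that the response saturates and the effect dial
#: would stop being monotone.
_EFFECT_GAIN = 0.10
#: Between-subject SD of the baseline white-noise fraction.
_SUBJECT_P_SD = 0.02
#: Between-subject log-SD of the attention->irregularity gain: subjects
#: express the effect with different strength, so a classifier trained on
#: other subjects generalizes imperfectly (per-subject min-max
#: normalization removes additive offsets but not separation/noise ratio).
_SUBJECT_GAIN_SD = 0.3
#: Mean log reaction time, log-ms (~420 ms).
_RT_MU0 = float(np.log(420.0))
#: Alpha-oscillation amplitude relative to unit background noise.
_ALPHA_REST, _ALPHA_TASK = 1.2, 0.3
#: Overall background scale, microvolts RMS.
_SCALE_UV = 20.0
#: EOG leads carry less cerebral background than scalp electrodes.
_EOG_BACKGROUND = 0.5
_BLINK_AMP_UV = 200.0
_BLINK_DUR_S = 0.3
_ERROR_RATE = 0.02

ITI_CHOICES_S = (1.5, 2.0, 2.5)


@dataclass
class GroundTruth:
    """Per-trial latent attention state and its quantile discretization."""

    latent_attention: np.ndarray  # in [0, 1], one per trial
    true_level: np.ndarray  # {"HA", "MA", "LA"}, one per trial
    coupling_sign: int = -1  # complexity vs calibrated RT


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-SD 1/f (power) noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spectrum /= np.sqrt(f)
    x = np.fft.irfft(spectrum, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _discretize(latent: np.ndarray, alpha: float) -> np.ndarray:
    """Symmetric alpha-quantile levels: top -> HA, bottom -> LA, rest -> MA."""
    n = len(latent)
    n_tail = int(round(alpha * n))
    levels = np.full(n, "MA", dtype=object)
    order = np.argsort(latent, kind="stable")
    levels[order[:n_tail]] = "LA"
    levels[order[n - n_tail:]] = "HA"
    return levels.astype(str)


def _latent_ar1(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Stationary AR(1) mapped through the normal CDF into [0, 1]."""
    z = np.empty(n)
    z[0] = rng.standard_normal()
    innov = rng.standard_normal(n) * np.sqrt(1.0 - phi**2)
    for t in range(1, n):
        z[t] = phi * z[t - 1] + innov[t]
    return ndtr(z)


def simulate_subject(
    config: SimulationConfig,
    subject_id: str = "S00",
    seed: int | None = None,
) -> tuple[Recording, pd.DataFrame, GroundTruth]:
    """Simulate one session: resting block, then the full trial sequence.

    Returns the raw recording (32 EEG + 2 EOG channels, microvolts), the
    behavioral trial table (``trial_idx``, ``onset_s``, ``trial_type``,
    ``rt_ms``, ``correct``) and the generating ground truth. Two calls with
    the same config and seed are bit-identical.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fs = config.fs
    n_trials = config.n_trials

    # --- behavior ---------------------------------------------------------
    latent = _latent_ar1(rng, n_trials, config.attention_ar_coeff)
    trial_types = np.array(["AX"] * config.n_ax_trials + ["other"] * (n_trials - config.n_ax_trials))
    rng.shuffle(trial_types)
    subject_rt_offset = rng.normal(0.0, config.rt_subject_sigma)
    rt_ms = np.exp(
        _RT_MU0
        + subject_rt_offset
        + config.rt_attention_slope * latent
        + config.rt_lognormal_sigma * rng.standard_normal(n_trials)
    )
    correct = rng.random(n_trials) > _ERROR_RATE

    itis = rng.choice(ITI_CHOICES_S, size=n_trials)
    rest_s = config.rest_minutes * 60.0
    onsets = rest_s + np.concatenate(([0.0], np.cumsum(config.epoch_len + itis)[:-1]))
    total_s = rest_s + float(np.sum(config.epoch_len + itis))
    n_samples = int(round(total_s * fs))

    trials = pd.DataFrame(
        {
            "trial_idx": np.arange(n_trials),
            "onset_s": onsets,
            "trial_type": trial_types,
            "rt_ms": rt_ms,
            "correct": correct,
        }
    )

    # --- drive waveforms --------------------------------------------------
    # Attention drive: 0 at rest, 0.5 + latent during a trial slot (held
    # through the ITI); task floor keeps task irregularity above rest even
    # for the least attentive trials.
    drive = np.zeros(n_samples)
    task_mask = np.zeros(n_samples, dtype=bool)
    slot_starts = (onsets * fs).round().astype(int)
    slot_ends = np.append(slot_starts[1:], n_samples)
    for t0, t1, lat in zip(slot_starts, slot_ends, latent):
        drive[t0:t1] = 0.5 + lat
        task_mask[t0:t1] = True

    alpha_amp = np.where(task_mask, _ALPHA_TASK, _ALPHA_REST)
    tgrid = np.arange(n_samples) / fs
    subject_p_jitter = rng.normal(0.0, _SUBJECT_P_SD)
    subject_gain = np.exp(rng.normal(0.0, _SUBJECT_GAIN_SD))
    alpha_freq = rng.uniform(9.0, 11.0)

    # --- EEG synthesis ----------------------------------------------------
    data = np.empty((len(ALL_CHANNELS), n_samples))
    for ci, name in enumerate(ALL_CHANNELS):
        pink = _pink_noise(rng, n_samples)
        white = rng.standard_normal(n_samples)
        if config.frontal_only_effect:
            ch_scale = 1.0 if name in FRONTAL_CHANNELS else 0.0
        else:
            ch_scale = effect_scale(name)
        p = _P0 + subject_p_jitter + _EFFECT_GAIN * subject_gain * config.entropy_effect * drive * ch_scale
        p = np.clip(p, 0.01, 0.9)
        x = np.sqrt(1.0 - p) * pink + np.sqrt(p) * white
        x += alpha_amp * np.sin(2 * np.pi * alpha_freq * tgrid + rng.uniform(0, 2 * np.pi))
        x *= _SCALE_UV
        if channel_role(name) == "EOG":
            x *= _EOG_BACKGROUND
        if config.line_noise_amp > 0:
            x += config.line_noise_amp * rng.uniform(0.8, 1.2) * np.sin(
                2 * np.pi * 50.0 * tgrid + rng.uniform(0, 2 * np.pi)
            )
        data[ci] = x

    # --- blinks (shared event train, per-channel gain) --------------------
    if config.blink_rate > 0:
        n_blinks = rng.poisson(config.blink_rate * total_s / 60.0)
        blink_len = int(round(_BLINK_DUR_S * fs))
        template = 0.5 * (1 - np.cos(2 * np.pi * np.arange(blink_len) / blink_len))
        starts = rng.integers(0, max(1, n_samples - blink_len), size=n_blinks)
        train = np.zeros(n_samples)
        for s in starts:
            train[s : s + blink_len] += template
        for ci, name in enumerate(ALL_CHANNELS):
            data[ci] += _BLINK_AMP_UV * blink_gain(name) * train

    rec = Recording(
        data=data,
        fs=fs,
        channel_labels=list(ALL_CHANNELS),
        subject_id=subject_id,
    )
    truth = GroundTruth(
        latent_attention=latent,
        true_level=_discretize(latent, config.label_alpha),
    )
    return rec, trials, truth


def simulate_cohort(
    config: SimulationConfig,
) -> list[tuple[Recording, pd.DataFrame, GroundTruth]]:
    """Simulate ``config.n_subjects`` subjects with derived per-subject seeds.

    Subject ``i``'s seed is derived from ``(master_seed, i)`` only, so a
    given subject's data does not depend on the cohort size. Subject-specific
    RT offsets (SD ``rt_subject_sigma`` log-ms) make absolute reaction times
    differ across subjects, exercising the calibration step downstream.
    """
    if config.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    out = []
    for i in range(config.n_subjects):
        sid = f"S{i:02d}"
        seed_seq = np.random.SeedSequence([config.seed, i])
        out.append(simulate_subject(config, sid, seed=seed_seq.generate_state(1)[0]))
    return out


# --- persistence ----------------------------------------------------------

def write_events_csv(trials: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trials.to_csv(path, index=False)
    return path


def write_ground_truth_csv(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "latent_attention": truth.latent_attention,
            "true_level": truth.true_level,
            "coupling_sign": truth.coupling_sign,
        }
    ).to_csv(path, index=False)
    return path


def write_cohort(config: SimulationConfig, out_dir: str | Path) -> list[Path]:
    """Write one recording + events CSV + ground-truth CSV per subject."""
    out_dir = Path(out_dir)
    written = []
    for rec, trials, truth in simulate_cohort(config):
        base = out_dir / rec.subject_id
        written.append(save_recording(rec, base / "recording"))
        written.append(write_events_csv(trials, base / "events.csv"))
        written.append(write_ground_truth_csv(truth, base / "ground_truth.csv"))
    return written
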