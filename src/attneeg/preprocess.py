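"""Cleaning and epoching: zero-phase filters, EOG-correlated ICA rejection,
and onset-anchored 3-s segmentation.

Filtering uses 3rd-order Butterworth IIR sections applied forward-backward
(``sosfiltfilt``), so event alignment is preserved. Ocular rejection
decomposes the EEG-role channels into independent components, zeroes every
component whose absolute correlation with either EOG lead exceeds a
threshold, and back-projects the remainder.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .core import Epoch, Recording

log = logging.getLogger(__name__)


def notch_filter(rec: Recording, freq: float = 50.0, bandwidth: float = 2.0) -> Recording:
    """Zero-phase notch at ``freq`` Hz (power-line suppression)."""
    if freq >= rec.fs / 2:
        raise ValueError(f"notch frequency {freq} Hz must be below Nyquist {rec.fs / 2} Hz")
    b, a = signal.iirnotch(freq, Q=freq / bandwidth, fs=rec.fs)
    out = signal.filtfilt(b, a, rec.data, axis=1)
    return rec.with_data(out)


def bandpass_filter(rec: Recording, lo: float = 0.3, hi: float = 70.0, order: int = 3) -> Recording:
    """Zero-phase Butterworth band-pass (default 0.3-70 Hz, order 3)."""
    if not (0 < lo < hi < rec.fs / 2):
        raise ValueError(f"invalid band ({lo}, {hi}) for fs={rec.fs}")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.with_data(out)


def remove_ocular_ica(
    rec: Recording,
    n_components: int = 30,
    reject_threshold: float = 0.7,
    seed: int = 0,
    max_retries: int = 3,
) -> tuple[Recording, list[int]]:
    """Reject EOG-correlated independent components from the EEG channels.

    The EEG-role channels are decomposed into ``n_components`` ICs; any IC
    whose maximum absolute Pearson correlation with either EOG channel
    exceeds ``reject_threshold`` is zeroed before back-projection. EOG
    channels themselves are passed through untouched. If no IC crosses the
    threshold the input is returned unchanged (exact no-op).

    Returns the cleaned recording and the rejected IC indices.
    """
    eeg_idx = [i for i, r in enumerate(rec.channel_roles) if r == "EEG"]
    eog_idx = [i for i, r in enumerate(rec.channel_roles) if r == "EOG"]
    if len(eeg_idx) < n_components:
        raise ValueError(f"need >= {n_components} EEG channels, got {len(eeg_idx)}")
    if not eog_idx:
        raise ValueError("no EOG-role channels present")

    X = rec.data[eeg_idx].T  # samples x channels
    eog = rec.data[eog_idx]

    # FastICA's symmetric iteration rarely meets tol when most background
    # sources are near-Gaussian; the unmixing estimate is still usable for
    # correlation-based ocular rejection, so after the retries we proceed
    # with the last fit rather than refusing to clean the recording.
    sources = None
    for attempt in range(max_retries):
        ica = FastICA(
            n_components=n_components,
            random_state=seed + attempt,
            whiten="unit-variance",
            max_iter=2000,
            tol=1e-3,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            sources = ica.fit_transform(X)
            if not any(issubclass(w.category, ConvergenceWarning) for w in caught):
                break
        log.warning("ICA did not converge (attempt %d/%d)", attempt + 1, max_retries)
    else:
        log.error("ICA did not meet tolerance after %d seeds; using last fit", max_retries)

    # max |corr| of each IC with either EOG lead
    rejected: list[int] = []
    for k in range(sources.shape[1]):
        r = max(abs(float(np.corrcoef(sources[:, k], e)[0, 1])) for e in eog)
        if r >= reject_threshold:
            rejected.append(k)

    if not rejected:
        log.info("no IC exceeded |r| >= %.2f; recording returned unchanged", reject_threshold)
        return rec, []

    kept = sources.copy()
    kept[:, rejected] = 0.0
    X_clean = kept @ ica.mixing_.T + ica.mean_

    out = rec.data.copy()
    out[eeg_idx] = X_clean.T
    return rec.with_data(out), rejected


def segment_epochs(
    rec: Recording,
    trials: pd.DataFrame | None = None,
    epoch_len: float = 3.0,
    rest_block: tuple[float, float] | None = None,
) -> list[Epoch]:
    """Cut onset-anchored task epochs and tile the rest block into RS epochs.

    Task epochs are ``[onset, onset + epoch_len)`` windows, one per trial;
    trials whose window falls outside the recording are dropped with a
    warning. The rest block is tiled into non-overlapping ``epoch_len``
    windows (floor division; the trailing partial window is discarded),
    labeled ``RS``.
    """
    n_ep = int(round(epoch_len * rec.fs))
    epochs: list[Epoch] = []

    if rest_block is not None:
        r0, r1 = rest_block
        i0 = int(round(r0 * rec.fs))
        n_blocks = int((int(round(r1 * rec.fs)) - i0) // n_ep)
        for b in range(n_blocks):
            s = i0 + b * n_ep
            epochs.append(
                Epoch(
                    data=rec.data[:, s : s + n_ep].copy(),
                    fs=rec.fs,
                    channel_labels=list(rec.channel_labels),
                    subject_id=rec.subject_id,
                    source=("rest", b),
                    label="RS",
                )
            )

    if trials is not None:
        for row in trials.itertuples():
            s = int(round(row.onset_s * rec.fs))
            if s < 0 or s + n_ep > rec.n_samples:
                log.warning(
                    "trial %s onset %.2f s outside recording; dropped", row.trial_idx, row.onset_s
                )
                continue
            epochs.append(
                Epoch(
                    data=rec.data[:, s : s + n_ep].copy(),
                    fs=rec.fs,
                    channel_labels=list(rec.channel_labels),
                    subject_id=rec.subject_id,
                    source=("task", int(row.trial_idx)),
                )
            )
    return epochs


def preprocess_recording(
    rec: Recording,
    notch_hz: float = 50.0,
    band: tuple[float, float] = (0.3, 70.0),
    run_ica: bool = True,
    ica_components: int = 30,
    eog_reject_threshold: float = 0.7,
    seed: int = 0,
) -> Recording:
    """Notch -> band-pass -> (optional) ocular ICA, in the recorded order."""
    rec = notch_filter(rec, notch_hz)
    rec = bandpass_filter(rec, *band)
    if run_ica:
        rec, _ = remove_ocular_ica(
            rec,
            n_components=ica_components,
            reject_threshold=eog_reject_threshold,
            seed=seed,
        )
    return rec
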