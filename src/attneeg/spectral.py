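"""Classical frequency-domain features: wavelet-packet band separation and
Welch power ratios beta/theta, beta/alpha, beta/(alpha+theta).

A 7-layer wavelet packet decomposition tiles [0, fs/2] into 128 uniform
sub-bands of width fs/256. Each terminal node (frequency ordering) is
assigned to theta (4-8 Hz), alpha (8-13 Hz) or beta (13-30 Hz) when at least
half of its interval overlaps the band; the band signal is the inverse
transform of the retained nodes. Band power is then the Welch PSD of the
band signal integrated over the band range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps

from .channels import FRONTAL_CHANNELS
from .core import Epoch

__all__ = [
    "BandDefinition",
    "BANDS",
    "wpd_band_signal",
    "welch_band_power",
    "power_ratio_features",
    "SPECTRAL_FEATURE_NAMES",
]

SPECTRAL_FEATURE_NAMES = ("beta_theta", "beta_alpha", "beta_alphatheta")


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float


#: The three classical EEG bands used for the power-ratio features.
BANDS = {
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
}


def _band_nodes(fs: float, band: BandDefinition, levels: int) -> list[int]:
    """Frequency-ordered terminal-node indices overlapping >= 50% with band."""
    n_nodes = 2**levels
    width = (fs / 2) / n_nodes
    nodes = []
    for k in range(n_nodes):
        lo_k, hi_k = k * width, (k + 1) * width
        overlap = min(hi_k, band.hi) - max(lo_k, band.lo)
        if overlap >= 0.5 * width:
            nodes.append(k)
    return nodes


def wpd_band_signal(
    x: np.ndarray,
    fs: float,
    band: BandDefinition,
    levels: int = 7,
    wavelet: str = "sym16",
) -> np.ndarray:
    """Reconstruct the ``band`` oscillation from the level-``levels`` wavelet
    packet nodes whose frequency tiles overlap it. Output length = input length."""
    x = np.asarray(x, dtype=np.float64).ravel()
    if band.hi > fs / 2:
        raise ValueError(f"band {band.name} ({band.lo}-{band.hi} Hz) exceeds Nyquist {fs / 2} Hz")
    if len(x) < 2**levels:
        raise ValueError(f"series length {len(x)} < 2^{levels}")
    wp = pywt.WaveletPacket(x, wavelet=wavelet, mode="symmetric", maxlevel=levels)
    leaf_paths = [node.path for node in wp.get_level(levels, order="freq")]
    keep = {leaf_paths[k] for k in _band_nodes(fs, band, levels)}

    out = pywt.WaveletPacket(None, wavelet=wavelet, mode="symmetric", maxlevel=levels)
    for path in keep:
        out[path] = wp[path].data
    y = out.reconstruct(update=False)
    return np.asarray(y)[: len(x)]


def welch_band_power(
    x: np.ndarray,
    fs: float,
    band: BandDefinition,
    seg_seconds: float = 1.0,
) -> float:
    """Band power (uV^2) from a Welch PSD with Hamming windows of
    ``seg_seconds`` and 50% overlap, integrated over [lo, hi)."""
    x = np.asarray(x, dtype=np.float64).ravel()
    nperseg = int(round(seg_seconds * fs))
    if len(x) < nperseg:
        raise ValueError(f"series length {len(x)} shorter than one Welch segment ({nperseg})")
    f, psd = sps.welch(x, fs=fs, window="hamming", nperseg=nperseg, noverlap=nperseg // 2)
    mask = (f >= band.lo) & (f < band.hi)
    df = f[1] - f[0]
    return float(np.sum(psd[mask]) * df)


def power_ratio_features(
    epoch: Epoch,
    channels: tuple[str, ...] | list[str] | None = None,
    levels: int = 7,
    wavelet: str = "sym16",
    method: str = "wpd",
) -> dict[str, float]:
    """Three power-ratio features per channel: beta/theta, beta/alpha,
    beta/(alpha+theta).

    ``method="wpd"`` (default) measures Welch power on the wavelet-packet
    band reconstruction; ``method="raw"`` integrates the raw epoch's Welch
    PSD over the band ranges directly. A zero denominator flags the epoch
    invalid (NaN ratios).

    Returns ``{"<channel>.<feature>": value}`` (13 channels -> 39 values).
    """
    if method not in ("wpd", "raw"):
        raise ValueError("method must be 'wpd' or 'raw'")
    channels = tuple(channels) if channels is not None else FRONTAL_CHANNELS
    missing = [c for c in channels if c not in epoch.channel_labels]
    if missing:
        raise ValueError(f"channels {missing} not in epoch")

    feats: dict[str, float] = {}
    for ch in channels:
        x = epoch.channel(ch)
        power = {}
        for key, band in BANDS.items():
            y = wpd_band_signal(x, epoch.fs, band, levels, wavelet) if method == "wpd" else x
            power[key] = welch_band_power(y, epoch.fs, band)
        th, al, be = power["theta"], power["alpha"], power["beta"]
        feats[f"{ch}.beta_theta"] = be / th if th > 0 else float("nan")
        feats[f"{ch}.beta_alpha"] = be / al if al > 0 else float("nan")
        denom = al + th
        feats[f"{ch}.beta_alphatheta"] = be / denom if denom > 0 else float("nan")
    return feats
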