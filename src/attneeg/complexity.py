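"""Single-scale and multiscale complexity estimators: ApEn, SampEn, FuzzyEn,
coarse-graining, MSE/MFE curves and their scale-1-10 area indices.

All three single-scale estimators embed the series into overlapping
``m``-length vectors and compare them under the Chebyshev (maximum absolute
coordinate difference) distance at tolerance ``r`` = ``r_factor`` x SD of the
series:

* ApEn counts matches *including* the self-match, over all ``N - m + 1``
  templates, and returns ``phi_m - phi_{m+1}`` where ``phi`` is the mean log
  match fraction.
* SampEn excludes self-matches, uses ``N - m`` templates at both lengths,
  and returns ``ln(phi_m / phi_{m+1})`` — equivalently ``-ln(A/B)`` on the
  total match counts.
* FuzzyEn removes each vector's own mean (baseline removal), replaces the
  hard threshold by the membership ``exp(-d^n / r)``, and returns
  ``ln(phi_m) - ln(phi_{m+1})``. The series is standardized to unit SD
  before embedding, so distances are in SD units and the exponential
  membership — whose argument is not homogeneous in amplitude for n != 1 —
  becomes amplitude-invariant, consistent with the SD-relative tolerance of
  the two hard-threshold estimators.

Multiscale curves evaluate SampEn (MSE) or FuzzyEn (MFE) on non-overlapping
block averages at scales tau = 1..s, with the tolerance held fixed at the
scale-1 value. The curve area over scales 1-10 (trapezoidal) gives the
scalar indices MSEI and MFEI.

Matches are counted with closed balls (``d <= r``); for continuous data this
coincides with the strict inequality almost surely, and for constant series
the estimators return 0 by the all-vectors-identical limit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from functools import lru_cache

from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import pdist

from .channels import FRONTAL_CHANNELS
from .config import DEFAULT_ENTROPY_PARAMS, EntropyParams
from .core import Epoch

log = logging.getLogger(__name__)

__all__ = [
    "apen",
    "sampen",
    "fuzzyen",
    "coarse_grain",
    "multiscale_curve",
    "curve_area_index",
    "complexity_features",
    "MultiscaleCurve",
    "COMPLEXITY_FEATURE_NAMES",
]

COMPLEXITY_FEATURE_NAMES = ("apen", "sampen", "fuzzyen", "msei", "mfei")


@lru_cache(maxsize=4)
def _triu_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def _check_series(x: np.ndarray, m: int) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64).ravel()
    if len(x) < m + 2:
        raise ValueError(f"series length {len(x)} too short for m={m}")
    return x


def _resolve_r(x: np.ndarray, params: EntropyParams, r: float | None) -> float:
    """Absolute tolerance: explicit ``r`` wins, else r_factor x SD(x)."""
    if r is not None:
        if r <= 0:
            raise ValueError("tolerance r must be > 0")
        return float(r)
    return float(params.r_factor * x.std())


def apen(x: np.ndarray, params: EntropyParams | None = None, r: float | None = None) -> float:
    """Approximate entropy (nats); self-matches included."""
    params = params or DEFAULT_ENTROPY_PARAMS["apen"]
    m = params.m
    x = _check_series(x, m)
    if x.std() == 0 and r is None:
        return 0.0  # all templates identical: phi_m == phi_{m+1}
    rv = _resolve_r(x, params, r)

    # phi_m over the n1 = N-m+1 length-m templates; phi_{m+1} over the first
    # n1-1 rows extended by one coordinate, so its pair matches are the
    # length-m matches restricted to those rows AND matching on the extra
    # coordinate |x[i+m] - x[j+m]|. One multi-column pdist serves both.
    emb = sliding_window_view(x, m)  # (n1, m)
    n1 = len(emb)
    rows, cols = _triu_indices(n1)
    match_m = pdist(emb, "chebyshev") <= rv

    def phi(mask: np.ndarray, n: int) -> float:
        counts = np.bincount(rows[mask], minlength=n1)[:n] + np.bincount(cols[mask], minlength=n1)[:n]
        counts += 1  # self-match i == j
        return float(np.mean(np.log(counts / n)))

    last = pdist(x[m:, None], "cityblock") <= rv  # pairs over the first n1-1 rows
    inner = cols < n1 - 1
    match_m1 = np.zeros_like(match_m)
    match_m1[inner] = match_m[inner] & last
    return phi(match_m, n1) - phi(match_m1, n1 - 1)


def sampen(x: np.ndarray, params: EntropyParams | None = None, r: float | None = None) -> float:
    """Sample entropy (nats); self-matches excluded, ``N - m`` templates.

    Returns NaN (with a log record) when no template pair matches at length
    ``m + 1``, i.e. the statistic is undefined — never a silent zero.
    """
    params = params or DEFAULT_ENTROPY_PARAMS["sampen"]
    m = params.m
    x = _check_series(x, m)
    if x.std() == 0 and r is None:
        return 0.0
    rv = _resolve_r(x, params, r)

    n_templ = len(x) - m
    # Unordered template pairs (i < j) within tolerance, Chebyshev metric.
    # Both template lengths share the same n_templ rows, so the (m+1)-length
    # distance is the max of the m-length distance and the last-coordinate
    # difference |x[i+m] - x[j+m]| — one condensed pdist covers both counts.
    emb = sliding_window_view(x, m)[:n_templ]
    match_m = pdist(emb, "chebyshev") <= rv
    last = pdist(x[m : m + n_templ, None], "cityblock") <= rv
    b = float(np.count_nonzero(match_m))
    a = float(np.count_nonzero(match_m & last))
    if a == 0 or b == 0:
        log.warning("SampEn undefined (no matches at m+1): N=%d, r=%.4g", len(x), rv)
        return float("nan")
    return float(np.log(b / a))


def _fuzzy_phi(x: np.ndarray, mm: int, n_templ: int, r: float, n: float) -> float:
    """Mean fuzzy similarity over ``n_templ`` baseline-removed vectors."""
    v = sliding_window_view(x, mm)[:n_templ]
    v = v - v.mean(axis=1, keepdims=True)
    d = pdist(v, "chebyshev")  # condensed upper triangle, i < j
    if n == 2.0:
        d *= d
    elif n != 1.0:
        np.power(d, n, out=d)
    d /= -r
    np.exp(d, out=d)  # similarity A_ij
    # A is symmetric with unit diagonal; Eq. sum excludes j == i
    return float(2.0 * d.sum() / (n_templ * (n_templ - 1)))


def fuzzyen(x: np.ndarray, params: EntropyParams | None = None, r: float | None = None) -> float:
    """Fuzzy entropy (nats): exponential membership on baseline-removed,
    SD-standardized vectors.

    When ``r`` is given explicitly the series is used as-is (the multiscale
    path standardizes once by the scale-1 SD and passes ``r = r_factor``).
    """
    params = params or DEFAULT_ENTROPY_PARAMS["fuzzyen"]
    m = params.m
    x = _check_series(x, m)
    if r is None:
        sd = x.std()
        if sd == 0:
            return 0.0  # baseline-removed vectors all zero: A_ij == 1 at both lengths
        x = x / sd
        rv = float(params.r_factor)
    else:
        if r <= 0:
            raise ValueError("tolerance r must be > 0")
        rv = float(r)
    n_templ = len(x) - m
    phi_m = _fuzzy_phi(x, m, n_templ, rv, params.n)
    phi_m1 = _fuzzy_phi(x, m + 1, n_templ, rv, params.n)
    return float(np.log(phi_m) - np.log(phi_m1))


def coarse_grain(x: np.ndarray, tau: int) -> np.ndarray:
    """Non-overlapping block averages at scale ``tau`` (trailing partial
    block discarded); ``tau = 1`` is the identity."""
    x = np.asarray(x, dtype=np.float64).ravel()
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if tau > len(x):
        raise ValueError(f"tau={tau} exceeds series length {len(x)}")
    n_blocks = len(x) // tau
    if tau == 1:
        return x.copy()
    return x[: n_blocks * tau].reshape(n_blocks, tau).mean(axis=1)


@dataclass
class MultiscaleCurve:
    """Entropy per coarse-graining scale; NaN at scales where the estimator
    was undefined (listed in ``undefined_scales``)."""

    scales: tuple[int, ...]
    values: np.ndarray
    estimator: str  # "MSE" | "MFE"
    undefined_scales: tuple[int, ...] = field(default_factory=tuple)
    r_value: float = 0.0


def multiscale_curve(
    x: np.ndarray,
    params: EntropyParams | None = None,
    estimator: str = "sampen",
) -> MultiscaleCurve:
    """MSE (``estimator="sampen"``) or MFE (``"fuzzyen"``) curve.

    The tolerance is fixed once from the SD of the original (scale-1) series
    and reused at every scale. Scales whose coarse-grained series is shorter
    than ``m + 2``, or where SampEn finds no matches, are flagged undefined.
    """
    if estimator not in ("sampen", "fuzzyen"):
        raise ValueError("estimator must be 'sampen' or 'fuzzyen'")
    params = params or DEFAULT_ENTROPY_PARAMS["mse" if estimator == "sampen" else "mfe"]
    x = np.asarray(x, dtype=np.float64).ravel()
    est = sampen if estimator == "sampen" else fuzzyen
    if estimator == "fuzzyen":
        # standardize once by the scale-1 SD; tolerance then lives in SD units
        sd = x.std()
        if sd > 0:
            x = x / sd
        r_abs = float(params.r_factor) if sd > 0 else 0.0
    else:
        r_abs = float(params.r_factor * x.std())

    values = np.full(len(params.scales), np.nan)
    undefined: list[int] = []
    for i, tau in enumerate(params.scales):
        y = coarse_grain(x, tau)
        if len(y) < params.m + 2:
            log.warning("scale %d: coarse series too short (N=%d); undefined", tau, len(y))
            undefined.append(tau)
            continue
        if len(y) < 10 * (params.m + 2):
            log.debug("scale %d: low-N estimate (N=%d)", tau, len(y))
        if r_abs == 0:
            values[i] = 0.0
            continue
        v = est(y, params, r=r_abs)
        if np.isnan(v):
            undefined.append(tau)
        else:
            values[i] = v
    return MultiscaleCurve(
        scales=params.scales,
        values=values,
        estimator="MSE" if estimator == "sampen" else "MFE",
        undefined_scales=tuple(undefined),
        r_value=r_abs,
    )


def curve_area_index(curve: MultiscaleCurve, lo: int = 1, hi: int = 10) -> float:
    """Trapezoidal area under the curve over scales ``lo``..``hi`` (nats x scale).

    Every scale in the range must be present and defined; undefined values
    raise rather than being silently interpolated.
    """
    wanted = [tau for tau in range(lo, hi + 1) if tau in curve.scales]
    if [tau for tau in range(lo, hi + 1)] != wanted:
        missing = sorted(set(range(lo, hi + 1)) - set(curve.scales))
        raise ValueError(f"scales {missing} absent from curve")
    idx = [curve.scales.index(tau) for tau in wanted]
    vals = curve.values[idx]
    if np.any(np.isnan(vals)):
        bad = [tau for tau, v in zip(wanted, vals) if np.isnan(v)]
        raise ValueError(f"curve undefined at scales {bad} inside [{lo}, {hi}]")
    return float(np.trapezoid(vals, np.asarray(wanted, dtype=float)))


def complexity_features(
    epoch: Epoch,
    channels: tuple[str, ...] | list[str] | None = None,
    params: dict[str, EntropyParams] | None = None,
    index_range: tuple[int, int] = (1, 10),
    return_curves: bool = False,
):
    """Five complexity features per channel: apen, sampen, fuzzyen, msei, mfei.

    Defaults follow the analysis parameter sets (ApEn m=2 r=0.2; SampEn m=2
    r=0.15; FuzzyEn m=2 r=0.15 n=2; multiscale curves over the configured
    scales with the area index on scales 1-10). When the single-scale
    parameters match the multiscale ones (the default), SampEn and FuzzyEn
    are read off the scale-1 curve point, which is bit-identical to the
    direct call. Undefined estimates propagate as NaN.

    Returns a flat ``{"<channel>.<feature>": value}`` dict (13 frontal
    channels -> 65 values), plus the per-channel curves if requested.
    """
    channels = tuple(channels) if channels is not None else FRONTAL_CHANNELS
    p = dict(DEFAULT_ENTROPY_PARAMS)
    if params:
        p.update(params)
    missing = [c for c in channels if c not in epoch.channel_labels]
    if missing:
        raise ValueError(f"channels {missing} not in epoch")

    feats: dict[str, float] = {}
    curves: dict[str, dict[str, MultiscaleCurve]] = {}
    for ch in channels:
        x = epoch.channel(ch)
        mse = multiscale_curve(x, p["mse"], "sampen")
        mfe = multiscale_curve(x, p["mfe"], "fuzzyen")

        if (p["sampen"].m, p["sampen"].r_factor) == (p["mse"].m, p["mse"].r_factor):
            se = float(mse.values[mse.scales.index(1)]) if 1 in mse.scales else sampen(x, p["sampen"])
        else:
            se = sampen(x, p["sampen"])
        fkey = (p["fuzzyen"].m, p["fuzzyen"].r_factor, p["fuzzyen"].n)
        if fkey == (p["mfe"].m, p["mfe"].r_factor, p["mfe"].n):
            fe = float(mfe.values[mfe.scales.index(1)]) if 1 in mfe.scales else fuzzyen(x, p["fuzzyen"])
        else:
            fe = fuzzyen(x, p["fuzzyen"])

        try:
            msei = curve_area_index(mse, *index_range)
        except ValueError:
            msei = float("nan")
        try:
            mfei = curve_area_index(mfe, *index_range)
        except ValueError:
            mfei = float("nan")

        feats[f"{ch}.apen"] = apen(x, p["apen"])
        feats[f"{ch}.sampen"] = se
        feats[f"{ch}.fuzzyen"] = fe
        feats[f"{ch}.msei"] = msei
        feats[f"{ch}.mfei"] = mfei
        if return_curves:
            curves[ch] = {"MSE": mse, "MFE": mfe}

    return (feats, curves) if return_curves else feats
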