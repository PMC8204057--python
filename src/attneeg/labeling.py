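"""Behavioral labeling: calibrated response times and alpha-quantile
attention levels.

Absolute reaction time differs between people, so per-subject calibration
(C-RT = RT minus the subject's mean RT) removes the between-subject speed
offset before trials are compared. Attention levels are then symmetric
quantile cuts of the C-RT distribution within each subject: the fastest
``alpha`` fraction of surviving trials is labeled high attention (HA), the
slowest ``alpha`` fraction low attention (LA), and the remainder medium
attention (MA).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class LabelingError(ValueError):
    pass


def calibrate_rt(trials: pd.DataFrame) -> pd.DataFrame:
    """Add a ``crt`` column: RT centered on the subject's mean valid RT."""
    rt = trials["rt_ms"]
    valid = rt.notna()
    if valid.sum() < 2:
        raise LabelingError("need at least 2 trials with a valid reaction time")
    out = trials.copy()
    out["crt"] = rt - rt[valid].mean()
    return out


def remove_rt_outliers(trials: pd.DataFrame, k_sd: float = 3.0) -> pd.DataFrame:
    """Drop trials with |C-RT| beyond ``k_sd`` SDs, in a single pass.

    Trials without a C-RT (no response) are dropped as well.
    """
    if "crt" not in trials:
        raise LabelingError("calibrate_rt must run before outlier removal")
    crt = trials["crt"]
    sd = crt.std(ddof=1)
    keep = crt.notna() & (crt.abs() <= k_sd * sd)
    return trials[keep].reset_index(drop=True)


def assign_attention_levels(trials: pd.DataFrame, alpha: float = 0.25) -> pd.DataFrame:
    """Label surviving trials HA / MA / LA by symmetric ``alpha`` quantiles.

    The shortest ``round(alpha * n)`` C-RTs become HA and the longest become
    LA. Ties at a quantile boundary are broken by trial order: the earlier
    trial receives the more extreme label.
    """
    if not (0 < alpha < 0.5):
        raise ValueError("alpha must be in (0, 0.5)")
    if "crt" not in trials:
        raise LabelingError("calibrate_rt must run before labeling")
    out = trials.copy().reset_index(drop=True)
    n = len(out)
    n_tail = int(round(alpha * n))
    order_fast = np.lexsort((out["trial_idx"].to_numpy(), out["crt"].to_numpy()))
    order_slow = np.lexsort((out["trial_idx"].to_numpy(), -out["crt"].to_numpy()))
    labels = np.full(n, "MA", dtype=object)
    ha = order_fast[:n_tail]
    labels[ha] = "HA"
    # fully tied C-RTs could select an HA trial from the slow end too;
    # LA takes the earliest not already claimed
    la = [i for i in order_slow if labels[i] != "HA"][:n_tail]
    labels[la] = "LA"
    out["label"] = labels.astype(str)
    return out


def label_trials(
    trials: pd.DataFrame, alpha: float = 0.25, k_sd: float = 3.0
) -> pd.DataFrame:
    """Full behavioral labeling chain: calibrate -> de-outlier -> quantile cut."""
    return assign_attention_levels(remove_rt_outliers(calibrate_rt(trials), k_sd), alpha)
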