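"""Electrode layout used throughout the pipeline.

A 32-channel 10-10 cap plus two bipolar EOG leads. The 13-channel frontal
group is the region the classifier and the dynamics analysis operate on.
"""

from __future__ import annotations

#: 32 scalp electrodes, cap order.
EEG_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "AF3", "AF4", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "PO3", "PO4", "O1", "Oz", "O2",
)

#: Two ocular leads (one supra-orbital, one canthal).
EOG_CHANNELS: tuple[str, ...] = ("EOG1", "EOG2")

ALL_CHANNELS: tuple[str, ...] = EEG_CHANNELS + EOG_CHANNELS

#: Frontal electrode group: the region carrying the attention effect.
FRONTAL_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "AF3", "AF4", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
)

# Effect-size scaling per electrode group: frontal electrodes carry the full
# attention-related irregularity effect, everything else half.
_EFFECT_SCALE = {name: 1.0 for name in FRONTAL_CHANNELS}
_EFFECT_SCALE.update({name: 0.5 for name in EEG_CHANNELS if name not in FRONTAL_CHANNELS})

# Blink propagation gain: strongest at the fronto-polar sites, decaying
# toward the back of the head; EOG leads see the blink at full amplitude.
_BLINK_GAIN = {
    "Fp1": 0.60, "Fp2": 0.60, "AF3": 0.45, "AF4": 0.45,
    "F7": 0.28, "F3": 0.28, "Fz": 0.28, "F4": 0.28, "F8": 0.28,
    "FC5": 0.15, "FC1": 0.15, "FC2": 0.15, "FC6": 0.15,
    "EOG1": 1.0, "EOG2": 0.9,
}


def effect_scale(name: str) -> float:
    """Fraction of the attention effect expressed at electrode ``name``."""
    return _EFFECT_SCALE.get(name, 0.0)


def blink_gain(name: str) -> float:
    """Blink-artifact gain at electrode ``name`` relative to the EOG."""
    return _BLINK_GAIN.get(name, 0.05)


def channel_role(name: str) -> str:
    return "EOG" if name in EOG_CHANNELS else "EEG"
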