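"""Configuration dataclasses for simulation, entropy estimation and pipeline runs.

All configs round-trip through YAML unchanged (``to_yaml`` / ``from_yaml``),
so a single file fully determines a pipeline run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Optional, Sequence

import yaml


@dataclass
class SimulationConfig:
    """Parameters of the synthetic AX-CPT cohort generator.

    The defaults are the recorded study conditions: 192-trial sessions with
    144 AX sequences, 1000 Hz sampling, 3-s epochs and a 3-minute resting
    block. ``entropy_effect`` is the separation (in within-class SD units of
    the latent drive) between the irregularity of high/medium/low attention
    and resting EEG; ``rt_attention_slope`` couples the latent attention state
    to log reaction time (negative: attentive = fast).
    """

    n_subjects: int = 10
    n_trials: int = 192
    n_ax_trials: int = 144
    fs: float = 1000.0
    epoch_len: float = 3.0
    rest_minutes: float = 3.0
    attention_ar_coeff: float = 0.9
    rt_lognormal_sigma: float = 0.2
    rt_attention_slope: float = -0.6
    rt_subject_sigma: float = 0.15
    entropy_effect: float = 1.0
    frontal_only_effect: bool = False
    line_noise_amp: float = 1.0
    blink_rate: float = 12.0
    label_alpha: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials <= 0 or self.n_subjects <= 0:
            raise ValueError("counts must be positive")
        if self.n_ax_trials > self.n_trials or self.n_ax_trials < 0:
            raise ValueError("n_ax_trials must be in [0, n_trials]")
        if self.fs <= 2 * 70.0:
            raise ValueError("fs must exceed twice the 70 Hz band edge")
        if self.epoch_len <= 0 or self.rest_minutes < 0:
            raise ValueError("durations must be positive")
        if not (0 <= self.attention_ar_coeff < 1):
            raise ValueError("attention_ar_coeff must be in [0, 1)")
        if self.entropy_effect < 0:
            raise ValueError("entropy_effect must be >= 0")
        if not (0 < self.label_alpha < 0.5):
            raise ValueError("label_alpha must be in (0, 0.5)")


@dataclass
class EntropyParams:
    """Parameters of one entropy estimator.

    m : embedding dimension; r_factor : tolerance as a fraction of the series
    SD; n : fuzzy membership exponent (FuzzyEn only); scales : coarse-graining
    factors for the multiscale curve.
    """

    m: int = 2
    r_factor: float = 0.15
    n: float = 2.0
    scales: tuple[int, ...] = tuple(range(1, 51))

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r_factor <= 0:
            raise ValueError("r_factor must be > 0")
        if self.n <= 0:
            raise ValueError("n must be > 0")
        self.scales = tuple(int(s) for s in self.scales)
        if any(s < 1 or s > 50 for s in self.scales):
            raise ValueError("scales must lie in 1..50")
        if any(b <= a for a, b in zip(self.scales, self.scales[1:])):
            raise ValueError("scales must be strictly increasing")


#: Estimator parameter sets used for feature extraction.
DEFAULT_ENTROPY_PARAMS = {
    "apen": EntropyParams(m=2, r_factor=0.2, scales=(1,)),
    "sampen": EntropyParams(m=2, r_factor=0.15, scales=(1,)),
    "fuzzyen": EntropyParams(m=2, r_factor=0.15, n=2.0, scales=(1,)),
    "mse": EntropyParams(m=2, r_factor=0.15),
    "mfe": EntropyParams(m=2, r_factor=0.15, n=2.0),
}


@dataclass
class PipelineConfig:
    """End-to-end run configuration (simulate -> ... -> stats)."""

    out_dir: str = "attneeg_run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    notch_hz: float = 50.0
    bandpass: tuple[float, float] = (0.3, 70.0)
    run_ica: bool = True
    ica_components: int = 30
    eog_reject_threshold: float = 0.7
    alpha: float = 0.25
    rt_outlier_sd: float = 3.0
    featureset: str = "complexity"  # complexity | classical | combined
    mse_scales: tuple[int, ...] = tuple(range(1, 51))
    index_scale_range: tuple[int, int] = (1, 10)
    cv_schemes: tuple[str, ...] = ("kfold", "loocv")
    tasks: tuple[str, ...] = ("4level", "3level", "2level")
    model: str = "gbt"
    tune: bool = True
    seed: int = 0

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], dict):
            d["simulation"] = SimulationConfig(**d["simulation"])
        for key in ("bandpass", "mse_scales", "index_scale_range", "cv_schemes", "tasks"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
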