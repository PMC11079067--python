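"""Configuration objects for the simulator and pipeline.

All defaults are the study conditions the package simulates: a 127-patient
vestibular-schwannoma cohort monitored with binaural click-evoked BAEPs
(11.9 Hz stimulation, 2000-sweep averages, so one averaged epoch every
~168 s per ear), a 66.1% preoperative hearing-preservation rate, and
sub-microvolt wave amplitudes (0.1-0.5 uV) that make the raw recording highly
susceptible to session-wide interference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from .features import WAVES


class ConfigError(ValueError):
    """Invalid configuration value."""


#: canonical adult reference latencies, ms
DEFAULT_REFERENCE_LATENCIES = {"i": 1.7, "ii": 2.8, "iii": 3.9, "iv": 5.1, "v": 5.7}

#: reference peak-to-trough amplitudes, uV (BAEP amplitudes run 0.1-0.5 uV)
DEFAULT_REFERENCE_AMPLITUDES = {"i": 0.20, "v": 0.30}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic binaural-BAEP cohort generator."""

    n_patients: int = 127
    seed: int = 0
    surgery_duration: float = 240.0          # minutes
    epoch_interval: float = 168.0            # seconds; 2000 sweeps / 11.9 Hz
    inter_ear_offset: float = 60.0           # seconds between the two ears' epochs
    epoch_dropout: float = 0.04              # per-epoch probability of a lost average
    reference_latencies: dict = field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_LATENCIES))
    reference_amplitudes: dict = field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_AMPLITUDES))
    injury_effect_latency: float = 1.0       # ms of wave-V delay per unit dysfunction
    injury_effect_amplitude: float = 0.8     # fractional wave-V amplitude loss per unit
    common_mode_sd: float = 0.7              # stationary sd of shared log-amplitude drift
    common_mode_latency_sd: float = 0.02     # stationary sd of shared log-latency drift
    common_mode_tau: float = 60.0            # drift correlation time, minutes
    measurement_noise_sd: float = 0.15       # per-epoch log-amplitude noise sd
    latency_noise_frac: float = 0.1          # latency noise = this fraction of amplitude noise
    wave_loss_threshold: float = 0.05        # uV; below this a wave is reported absent
    baseline_latency_sd: float = 0.015       # per-ear fractional baseline spread
    baseline_amplitude_sd: float = 0.15      # per-ear log baseline spread
    hp_link_slope: float = 8.0               # logistic slope of cochlear function -> WRS
    hp_link_intercept: float = 0.45          # logistic midpoint (cochlear function units)
    wrs_max: float = 90.0                    # % at full cochlear function
    pta_min: float = 10.0                    # dB at full cochlear function
    pta_max: float = 100.0                   # dB at zero cochlear function
    audiometry_noise_sd: float = 1.0         # dB / percentage-point measurement noise
    p_preop_hp: float = 0.661                # target preoperative HP probability
    p_postop_hp_given_pre: float = 0.452     # P(postop HP | preop HP)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.epoch_interval <= 0:
            raise ConfigError("epoch_interval must be > 0")
        if self.surgery_duration <= 0:
            raise ConfigError("surgery_duration must be > 0")
        if not 0.0 <= self.p_preop_hp <= 1.0:
            raise ConfigError("p_preop_hp must lie in [0, 1]")
        if not 0.0 <= self.p_postop_hp_given_pre <= 1.0:
            raise ConfigError("p_postop_hp_given_pre must lie in [0, 1]")
        if not 0.0 <= self.epoch_dropout < 1.0:
            raise ConfigError("epoch_dropout must lie in [0, 1)")
        for name in ("injury_effect_latency", "injury_effect_amplitude",
                     "common_mode_sd", "common_mode_latency_sd",
                     "measurement_noise_sd", "audiometry_noise_sd",
                     "baseline_latency_sd", "baseline_amplitude_sd",
                     "wave_loss_threshold"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        missing = [w for w in WAVES if w not in self.reference_latencies]
        if missing:
            raise ConfigError(f"reference_latencies missing waves {missing}")
        lats = [self.reference_latencies[w] for w in WAVES]
        if not all(a < b for a, b in zip(lats, lats[1:])):
            raise ConfigError("reference latencies must increase in wave order I<II<III<IV<V")
        if any(v <= 0 for v in self.reference_amplitudes.values()):
            raise ConfigError("reference amplitudes must be positive")


@dataclass
class StandardizationConfig:
    """Options of the healthy-side standardization stage.

    ``normal_reference`` maps indicator -> constant laboratory normal value;
    it is only needed to report the reference-scaled standardized values
    (reference * (affected/healthy)) - the dimensionless index itself never
    uses it.
    """

    max_interval: float = 180.0          # seconds; pairing tolerance ("<= 3 min")
    summary_method: str = "median"       # phase representative: median | mean
    normal_reference: Optional[dict] = None

    def validate(self) -> None:
        if self.max_interval <= 0:
            raise ConfigError("max_interval must be > 0")
        if self.summary_method not in ("median", "mean"):
            raise ConfigError("summary_method must be 'median' or 'mean'")
        if self.normal_reference is not None:
            bad = {k: v for k, v in self.normal_reference.items() if v <= 0}
            if bad:
                raise ConfigError(f"normal_reference values must be positive: {bad}")


@dataclass
class StatsConfig:
    """Options of the predictor-evaluation battery."""

    alpha: float = 0.05                  # univariate screening / stepwise stay threshold
    stepwise_direction: str = "backward"

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.stepwise_direction not in ("backward", "forward"):
            raise ConfigError("stepwise_direction must be 'backward' or 'forward'")


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    standardization: StandardizationConfig = field(default_factory=StandardizationConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    output_dir: str = "baepstd_out"
    verbosity: str = "info"

    def validate(self) -> None:
        self.simulation.validate()
        self.standardization.validate()
        self.stats.validate()

    def as_dict(self) -> dict:
        return asdict(self)


def _build(cls, data: dict):
    valid = {f for f in cls.__dataclass_fields__}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def pipeline_config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data)
    sim = _build(SimulationConfig, data.pop("simulation", {}))
    std = _build(StandardizationConfig, data.pop("standardization", {}))
    stats = _build(StatsConfig, data.pop("stats", {}))
    cfg = _build(PipelineConfig,
                 {**data, "simulation": sim, "standardization": std, "stats": stats})
    cfg.validate()
    return cfg


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline configuration from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return pipeline_config_from_dict(data)
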