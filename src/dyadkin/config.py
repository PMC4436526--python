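"""Run configuration: one structured YAML file drives the whole pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class PreprocessConfig:
    """Parameters of the five cleaning steps.

    Defaults follow the measurement protocol: spikes flagged at 3 SD of
    the double-differenced series; bidirectional 4th-order Butterworth at
    15 Hz; 13 degree clockwise in-plane rotation correcting the angled
    board in the video condition; 111 ms video presentation latency; and
    trials defined as index-finger excursions >100 mm from the start point
    lasting >5 s.
    """

    spike_sd_threshold: float = 3.0
    filter_cutoff_hz: float = 15.0
    filter_order: int = 4
    rotation_deg: float = 13.0
    video_latency_s: float = 0.111
    trial_min_displacement_mm: float = 100.0
    trial_min_duration_s: float = 5.0
    max_trials: int = 10

    def validate(self, sample_rate: float) -> "PreprocessConfig":
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be strictly positive")
        if self.filter_cutoff_hz >= sample_rate / 2:
            raise ValueError("filter cutoff must be below the Nyquist frequency")
        return self


@dataclass
class AnalysisConfig:
    """Lag-scan and aggregation parameters.

    ``max_lag_s`` spans the +-5 s scan (+-1200 samples at 240 Hz).
    ``min_overlap_frac`` discards lags whose overlap drops below this
    fraction of the trial length, preventing spurious |r| ~ 1 from tiny
    overlaps.  ``z_before_mean`` Fisher-transforms per-trial r before
    averaging across trials (the standard way to aggregate correlations);
    set false to average r first and transform the mean.
    """

    max_lag_s: float = 5.0
    min_overlap_frac: float = 0.5
    z_before_mean: bool = True


@dataclass
class ScenarioConfig:
    """Behavioral parameters of the simulated dyads per condition.

    Lags are seconds by which the imitator trails the actor; noise is the
    SD in mm of the low-passed coupling noise added to the imitator's
    channels.  Video and complex cells are degraded relative to
    face-to-face/simple, mirroring the direction of the observed effects.
    """

    lag_face_to_face_s: float = 0.65
    lag_video_s: float = 0.80
    lag_complex_extra_s: float = 0.15
    noise_face_to_face_mm: float = 25.0
    noise_video_mm: float = 35.0
    noise_complex_extra_mm: float = 10.0
    gain: float = 1.0
    n_trials: int = 10
    trial_s: float = 20.0
    rest_s: float = 5.0


@dataclass
class RunConfig:
    sample_rate: float = 240.0
    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for key, sub in (
            ("preprocess", PreprocessConfig),
            ("analysis", AnalysisConfig),
            ("scenario", ScenarioConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path
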