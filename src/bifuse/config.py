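"""Run configuration: one nested, YAML-serializable record of every
constant in the pipeline.  The defaults are the study constants: 8-25 Hz
EEG band, 0.01-0.1 Hz fNIRS band, 128 Hz working rate, 3-s windows with
1-s (strategy B) or 3-s (strategy A) steps, early-stopping strip k = 10
with alpha = 0.001, at most 500 epochs, dropout 0.2.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class SyntheticSection:
    n_trials_per_class: int = 30
    trial_length_s: float = 10.0
    eeg_rate_hz: float = 200.0
    fnirs_rate_hz: float = 10.0
    erd_depth: float = 0.5
    hemo_amplitude: float = 0.5
    noise_sd: float = 1.0


@dataclass
class PreprocessSection:
    eeg_band_hz: tuple[float, float] = (8.0, 25.0)
    fnirs_band_hz: tuple[float, float] = (0.01, 0.1)
    target_rate_hz: float = 128.0
    baseline_window_s: tuple[float, float] = (-5.0, -2.0)
    normalize_scope: str = "channel"   # or "trial"
    fnirs_filter_first: bool = True    # filter at 10 Hz before upsampling


@dataclass
class AugmentSection:
    window_s: float = 3.0
    step_a_s: float = 3.0
    step_b_s: float = 1.0
    split: str = "grouped"             # or "per-subtrial"
    test_fraction: float = 0.2


@dataclass
class NetworkSection:
    stage: str = "early"
    concat_axis: str = "depth"
    fnirs_chromophore: str = "hbo"
    f1_temporal_filters: int = 8
    depth_multiplier: int = 2
    temporal_kernel_len: int = 54
    separable_kernel_len: int = 8
    sep_depth_multiplier: int = 2
    pointwise_filters: int = 32
    pool1_len: int = 4
    pool2_len: int = 16
    dropout_p: float = 0.2
    uses_batchnorm: bool = True


@dataclass
class TrainSection:
    max_epochs: int = 500
    learning_rate: float = 1e-3
    batch_size: int = 16
    early_stop_k: int = 10
    early_stop_alpha: float = 0.001


@dataclass
class EvaluateSection:
    tie_rule: str = "probability"
    voting: bool = True


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "results"
    synthetic: SyntheticSection = field(default_factory=SyntheticSection)
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    augment: AugmentSection = field(default_factory=AugmentSection)
    network: NetworkSection = field(default_factory=NetworkSection)
    train: TrainSection = field(default_factory=TrainSection)
    evaluate: EvaluateSection = field(default_factory=EvaluateSection)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        return yaml.safe_dump(plain(self.to_dict()), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sections = {
            "synthetic": SyntheticSection,
            "preprocess": PreprocessSection,
            "augment": AugmentSection,
            "network": NetworkSection,
            "train": TrainSection,
            "evaluate": EvaluateSection,
        }
        kwargs: dict = {}
        for key, value in d.items():
            if key in sections:
                fields = {f.name for f in dataclasses.fields(sections[key])}
                clean = {}
                for k, v in value.items():
                    if k not in fields:
                        raise KeyError(f"unknown config key {key}.{k}")
                    clean[k] = tuple(v) if isinstance(v, list) else v
                kwargs[key] = sections[key](**clean)
            elif key in ("seed", "output_dir"):
                kwargs[key] = value
            else:
                raise KeyError(f"unknown config section {key!r}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text) or {})

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())
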