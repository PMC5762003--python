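"""Run configuration: plain-text (YAML) config with strict key checking."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .network import NetworkSpec
from .preprocess import FRAME_SHAPE, TRAIN_SHAPE

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Top-level run configuration; unknown keys are rejected on load."""

    # paths
    manifest: str = ""
    out_dir: str = "runs/out"
    # network
    variant: str = "sunet"
    depth: int = 4
    channels: int = 64
    dropout_rate: float = 0.5
    dilation_rate: int = 2
    kernel_size: int = 2
    # training
    learning_rate: float = 1e-4
    batch_size: int = 32
    iterations: int = 3000
    label_smoothing: float = 0.1
    l2_weight: float = 1e-5
    augment: bool = True
    target_frame: list = field(default_factory=lambda: list(FRAME_SHAPE))
    train_size: list = field(default_factory=lambda: list(TRAIN_SHAPE))
    # phantom
    n_patients: int = 5
    images_per_patient: int = 3
    jitter_mm: float = 1.6
    # global
    seed: int = 0
    log_level: str = "INFO"

    def network_spec(self) -> NetworkSpec:
        return NetworkSpec(
            variant=self.variant,
            depth=self.depth,
            channels=self.channels,
            dropout_rate=self.dropout_rate,
            dilation_rate=self.dilation_rate,
            kernel_size=self.kernel_size,
        )

    def train_config(self):
        from .training import TrainConfig

        return TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            iterations=self.iterations,
            label_smoothing=self.label_smoothing,
            l2_weight=self.l2_weight,
            seed=self.seed,
            augment=self.augment,
            frame_shape=tuple(self.target_frame),
            train_shape=tuple(self.train_size),
        )


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path):
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))
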