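"""Run configuration: one YAML file binding phantom generation, network
architecture, and training into a reproducible run."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .network import NetworkSpec
from .phantom import PhantomConfig
from .training import TrainConfig


@dataclass
class RunConfig:
    """The union of PhantomConfig, NetworkSpec, and TrainConfig plus the
    output directory and log verbosity; round-trips losslessly through
    YAML."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    out_dir: str = "runs/default"
    verbosity: str = "info"

    def to_dict(self) -> dict:
        return {
            "phantom": self.phantom.to_dict(),
            "network": self.network.to_dict(),
            "train": self.train.to_dict(),
            "out_dir": self.out_dir,
            "verbosity": self.verbosity,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            phantom=PhantomConfig.from_dict(d.get("phantom", {})) if d.get("phantom")
            else PhantomConfig(),
            network=NetworkSpec.from_dict(d.get("network", {})) if d.get("network")
            else NetworkSpec(),
            train=TrainConfig.from_dict(d.get("train", {})) if d.get("train")
            else TrainConfig(),
            out_dir=d.get("out_dir", "runs/default"),
            verbosity=d.get("verbosity", "info"),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
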