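"""Experiment configuration: YAML round-trip and the pipeline constants.

Defaults carry the pipeline's canonical settings: 60% training fraction,
inflated training size N_tilde = 5000, 100 repetitions, merge alpha 0.05.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .evaluate import DEFAULT_ARMS, ArmSpec

__all__ = ["ExperimentConfig"]


@dataclass
class ExperimentConfig:
    cohort_csv: str | None = None  # None: simulate with cohort defaults
    n_children: int = 458
    train_fraction: float = 0.6
    inflated_size: int = 5000
    repetitions: int = 100
    merge_alpha: float = 0.05
    arms: tuple[ArmSpec, ...] = DEFAULT_ARMS
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0,1)")
        if not 0.0 < self.merge_alpha < 1.0:
            raise ValueError("merge_alpha must be in (0,1)")
        if min(self.inflated_size, self.repetitions, self.n_children) <= 0:
            raise ValueError("sizes and repetitions must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["arms"] = [asdict(a) for a in self.arms]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "arms" in d:
            d["arms"] = tuple(ArmSpec(**a) for a in d["arms"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Stable hash of the configuration, stamped into every output.

        The output directory is excluded: where results are written does not
        change what experiment they describe.
        """
        d = self.to_dict()
        d.pop("output_dir", None)
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
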