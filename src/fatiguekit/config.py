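"""Hierarchical run configuration and reproducibility plumbing.

One YAML file with per-stage sections drives the whole pipeline; every
random stage draws its seed deterministically from (global seed, stage
name) so a manifest plus config reproduces any stage bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import hashlib
import json

import yaml

from .gan import GANSpec
from .network import TrainConfig
from .synth import SynthConfig

SCENARIOS: dict[str, tuple[int, ...]] = {
    "two_level": (0, 4),        # Normal vs Complete Fatigue
    "three_level": (0, 2, 4),   # Normal vs Mid Fatigue vs Complete Fatigue
    "five_level": (0, 1, 2, 3, 4),
}


def scenario_levels(name: str) -> tuple[int, ...]:
    if name not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {name!r}; valid scenarios: "
            + ", ".join(f"{k} ({len(v)} classes)" for k, v in SCENARIOS.items()))
    return SCENARIOS[name]


@dataclass
class RunConfig:
    """Everything a full pipeline run needs, with per-stage sections."""

    scenario: str = "five_level"
    channels: tuple[str, ...] = ("P4", "C3", "O1", "O2")
    seed: int = 0
    out_dir: str = "runs/default"
    n_per_class: int = 100
    epoch_len_s: float = 15.0
    activation: str = "t2f"
    target_total: int | None = None
    snr_grid_db: tuple[float, ...] = (-10.0, 0.0, 10.0, 20.0, float("inf"))
    replicates: int = 3
    synth: SynthConfig = field(default_factory=SynthConfig)
    gan: GANSpec = field(default_factory=GANSpec)
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self):
        scenario_levels(self.scenario)

    @property
    def levels(self) -> tuple[int, ...]:
        return scenario_levels(self.scenario)

    @property
    def n_classes(self) -> int:
        return len(self.levels)

    def stage_seed(self, stage: str) -> int:
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31 - 1)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["snr_grid_db"] = [("inf" if v == float("inf") else v)
                            for v in self.snr_grid_db]
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _build_section(cls, data: dict, section: str):
    valid = set(cls.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in section {section!r}; "
            f"valid keys: {sorted(valid)}")
    data = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
    return cls(**data)


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a RunConfig from YAML, applying flat key overrides on top."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update(overrides or {})
    sections = {"synth": SynthConfig, "gan": GANSpec, "train": TrainConfig}
    kwargs: dict = {}
    valid_top = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - valid_top
    if unknown:
        raise ValueError(
            f"unknown top-level config key(s) {sorted(unknown)}; "
            f"valid keys: {sorted(valid_top)}")
    for key, value in data.items():
        if key in sections and isinstance(value, dict):
            kwargs[key] = _build_section(sections[key], value, key)
        elif key == "snr_grid_db":
            kwargs[key] = tuple(float("inf") if v in ("inf", "Infinity")
                                else float(v) for v in value)
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)
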