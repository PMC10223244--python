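"""Run configuration: YAML loading, defaulting, and config digests.

A single :class:`RunConfig` carries every tunable of the pipeline — the
synthetic-generator scale, the pool-training knobs, and the consensus /
sensitivity / pharmacophore thresholds.  Flags given on the command line
override the YAML file, which overrides the defaults.  The digest of the
fully resolved settings is embedded in every output artifact so results can
be traced to the exact configuration that produced them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .ensemble import TrainConfig
from .synthgen import GeneratorConfig


@dataclass
class RunConfig:
    seed: int = 0

    # synthetic generator scale
    n_compounds: int = 216
    n_sites: int = 17
    informative_sites: tuple[int, ...] = (1, 2, 4, 14)
    effect_size: float = 1.5

    # pool training
    hidden_sizes: tuple[int, ...] = tuple(range(3, 18))
    activations: tuple[str, ...] = ("identity", "logistic", "tanh", "exponential")
    n_candidates: int = 200
    max_epochs: int = 400
    learning_rate: float = 0.02
    patience: int = 40
    alpha: float = 0.1

    # consensus & analysis thresholds
    consensus_min_votes: int = 4
    sensitivity_threshold: float | None = None  # None -> round(100 / n_sites)
    min_networks: int = 5
    pharmacophore_min_support: int | None = None  # None -> ceil(0.75 * group)

    def __post_init__(self) -> None:
        if not 4 <= self.consensus_min_votes <= 7:
            raise ValueError("consensus_min_votes must be 4..7 (majority of 7)")
        if not 1 <= self.min_networks <= 7:
            raise ValueError("min_networks must be 1..7")
        if self.sensitivity_threshold is not None and self.sensitivity_threshold <= 0:
            raise ValueError("sensitivity_threshold must be positive")

    def generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(
            n_compounds=self.n_compounds,
            n_sites=self.n_sites,
            informative_sites=tuple(self.informative_sites),
            effect_size=self.effect_size,
            seed=self.seed,
        )

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            hidden_sizes=tuple(self.hidden_sizes),
            activations=tuple(self.activations),
            n_candidates=self.n_candidates,
            max_epochs=self.max_epochs,
            learning_rate=self.learning_rate,
            patience=self.patience,
            alpha=self.alpha,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("informative_sites", "hidden_sizes", "activations"):
            d[key] = list(d[key])
        return d

    def digest(self) -> str:
        """Short hash of the fully resolved settings."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        settings: dict = {}
        if path is not None:
            loaded = yaml.safe_load(Path(path).read_text()) or {}
            if not isinstance(loaded, dict):
                raise ValueError(f"{path}: config must be a YAML mapping")
            unknown = set(loaded) - set(cls.__dataclass_fields__)
            if unknown:
                raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
            settings.update(loaded)
        settings.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("informative_sites", "hidden_sizes", "activations"):
            if key in settings:
                settings[key] = tuple(settings[key])
        return cls(**settings)
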