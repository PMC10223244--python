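"""Pool training and selection of the 3 x 7 network ensemble.

For each of the three binary gradations (``h``, ``hm``, ``a``) and each of
the seven sampling variants, a pool of candidate perceptrons is trained
(enumerating hidden sizes x activation functions with fresh seeds) and a
single best network is selected, giving 21 networks in total.

Selection is a two-stage criterion: when the pool is large, it is first cut
to the top 600 by minimum subset accuracy; then the top 5 by the minimum of
(train, test, validation) accuracy are short-listed, and among those the
network with the highest overall accuracy F0 on the general (full) set wins.
Ties break deterministically: fewer hidden units, then lower seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__ as _pkg_version
from .datasets import TrainingTable
from .evaluation import DomainBounds, fit_applicability_domain
from .mlp import ACTIVATIONS, NetworkSpec, TrainedNetwork, fit_mlp

LEVELS: tuple[str, ...] = ("h", "hm", "a")
N_VARIANTS = 7


@dataclass
class TrainConfig:
    """Knobs of pool training; defaults converge in seconds at the 216 x 17 scale."""

    hidden_sizes: tuple[int, ...] = tuple(range(3, 18))
    activations: tuple[str, ...] = ACTIVATIONS
    n_candidates: int = 200
    max_epochs: int = 400
    learning_rate: float = 0.02
    patience: int = 40
    alpha: float = 0.1  # L2 penalty on weight matrices
    retain_best: int = 600  # pre-cut applied only when the pool exceeds it
    shortlist: int = 5

    def __post_init__(self) -> None:
        unknown = set(self.activations) - set(ACTIVATIONS)
        if unknown:
            raise ValueError(f"unknown activations: {sorted(unknown)}")
        if self.n_candidates < 1:
            raise ValueError("need at least one candidate")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden_sizes"] = list(self.hidden_sizes)
        d["activations"] = list(self.activations)
        return d


def enumerate_specs(config: TrainConfig, n_inputs: int) -> list[NetworkSpec]:
    """Cyclic enumeration of hidden-size x activation specs, ``n_candidates`` long."""
    grid = [
        NetworkSpec(n_inputs=n_inputs, n_hidden=m, hidden_activation=a)
        for m, a in itertools.product(config.hidden_sizes, config.activations)
    ]
    return [grid[i % len(grid)] for i in range(config.n_candidates)]


def _subset_accuracy(net: TrainedNetwork, x: np.ndarray, y: np.ndarray) -> float:
    if len(y) == 0:
        return float("nan")
    return 100.0 * float(np.mean(net.predict(x) == y))


def candidate_seeds(master_seed: int, level: str, variant: int, n: int) -> list[int]:
    """Deterministic per-candidate seeds derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), LEVELS.index(level), int(variant)])
    return [int(s) for s in ss.generate_state(n, dtype=np.uint32)]


def train_candidate(
    spec: NetworkSpec,
    table: TrainingTable,
    level: str,
    variant: int,
    seed: int,
    config: TrainConfig | None = None,
) -> TrainedNetwork:
    """Fit one candidate on the variant's training subset.

    Standardization statistics come from the training rows only; early
    stopping is monitored on the variant's test subset.  All three subset
    accuracies (percent correct) are recorded on the returned network.
    """
    if variant not in range(N_VARIANTS):
        raise ValueError(f"variant must be 0..6, got {variant}")
    config = config or TrainConfig()
    x = table.energies
    y = table.labels(level)
    roles = table.roles(variant)
    tr, te, va = roles == "train", roles == "test", roles == "val"
    net = fit_mlp(
        x[tr], y[tr], spec, seed,
        x_stop=x[te], y_stop=y[te],
        max_epochs=config.max_epochs,
        learning_rate=config.learning_rate,
        patience=config.patience,
        alpha=config.alpha,
    )
    net.level = level
    net.variant = variant
    net.acc_train = _subset_accuracy(net, x[tr], y[tr])
    net.acc_test = _subset_accuracy(net, x[te], y[te])
    net.acc_val = _subset_accuracy(net, x[va], y[va])
    return net


def train_pool(
    table: TrainingTable,
    level: str,
    variant: int,
    config: TrainConfig | None = None,
    master_seed: int = 0,
) -> list[TrainedNetwork]:
    """Train the full candidate pool for one (gradation, variant) cell."""
    config = config or TrainConfig()
    specs = enumerate_specs(config, n_inputs=len(table.site_ids))
    seeds = candidate_seeds(master_seed, level, variant, len(specs))
    return [
        train_candidate(spec, table, level, variant, seed, config)
        for spec, seed in zip(specs, seeds)
    ]


def _general_f0(net: TrainedNetwork, table: TrainingTable) -> float:
    y = table.labels(net.level)
    return 100.0 * float(np.mean(net.predict(table.energies) == y))


def _min_acc(net: TrainedNetwork) -> float:
    accs = [a for a in (net.acc_train, net.acc_test, net.acc_val) if not np.isnan(a)]
    return min(accs) if accs else float("-inf")


def select_best(
    pool: Sequence[TrainedNetwork],
    table: TrainingTable,
    config: TrainConfig | None = None,
) -> TrainedNetwork:
    """Two-stage selection: shortlist by worst subset accuracy, decide by
    general-set F0; deterministic tie-breaks (fewer hidden units, lower seed)."""
    pool = list(pool)
    if not pool:
        raise ValueError("empty candidate pool")
    config = config or TrainConfig()

    def subset_key(net: TrainedNetwork):
        return (-_min_acc(net), net.spec.n_hidden, net.seed)

    if len(pool) > config.retain_best:
        pool = sorted(pool, key=subset_key)[: config.retain_best]
    shortlist = sorted(pool, key=subset_key)[: config.shortlist]
    return min(shortlist, key=lambda n: (-_general_f0(n, table), n.spec.n_hidden, n.seed))


@dataclass
class EnsembleModel:
    """21 selected networks (3 gradations x 7 variants) plus their domain."""

    networks: dict[tuple[str, int], TrainedNetwork]
    site_ids: list[str]
    domain: DomainBounds
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = {(lv, v) for lv in LEVELS for v in range(N_VARIANTS)}
        if set(self.networks) != expected:
            missing = sorted(expected - set(self.networks))
            raise ValueError(f"ensemble grid incomplete; missing cells {missing}")

    @property
    def levels(self) -> tuple[str, ...]:
        return LEVELS

    def level_networks(self, level: str) -> list[TrainedNetwork]:
        return [self.networks[(level, v)] for v in range(N_VARIANTS)]

    def save(self, path: str | Path) -> None:
        doc = {
            "format": "mtqsar-ensemble",
            "schema_version": 1,
            "tool_version": _pkg_version,
            "site_ids": self.site_ids,
            "domain": self.domain.to_dict(),
            "provenance": self.provenance,
            "networks": {
                f"{lv}:{v}": self.networks[(lv, v)].to_dict()
                for lv in LEVELS
                for v in range(N_VARIANTS)
            },
        }
        Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "EnsembleModel":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != "mtqsar-ensemble":
            raise ValueError(f"{path}: not an ensemble model file")
        networks = {}
        for key, nd in doc["networks"].items():
            lv, v = key.split(":")
            networks[(lv, int(v))] = TrainedNetwork.from_dict(nd)
        return cls(
            networks=networks,
            site_ids=list(doc["site_ids"]),
            domain=DomainBounds.from_dict(doc["domain"]),
            provenance=doc.get("provenance", {}),
        )


def train_level_ensemble(
    table: TrainingTable,
    level: str,
    config: TrainConfig | None = None,
    master_seed: int = 0,
) -> list[TrainedNetwork]:
    """The seven selected networks of one gradation (one pool per variant)."""
    config = config or TrainConfig()
    return [
        select_best(train_pool(table, level, v, config, master_seed), table, config)
        for v in range(N_VARIANTS)
    ]


def build_ensemble(
    table: TrainingTable,
    config: TrainConfig | None = None,
    master_seed: int = 0,
) -> EnsembleModel:
    """Train pools and select one network per (gradation, variant) cell;
    fit and attach the three-sigma applicability domain."""
    config = config or TrainConfig()
    selected: dict[tuple[str, int], TrainedNetwork] = {}
    for lv in LEVELS:
        for net in train_level_ensemble(table, lv, config, master_seed):
            selected[(lv, net.variant)] = net
    domain = fit_applicability_domain(table.energies, table.site_ids)
    provenance = {
        "master_seed": int(master_seed),
        "config": config.to_dict(),
        "n_compounds": len(table),
    }
    return EnsembleModel(
        networks=selected, site_ids=list(table.site_ids), domain=domain,
        provenance=provenance,
    )
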