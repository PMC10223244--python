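"""Shared fixtures: synthetic tables, a small trained ensemble, stub networks."""

from __future__ import annotations

import numpy as np
import pytest

from mtqsar import (
    EnsembleModel,
    NetworkSpec,
    TrainConfig,
    TrainedNetwork,
    assemble_training_table,
    build_ensemble,
    fit_applicability_domain,
)
from mtqsar.synthgen import GeneratorConfig, gen_affinity_matrix

#: Small, fast pool configuration used throughout the suite.
FAST_TRAIN = TrainConfig(
    hidden_sizes=(4, 8),
    activations=("tanh", "logistic"),
    n_candidates=4,
    max_epochs=300,
    patience=30,
)


def make_table(n=70, effect=3.0, seed=0, n_sites=17):
    """Synthetic training table with a strong planted signal."""
    cfg = GeneratorConfig(n_compounds=n, n_sites=n_sites, effect_size=effect, seed=seed)
    matrix, labels, truth = gen_affinity_matrix(cfg)
    return assemble_training_table(matrix, labels), matrix, truth


@pytest.fixture(scope="session")
def strong_table():
    table, _, truth = make_table(n=70, effect=3.0, seed=11)
    return table, truth


@pytest.fixture(scope="session")
def strong_model(strong_table) -> EnsembleModel:
    table, _ = strong_table
    return build_ensemble(table, FAST_TRAIN, master_seed=5)


def make_constant_net(level: str, variant: int, out_class: int, k: int = 17) -> TrainedNetwork:
    """A degenerate network that always votes ``out_class`` (test stub)."""
    spec = NetworkSpec(n_inputs=k, n_hidden=1, hidden_activation="identity")
    b2 = np.array([5.0, -5.0]) if out_class == 0 else np.array([-5.0, 5.0])
    return TrainedNetwork(
        spec=spec,
        w1=np.zeros((k, 1)),
        b1=np.zeros(1),
        w2=np.zeros((1, 2)),
        b2=b2,
        mean=np.zeros(k),
        sd=np.ones(k),
        level=level,
        variant=variant,
        acc_train=100.0,
        acc_test=100.0,
        acc_val=100.0,
        seed=variant,
    )


def make_stub_model(level_classes: dict[str, int], k: int = 17) -> EnsembleModel:
    """Ensemble whose 7 networks per gradation all vote a fixed class."""
    rng = np.random.default_rng(0)
    x = rng.normal(-6.0, 1.0, size=(20, k))
    domain = fit_applicability_domain(x, [f"S{j}" for j in range(k)])
    networks = {
        (lv, v): make_constant_net(lv, v, level_classes[lv], k)
        for lv in ("h", "hm", "a")
        for v in range(7)
    }
    return EnsembleModel(
        networks=networks, site_ids=[f"S{j}" for j in range(k)], domain=domain
    )
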