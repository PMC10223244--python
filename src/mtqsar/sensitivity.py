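"""Input-sensitivity analysis of trained networks and consensus target ranking.

The sensitivity index of input *i* is the mean-substitution error ratio:
the cross-entropy loss of the network when input *i* is frozen at its
training-subset mean, divided by the baseline loss.  An input the network
ignores scores exactly 1; influential inputs score above 1.  Within one
network the 17 indices are normalized to percentages of their sum.

A target site is *significant* for a network when its normalized
sensitivity strictly exceeds the threshold (default ``round(100 / k)``,
i.e. 6% for 17 inputs), and *consensus significant* for an ensemble when it
is significant in at least ``min_networks`` (default 5) of the 7 networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import TrainingTable, round_half_up
from .ensemble import N_VARIANTS, EnsembleModel
from .mlp import TrainedNetwork

_ZERO_LOSS_EPS = 1e-9


@dataclass
class SensitivityTable:
    """Normalized sensitivities of one gradation ensemble, sites x networks."""

    site_ids: list[str]
    network_ids: list[int]  # seed of each variant's selected network
    values: np.ndarray  # k x 7 percentages, columns sum to 100
    sign: np.ndarray  # per-site count of networks where value > threshold
    threshold: float
    min_networks: int

    def consensus_targets(self) -> list[str]:
        return consensus_significant(self.site_ids, self.sign, self.min_networks)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.site_ids,
                          columns=[str(n) for n in self.network_ids])
        df.insert(0, "Target", self.site_ids)
        df["Sign"] = self.sign
        return df.reset_index(drop=True)


def raw_sensitivity(net: TrainedNetwork, table: TrainingTable) -> np.ndarray:
    """Mean-substitution error ratios, one per input.

    Substitution means come from the training subset of the network's
    sampling variant; the loss ratio itself is evaluated on the general
    (full) set, like every other general-set estimate of the model, which
    keeps the index well-conditioned when the training loss is near zero.
    """
    roles = table.roles(net.variant)
    means = table.energies[roles == "train"].mean(axis=0)
    x = table.energies
    y = table.labels(net.level)
    baseline = net.loss(x, y)
    if baseline < _ZERO_LOSS_EPS:
        warnings.warn(
            f"baseline loss {baseline:.3g} below epsilon; ratios use epsilon floor",
            stacklevel=2,
        )
        baseline = _ZERO_LOSS_EPS
    out = np.empty(x.shape[1])
    for i in range(x.shape[1]):
        xi = x.copy()
        xi[:, i] = means[i]
        out[i] = net.loss(xi, y) / baseline
    return out


def normalize_sensitivity(raw: np.ndarray) -> np.ndarray:
    """Percentages of the per-network index sum; always totals 100."""
    raw = np.asarray(raw, dtype=float)
    total = raw.sum()
    if total <= 0:
        raise ValueError("sensitivity indices sum to zero; cannot normalize")
    return 100.0 * raw / total


def default_threshold(n_inputs: int) -> float:
    """Limiting sensitivity level: 100/k percent, rounded half-up (17 -> 6)."""
    return round_half_up(100.0 / n_inputs)


def significance_counts(values: np.ndarray, threshold: float) -> np.ndarray:
    """Per-site count of networks with sensitivity strictly above threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    values = np.asarray(values, dtype=float)
    return (values > threshold).sum(axis=1)


def consensus_significant(
    site_ids: list[str],
    sign: np.ndarray,
    min_networks: int = 5,
) -> list[str]:
    """Sites significant in at least ``min_networks`` of the ensemble's
    networks, in input order."""
    if not 1 <= min_networks <= N_VARIANTS:
        raise ValueError(f"min_networks must be 1..{N_VARIANTS}")
    return [s for s, c in zip(site_ids, np.asarray(sign)) if c >= min_networks]


def sensitivity_table(
    model: EnsembleModel,
    table: TrainingTable,
    level: str = "h",
    threshold: float | None = None,
    min_networks: int = 5,
) -> SensitivityTable:
    """Full consensus sensitivity analysis of one gradation ensemble."""
    nets = model.level_networks(level)
    values = np.column_stack(
        [normalize_sensitivity(raw_sensitivity(net, table)) for net in nets]
    )
    if threshold is None:
        threshold = default_threshold(len(table.site_ids))
    return SensitivityTable(
        site_ids=list(table.site_ids),
        network_ids=[net.seed for net in nets],
        values=values,
        sign=significance_counts(values, threshold),
        threshold=threshold,
        min_networks=min_networks,
    )
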