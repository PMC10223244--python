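"""Accuracy reporting in the canonical ensemble-table layout.

For each gradation ensemble the report lists the seven selected networks
(architecture, subset accuracies, general-set F0/Fa/Fn/ROC), an unweighted
``Mean`` row, and a ``Consensus`` row with the level-1 majority verdicts
evaluated on the general set; grand-mean rows close the table.  Display
values are rounded half-up to one decimal; the underlying
:class:`~mtqsar.evaluation.MetricsReport` objects stay unrounded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .consensus import level1_consensus
from .datasets import TrainingTable, round_half_up
from .ensemble import LEVELS, N_VARIANTS, EnsembleModel
from .evaluation import MetricsReport, aggregate_report, metrics_report
from .mlp import TrainedNetwork


def network_metrics(
    net: TrainedNetwork, table: TrainingTable, with_significance: bool = False
) -> MetricsReport:
    """General-set metrics of one network (continuous scores feed the ROC)."""
    y = table.labels(net.level)
    pred = net.predict(table.energies)
    scores = net.predict_proba(table.energies)[:, 1]
    return metrics_report(list(pred), list(y), scores=list(scores),
                          with_significance=with_significance)


def consensus_metrics(
    model: EnsembleModel, table: TrainingTable, level: str,
    with_significance: bool = False,
) -> MetricsReport:
    """General-set metrics of the level-1 majority verdicts of one ensemble."""
    y = table.labels(level)
    nets = model.level_networks(level)
    votes = np.column_stack([net.predict(table.energies) for net in nets])
    verdicts = [level1_consensus(row) for row in votes]
    return metrics_report(verdicts, list(y), with_significance=with_significance)


def _r1(x: float | None) -> float | None:
    return None if x is None else round_half_up(x, 1)


def ensemble_report(model: EnsembleModel, table: TrainingTable) -> pd.DataFrame:
    """The full accuracy table: per-network rows, Mean, Consensus, grand means."""
    columns = ["Level", "No", "Architecture", "Train", "Test", "Val", "F0", "Fa", "Fn", "ROC"]
    rows: list[list] = []
    mean_reports: list[MetricsReport] = []
    consensus_reports: list[MetricsReport] = []
    grand_subset: list[tuple[float, float, float]] = []

    for lv in LEVELS:
        nets = model.level_networks(lv)
        level_reports = []
        for net in nets:
            rep = network_metrics(net, table)
            level_reports.append(rep)
            rows.append([
                lv, net.seed, net.spec.architecture,
                _r1(net.acc_train), _r1(net.acc_test), _r1(net.acc_val),
                _r1(rep.f0), _r1(rep.fa), _r1(rep.fn), _r1(rep.roc),
            ])
        mean = aggregate_report(level_reports)
        mean_reports.append(mean)
        accs = np.array([[n.acc_train, n.acc_test, n.acc_val] for n in nets])
        subset_means = tuple(round_half_up(v, 1) for v in accs.mean(axis=0))
        grand_subset.append(tuple(accs.mean(axis=0)))
        rows.append([lv, "Mean", "", *subset_means, mean.f0, mean.fa, mean.fn, mean.roc])
        cons = consensus_metrics(model, table, lv)
        consensus_reports.append(cons)
        rows.append([lv, "Consensus", "", None, None, None,
                     _r1(cons.f0), _r1(cons.fa), _r1(cons.fn), _r1(cons.roc)])

    grand = aggregate_report(mean_reports)
    gsub = np.mean(np.array(grand_subset), axis=0)
    rows.append(["all", "General mean", "",
                 *(round_half_up(v, 1) for v in gsub),
                 grand.f0, grand.fa, grand.fn, grand.roc])
    gcons = aggregate_report([
        MetricsReport(f0=_r1(c.f0), fa=_r1(c.fa), fn=_r1(c.fn), roc=_r1(c.roc))
        for c in consensus_reports
    ])
    rows.append(["all", "General mean for consensus", "", None, None, None,
                 gcons.f0, gcons.fa, gcons.fn, gcons.roc])
    return pd.DataFrame(rows, columns=columns)
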