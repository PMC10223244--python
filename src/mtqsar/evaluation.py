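"""Confusion-based accuracy metrics, significance tests and applicability domain.

Metric conventions follow the classical QSAR usage:

* ``F0`` — overall accuracy on the evaluated set, percent;
* ``Fa`` — accuracy on the positive (active) class, i.e. sensitivity;
* ``Fn`` — accuracy on the negative (inactive) class, i.e. specificity;
* ``ROC`` — rank-based area under the ROC curve x 100 (for binary verdicts
  this reduces exactly to (Fa + Fn) / 2, the balanced accuracy);
* ``MCC`` — Matthews correlation coefficient of the 2x2 table.

The applicability domain is the "three sigma rule" box: per site a band of
mean +- 3 sample standard deviations of the training energies; the global
domain is the min/max over all per-site boundary values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .datasets import AffinityMatrix, round_half_up


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    n_undefined: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn, self.n_undefined) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_defined(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """One Table-row of accuracy figures; percentages, None where undefined."""

    f0: float | None = None
    fa: float | None = None
    fn: float | None = None
    roc: float | None = None
    mcc: float | None = None
    p_binomial: float | None = None
    p_fisher: float | None = None

    _COLUMNS = ("f0", "fa", "fn", "roc", "mcc", "p_binomial", "p_fisher")


@dataclass
class DomainBounds:
    """Three-sigma applicability box over the site-energy space."""

    site_ids: list[str]
    lower: np.ndarray
    upper: np.ndarray
    global_min: float
    global_max: float

    def to_dict(self) -> dict:
        return {
            "site_ids": list(self.site_ids),
            "lower": np.asarray(self.lower).tolist(),
            "upper": np.asarray(self.upper).tolist(),
            "global_min": self.global_min,
            "global_max": self.global_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DomainBounds":
        return cls(
            site_ids=list(d["site_ids"]),
            lower=np.asarray(d["lower"], dtype=float),
            upper=np.asarray(d["upper"], dtype=float),
            global_min=float(d["global_min"]),
            global_max=float(d["global_max"]),
        )


def confusion(pred: Sequence[int | None], truth: Sequence[int]) -> ConfusionCounts:
    """2x2 counts over defined predictions; ``None`` predictions are tallied
    separately as ``n_undefined``."""
    if len(pred) != len(truth):
        raise ValueError(f"length mismatch: {len(pred)} predictions vs {len(truth)} truths")
    c = ConfusionCounts()
    for p, t in zip(pred, truth):
        if p is None:
            c.n_undefined += 1
        elif p == 1 and t == 1:
            c.tp += 1
        elif p == 1 and t == 0:
            c.fp += 1
        elif p == 0 and t == 0:
            c.tn += 1
        else:
            c.fn += 1
    return c


def f_metrics(c: ConfusionCounts) -> tuple[float | None, float | None, float | None]:
    """(F0, Fa, Fn) percentages; a component with zero denominator is None."""
    total = c.n_defined
    f0 = 100.0 * (c.tp + c.tn) / total if total else None
    fa = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) else None
    fn = 100.0 * c.tn / (c.tn + c.fp) if (c.tn + c.fp) else None
    return f0, fa, fn


def roc_auc(scores: Sequence[float], truth: Sequence[int]) -> float | None:
    """Rank-based AUC (ties averaged) as a percentage; None if one class only.

    Scores may be continuous (positive-class probabilities) or the binary
    verdicts themselves, in which case the AUC equals balanced accuracy.
    """
    truth = np.asarray(truth, dtype=int)
    if len(np.unique(truth)) < 2:
        return None
    return 100.0 * float(roc_auc_score(truth, np.asarray(scores, dtype=float)))


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    tp, fp, tn, fn = float(c.tp), float(c.fp), float(c.tn), float(c.fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def binomial_significance(n_correct: int, n: int, p0: float = 0.5) -> float:
    """One-sided exact binomial tail P(X >= n_correct) under success rate p0."""
    if not (0 <= n_correct <= n):
        raise ValueError(f"invalid counts: {n_correct} of {n}")
    return float(stats.binomtest(n_correct, n, p0, alternative="greater").pvalue)


def fisher_significance(c: ConfusionCounts) -> float:
    """Two-sided Fisher exact test on the 2x2 confusion table."""
    _, p = stats.fisher_exact([[c.tp, c.fn], [c.fp, c.tn]], alternative="two-sided")
    return float(p)


def metrics_report(
    pred: Sequence[int | None],
    truth: Sequence[int],
    scores: Sequence[float] | None = None,
    with_significance: bool = False,
) -> MetricsReport:
    """Full metric row for one predictor on one labeled set."""
    c = confusion(pred, truth)
    f0, fa, fn = f_metrics(c)
    defined = [i for i, p in enumerate(pred) if p is not None]
    if scores is None:
        scores = [pred[i] for i in defined]
    else:
        scores = [scores[i] for i in defined]
    truth_d = [truth[i] for i in defined]
    rep = MetricsReport(f0=f0, fa=fa, fn=fn, roc=roc_auc(scores, truth_d), mcc=mcc(c))
    if with_significance:
        rep.p_binomial = binomial_significance(c.tp + c.tn, c.n_defined)
        rep.p_fisher = fisher_significance(c)
    return rep


def aggregate_report(rows: Sequence[MetricsReport]) -> MetricsReport:
    """Column-wise unweighted mean of metric rows, rounded half-up to 1 decimal.

    ``None`` entries are skipped per column; a column that is None in every
    row stays None.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("nothing to aggregate")
    out = MetricsReport()
    for col in MetricsReport._COLUMNS:
        vals = [getattr(r, col) for r in rows if getattr(r, col) is not None]
        if vals:
            setattr(out, col, round_half_up(sum(vals) / len(vals), 1))
    return out


def fit_applicability_domain(matrix: AffinityMatrix | np.ndarray,
                             site_ids: Sequence[str] | None = None) -> DomainBounds:
    """Three-sigma bounds per site plus the pooled global min/max.

    Uses the sample (n-1) standard deviation; requires at least two rows.
    """
    if isinstance(matrix, AffinityMatrix):
        x = matrix.delta_e
        site_ids = matrix.site_ids
    else:
        x = np.asarray(matrix, dtype=float)
        if site_ids is None:
            site_ids = [f"site{j}" for j in range(x.shape[1])]
    if x.shape[0] < 2:
        raise ValueError("applicability domain needs at least 2 compounds")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    lower = mean - 3.0 * sd
    upper = mean + 3.0 * sd
    return DomainBounds(
        site_ids=list(site_ids),
        lower=lower,
        upper=upper,
        global_min=float(lower.min()),
        global_max=float(upper.max()),
    )


def in_domain(x: Sequence[float], bounds: DomainBounds, mode: str = "global") -> bool:
    """Whether a descriptor vector falls inside the applicability box."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite descriptor vector")
    if mode == "global":
        return bool(np.all((x >= bounds.global_min) & (x <= bounds.global_max)))
    if mode == "per_site":
        return bool(np.all((x >= bounds.lower) & (x <= bounds.upper)))
    raise ValueError(f"unknown mode {mode!r}")
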