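"""Two-level consensus classification over the 3 x 7 network grid.

Level 1: within each gradation ensemble, the seven sampling-variant networks
vote; the verdict is the outcome shared by four or more of the seven (a
majority always exists with seven binary votes).

Level 2: the three level-1 verdicts are mapped to a final ordinal class by
non-contradiction.  Only the four nested triples are definite::

    (h,  hm,  a)  -> high
    (nh, hm,  a)  -> moderate
    (nh, nhm, a)  -> low
    (nh, nhm, na) -> inactive

The remaining four triples are self-contradictory and yield ``undefined``,
which is a first-class outcome, never coerced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datasets import AffinityMatrix
from .ensemble import LEVELS, N_VARIANTS, EnsembleModel
from .evaluation import in_domain

#: verdict triple (h, hm, a as 0/1) -> final ordinal class
LEVEL2_MAP: dict[tuple[int, int, int], str] = {
    (1, 1, 1): "high",
    (0, 1, 1): "moderate",
    (0, 0, 1): "low",
    (0, 0, 0): "inactive",
}


@dataclass
class PredictionSpectrum:
    """Full voting record of one compound: 21 votes, 3 verdicts, final class."""

    votes: np.ndarray  # 3 x 7 binary, rows ordered h, hm, a
    level1: dict[str, int]  # gradation -> majority verdict
    final: str  # high / moderate / low / inactive / undefined
    in_domain: bool
    compound_id: str | None = None
    probabilities: np.ndarray | None = None  # 3 x 7 positive-class softmax outputs


def level1_consensus(votes: Sequence[int]) -> int:
    """Simple unweighted majority over exactly seven binary votes (>= 4 wins)."""
    if len(votes) != N_VARIANTS:
        raise ValueError(f"expected {N_VARIANTS} votes, got {len(votes)}")
    votes = [int(v) for v in votes]
    if any(v not in (0, 1) for v in votes):
        raise ValueError("votes must be binary")
    return 1 if sum(votes) >= 4 else 0


def level2_classify(h_verdict: int, hm_verdict: int, a_verdict: int) -> str:
    """Map the three level-1 verdicts to the final class ('undefined' if
    the triple is contradictory)."""
    return LEVEL2_MAP.get((int(h_verdict), int(hm_verdict), int(a_verdict)), "undefined")


def predict(
    model: EnsembleModel,
    x: Sequence[float],
    domain_mode: str = "global",
    compound_id: str | None = None,
) -> PredictionSpectrum:
    """Classify one energy vector with the full two-level consensus.

    Each network applies its own training-subset standardization and votes by
    the argmax of its two softmax outputs; the continuous positive-class
    probabilities are retained for ROC analysis.  Out-of-domain vectors are
    flagged but still classified.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (len(model.site_ids),):
        raise ValueError(
            f"expected a vector of {len(model.site_ids)} site energies, got shape {x.shape}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite energy vector")
    votes = np.zeros((len(LEVELS), N_VARIANTS), dtype=int)
    probs = np.zeros((len(LEVELS), N_VARIANTS))
    for i, lv in enumerate(LEVELS):
        for v in range(N_VARIANTS):
            p = model.networks[(lv, v)].predict_proba(x)[0]
            probs[i, v] = p[1]
            votes[i, v] = int(p[1] >= 0.5)
    level1 = {lv: level1_consensus(votes[i]) for i, lv in enumerate(LEVELS)}
    final = level2_classify(level1["h"], level1["hm"], level1["a"])
    return PredictionSpectrum(
        votes=votes,
        level1=level1,
        final=final,
        in_domain=in_domain(x, model.domain, mode=domain_mode),
        compound_id=compound_id,
        probabilities=probs,
    )


def predict_batch(
    model: EnsembleModel,
    matrix: AffinityMatrix,
    domain_mode: str = "global",
) -> list[PredictionSpectrum]:
    """Row-wise :func:`predict` over an affinity matrix (site order must match)."""
    if list(matrix.site_ids) != list(model.site_ids):
        raise ValueError(
            f"site columns {matrix.site_ids} do not match model sites {model.site_ids}"
        )
    return [
        predict(model, matrix.delta_e[i], domain_mode, compound_id=code)
        for i, code in enumerate(matrix.compound_ids)
    ]
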