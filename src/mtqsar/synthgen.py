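"""Seeded synthetic-data generators with planted ground truth.

Every pipeline stage is testable offline against data whose answer is known
by construction: affinity matrices whose class signal lives in a designated
subset of "informative" sites, docking-run pools whose minima are planted,
multi-group quantitative activity values with five well-separated clusters,
and interaction tables with planted consensus points plus sub-threshold
distractors.

The default configuration mirrors the verified anxiolytic study conditions:
216 compounds, 17 target sites, docking energies within [-11.8, -0.5]
kCal/mol, five activity grades with marginals 30/64/67/34/21 of 216
(high / moderate / low / active / inactive), and four informative sites.
At informative sites the mean energy shift is linear in the activity score
(high=3, moderate=2, low=active=1, inactive=0) and scaled so that the
standardized mean separation between the active class (a) and the inactive
class (na) equals ``effect_size`` exactly; more active compounds get more
negative (stronger) energies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datasets import (
    GRADE_ORDER,
    ActivityRecord,
    AffinityMatrix,
    DockingRuns,
    GradedLabel,
)
from .pharmacophore import INTERACTION_TYPES, InteractionPoint

#: The 17 binding sites of the 14 anxiolytic-relevant target proteins
#: (three targets contribute two distinct sites each).
DEFAULT_SITE_IDS: tuple[str, ...] = (
    "ADRA1A", "ADRA1B", "ADRA2A", "ADRA2B", "AGTR1",
    "GABA-A-GABA", "GABA-A-Benz", "HTR1A", "HTR2A-Spec", "HTR2A-Allo",
    "HTR4", "HTR7", "MTNR1A", "MTNR1B", "NMDA-Glut", "NMDA-Ca", "SLC18A2",
)

#: Verified-database activity-grade composition (high, moderate, low, active,
#: inactive) of the 216-compound study set.
DEFAULT_CLASS_COUNTS: tuple[int, ...] = (30, 64, 67, 34, 21)

_ACTIVITY_SCORE = {"high": 3.0, "moderate": 2.0, "low": 1.0, "active": 1.0, "inactive": 0.0}


@dataclass
class GeneratorConfig:
    n_compounds: int = 216
    n_sites: int = 17
    site_ids: tuple[str, ...] | None = None
    informative_sites: tuple[int, ...] = (1, 2, 4, 14)  # ADRA1B, ADRA2A, AGTR1, NMDA-Glut
    effect_size: float = 1.5
    class_probs: tuple[float, ...] = tuple(c / 216 for c in DEFAULT_CLASS_COUNTS)
    energy_range: tuple[float, float] = (-11.8, -0.5)
    base_mean: float = -5.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.site_ids is None:
            self.site_ids = (
                DEFAULT_SITE_IDS
                if self.n_sites == len(DEFAULT_SITE_IDS)
                else tuple(f"SITE{j:02d}" for j in range(self.n_sites))
            )
        if len(self.site_ids) != self.n_sites:
            raise ValueError("site_ids length does not match n_sites")
        if len(self.class_probs) != len(GRADE_ORDER):
            raise ValueError(f"need {len(GRADE_ORDER)} class probabilities")
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        if not self.energy_range[0] < self.energy_range[1]:
            raise ValueError("energy_range must be (low, high) with low < high")
        if not set(self.informative_sites) <= set(range(self.n_sites)):
            raise ValueError("informative_sites outside site index range")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")


def _grade_offsets(cfg: GeneratorConfig) -> dict[str, float]:
    """Informative-site mean shift per grade, kCal/mol.

    Linear in activity score, normalized by the score expectation within the
    active class so that E[dE | a-class] - E[dE | inactive] =
    -effect_size * noise_sd.
    """
    probs = dict(zip(GRADE_ORDER, cfg.class_probs))
    p_active = sum(p for g, p in probs.items() if g != "inactive")
    mean_active_score = (
        sum(_ACTIVITY_SCORE[g] * probs[g] for g in GRADE_ORDER if g != "inactive") / p_active
        if p_active > 0
        else 1.0
    )
    scale = cfg.effect_size * cfg.noise_sd / mean_active_score
    return {g: -scale * _ACTIVITY_SCORE[g] for g in GRADE_ORDER}


def gen_affinity_matrix(
    cfg: GeneratorConfig,
) -> tuple[AffinityMatrix, list[GradedLabel], dict]:
    """Class-conditional Gaussian affinity matrix with planted informative sites.

    Returns the matrix, the sampled grade labels, and a truth record with the
    planted site identities and per-grade means.  Values are clipped to the
    energy range after noise; a warning is raised when more than 5% of draws
    hit the clip.
    """
    rng = np.random.default_rng(cfg.seed)
    grades = rng.choice(len(GRADE_ORDER), size=cfg.n_compounds, p=cfg.class_probs)
    offsets = _grade_offsets(cfg)
    n_digits = len(str(cfg.n_compounds))
    codes = [f"C{i + 1:0{n_digits}d}" for i in range(cfg.n_compounds)]
    labels = [GradedLabel(c, GRADE_ORDER[g]) for c, g in zip(codes, grades)]

    x = cfg.base_mean + cfg.noise_sd * rng.standard_normal((cfg.n_compounds, cfg.n_sites))
    shift = np.array([offsets[GRADE_ORDER[g]] for g in grades])
    for j in cfg.informative_sites:
        x[:, j] += shift
    lo, hi = cfg.energy_range
    clipped_frac = float(np.mean((x < lo) | (x > hi)))
    if clipped_frac > 0.05:
        warnings.warn(
            f"{100 * clipped_frac:.1f}% of energies clipped to {cfg.energy_range}; "
            "consider a wider range or smaller effect", stacklevel=2,
        )
    x = np.clip(x, lo, hi)

    truth = {
        "informative_sites": [cfg.site_ids[j] for j in cfg.informative_sites],
        "informative_indices": list(cfg.informative_sites),
        "grade_offsets": offsets,
        "base_mean": cfg.base_mean,
        "noise_sd": cfg.noise_sd,
        "effect_size": cfg.effect_size,
        "clipped_fraction": clipped_frac,
        "seed": cfg.seed,
    }
    return AffinityMatrix(codes, list(cfg.site_ids), x), labels, truth


def gen_docking_runs(
    cfg: GeneratorConfig, runs_per_cell: int = 50
) -> tuple[list[DockingRuns], AffinityMatrix]:
    """Docking-energy pools whose per-cell minimum is planted.

    The planted minimum matrix is drawn by :func:`gen_affinity_matrix`; the
    remaining pool values sit strictly above the minimum, so that
    minimum-aggregation recovers the planted matrix exactly.
    """
    if runs_per_cell < 1:
        raise ValueError("runs_per_cell must be >= 1")
    matrix, _, _ = gen_affinity_matrix(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    runs: list[DockingRuns] = []
    for i, code in enumerate(matrix.compound_ids):
        for j, site in enumerate(matrix.site_ids):
            m = matrix.delta_e[i, j]
            above = m + np.abs(rng.normal(1.0, 0.5, size=runs_per_cell - 1)) + 1e-6
            pool = rng.permutation(np.concatenate([[m], above]))
            runs.append(DockingRuns(code, site, tuple(float(v) for v in pool)))
    return runs, matrix


def gen_activity_records(
    n_groups: int = 33,
    per_group: tuple[int, int] = (11, 161),
    cfg: GeneratorConfig | None = None,
) -> tuple[list[ActivityRecord], dict]:
    """Multi-group quantitative activities with five well-separated clusters.

    Each assay group gets its own scale; cluster centers are spaced ten
    within-cluster standard deviations apart, so k-means grading is forced to
    recover the planted memberships.  Truth maps each record index to its
    planted grade.
    """
    cfg = cfg or GeneratorConfig()
    lo, hi = per_group
    if not (1 <= lo <= hi):
        raise ValueError("invalid per-group size range")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    records: list[ActivityRecord] = []
    truth: dict[int, str] = {}
    idx = 0
    for g in range(n_groups):
        size = int(rng.integers(lo, hi + 1))
        scale = float(rng.uniform(0.5, 50.0))
        # at least one member per cluster so every grade is represented
        membership = np.concatenate(
            [np.arange(5), rng.integers(0, 5, size=max(size - 5, 0))]
        )[:size]
        rng.shuffle(membership)
        centers = np.arange(5) * 10.0 * scale  # cluster 4 = most active
        values = centers[membership] + rng.normal(0.0, scale, size=size)
        for i in range(size):
            code = f"G{g + 1:02d}-C{i + 1:03d}"
            records.append(
                ActivityRecord(
                    compound_id=code,
                    group_id=f"G{g + 1:02d}",
                    value=float(values[i]),
                    source_ref="synthetic",
                )
            )
            truth[idx] = GRADE_ORDER[4 - membership[i]]  # highest cluster -> "high"
            idx += 1
    return records, {"grades": truth, "n_groups": n_groups, "seed": cfg.seed}


def gen_interaction_tables(
    groups: int = 2,
    compounds_per_group: int = 4,
    targets: Sequence[str] = ("ADRA1B", "ADRA2A", "AGTR1", "NMDA-Glut"),
    planted_points: int = 4,
    distractors: int = 3,
    seed: int = 0,
) -> tuple[list[InteractionPoint], dict]:
    """Interaction tables with planted consensus points and distractors.

    Planted points get support >= ceil(0.75 g) compounds (consensus must keep
    them); distractors get support <= floor(0.5 g) (consensus must drop
    them).  Truth lists the planted (fragment, interaction type) pairs per
    (group, target).
    """
    rng = np.random.default_rng(seed)
    residue_names = ("ASP", "GLU", "LYS", "PHE", "TRP", "SER", "TYR", "LEU")
    points: list[InteractionPoint] = []
    truth: dict[str, dict[str, list[tuple[str, str]]]] = {}
    hi_support = math.ceil(0.75 * compounds_per_group)
    lo_support = max(1, math.floor(0.5 * compounds_per_group))
    frag_counter = 0
    for g in range(groups):
        group_id = f"GRP{g + 1}"
        compounds = [f"{group_id}-{i + 1}" for i in range(compounds_per_group)]
        truth[group_id] = {}
        for t in targets:
            planted: list[tuple[str, str]] = []
            for kind, count, support_range in (
                ("P", planted_points, (hi_support, compounds_per_group)),
                ("D", distractors, (1, lo_support)),
            ):
                for _ in range(count):
                    frag_counter += 1
                    frag = f"{kind}F{frag_counter:03d}"
                    itype = str(rng.choice(INTERACTION_TYPES[:5]))
                    residue = f"{rng.choice(residue_names)}{int(rng.integers(10, 400))}"
                    support = int(rng.integers(support_range[0], support_range[1] + 1))
                    chosen = rng.choice(compounds_per_group, size=support, replace=False)
                    for c in chosen:
                        points.append(
                            InteractionPoint(
                                compound_id=compounds[c],
                                target_id=t,
                                fragment=frag,
                                interaction_type=itype,
                                residue=residue,
                            )
                        )
                    if kind == "P":
                        planted.append((frag, itype))
            truth[group_id][t] = planted
    return points, {
        "planted": truth,
        "groups": {f"GRP{g + 1}": [f"GRP{g + 1}-{i + 1}" for i in range(compounds_per_group)]
                   for g in range(groups)},
        "min_support": hi_support,
        "seed": seed,
    }
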