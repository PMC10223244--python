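"""Training-table construction from docking energies and graded activity.

The descriptor block of the model is an *affinity matrix*: one row per
compound, one column per target binding site, each cell the minimum docking
energy ``dE`` (kCal/mol, negative) observed over repeated docking runs of the
compound at that site.  Activity is an ordinal five-grade scale
(``high > moderate > low > active > inactive``; "active" marks compounds
reported active without a stated potency level).  Each ordinal grade is
re-expressed as three nested binary gradations:

* ``h/nh``   — high vs. not high,
* ``hm/nhm`` — high-or-moderate ("pronounced") vs. not,
* ``a/na``   — anything but inactive vs. inactive.

The assembled training table has 29 columns for the default 17 sites:
``Code, Level, LevH, LevHM, LevA``, the 17 site-energy columns, and seven
cyclic ``Sample1..Sample7`` train/test/val role assignments (5:1:1 blocks,
each variant shifted one row down from the previous).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Ordinal activity vocabulary, best grade first.
GRADE_ORDER: tuple[str, ...] = ("high", "moderate", "low", "active", "inactive")

#: Numeric encoding used when averaging several graded records of one
#: compound.  "active" carries no potency level and is excluded from the
#: average (it only forces the a/na gradation to "a").
GRADE_SCORE: dict[str, int] = {"high": 3, "moderate": 2, "low": 1, "inactive": 0}
_SCORE_GRADE: dict[int, str] = {v: k for k, v in GRADE_SCORE.items()}

#: One full sampling block: five training rows, one test row, one validation row.
ROLE_PATTERN: tuple[str, ...] = ("train", "train", "train", "train", "train", "test", "val")

#: Fixed column prefix of the assembled training table.
LABEL_COLUMNS: tuple[str, ...] = ("Code", "Level", "LevH", "LevHM", "LevA")
SAMPLE_COLUMNS: tuple[str, ...] = tuple(f"Sample{i}" for i in range(1, 8))


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero on the positive side (2.5 -> 3)."""
    factor = 10.0 ** ndigits
    return math.floor(x * factor + 0.5) / factor


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DockingRuns:
    """Raw pool of docking energies for one (compound, site) cell."""

    compound_id: str
    site_id: str
    energies: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.energies) == 0:
            raise ValueError(f"empty energy pool for ({self.compound_id}, {self.site_id})")
        if not all(math.isfinite(e) for e in self.energies):
            raise ValueError(f"non-finite energy in pool ({self.compound_id}, {self.site_id})")


@dataclass
class AffinityMatrix:
    """Compounds x sites matrix of minimum docking energies, kCal/mol."""

    compound_ids: list[str]
    site_ids: list[str]
    delta_e: np.ndarray

    def __post_init__(self) -> None:
        self.delta_e = np.asarray(self.delta_e, dtype=float)
        if self.delta_e.shape != (len(self.compound_ids), len(self.site_ids)):
            raise ValueError(
                f"delta_e shape {self.delta_e.shape} does not match "
                f"{len(self.compound_ids)} compounds x {len(self.site_ids)} sites"
            )
        if not np.all(np.isfinite(self.delta_e)):
            raise ValueError("affinity matrix contains non-finite values")

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def row(self, compound_id: str) -> np.ndarray:
        return self.delta_e[self.compound_ids.index(compound_id)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.delta_e, columns=self.site_ids)
        df.insert(0, "code", self.compound_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AffinityMatrix":
        if df.columns[0] != "code":
            raise ValueError("affinity CSV must start with a 'code' column")
        sites = list(df.columns[1:])
        return cls(list(df["code"].astype(str)), sites, df[sites].to_numpy(dtype=float))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def read_csv(cls, path: str | Path) -> "AffinityMatrix":
        return cls.from_frame(pd.read_csv(path, comment="#"))


@dataclass(frozen=True)
class ActivityRecord:
    """One literature activity measurement for one compound."""

    compound_id: str
    group_id: str
    value: float | None = None
    label: str | None = None
    source_ref: str = ""

    def __post_init__(self) -> None:
        if self.value is None and self.label is None:
            raise ValueError(f"record for {self.compound_id} has neither value nor label")
        if self.label is not None and self.label not in GRADE_ORDER:
            raise ValueError(f"unknown activity label {self.label!r}")


@dataclass(frozen=True)
class GradedLabel:
    compound_id: str
    level: str

    def __post_init__(self) -> None:
        if self.level not in GRADE_ORDER:
            raise ValueError(f"unknown activity level {self.level!r}")


@dataclass(frozen=True)
class CombinedLabels:
    """The three nested binary gradations derived from one ordinal grade."""

    lev_h: str
    lev_hm: str
    lev_a: str


@dataclass
class SamplingPlan:
    """Cyclic 5:1:1 train/test/val role assignments, one column per variant."""

    n: int
    variants: list[list[str]]

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def roles(self, variant: int) -> list[str]:
        return self.variants[variant]


class TrainingTable:
    """29-column (for 17 sites) table driving ensemble training.

    Thin wrapper over a :class:`pandas.DataFrame` with the canonical column
    layout; provides typed access to the energy block, binary labels and
    sampling roles.
    """

    def __init__(self, frame: pd.DataFrame):
        cols = list(frame.columns)
        if cols[:5] != list(LABEL_COLUMNS):
            raise ValueError(f"training table must start with columns {LABEL_COLUMNS}, got {cols[:5]}")
        if cols[-7:] != list(SAMPLE_COLUMNS):
            raise ValueError("training table must end with columns Sample1..Sample7")
        self.frame = frame.reset_index(drop=True)
        self.site_ids: list[str] = cols[5:-7]
        if not self.site_ids:
            raise ValueError("training table has no site-energy columns")
        # energy columns must be numeric
        self._X = self.frame[self.site_ids].to_numpy(dtype=float)
        if not np.all(np.isfinite(self._X)):
            raise ValueError("non-finite energies in training table")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_columns(self) -> int:
        return len(self.frame.columns)

    @property
    def codes(self) -> list[str]:
        return list(self.frame["Code"].astype(str))

    @property
    def energies(self) -> np.ndarray:
        """n x k matrix of site energies, kCal/mol."""
        return self._X

    def labels(self, level: str) -> np.ndarray:
        """Binary targets (1 = positive) for gradation ``h``/``hm``/``a``."""
        col = {"h": "LevH", "hm": "LevHM", "a": "LevA"}[level]
        return (self.frame[col] == level).to_numpy(dtype=int)

    def roles(self, variant: int) -> np.ndarray:
        return self.frame[f"Sample{variant + 1}"].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def read_csv(cls, path: str | Path) -> "TrainingTable":
        return cls(pd.read_csv(path, comment="#"))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TrainingTable) and self.frame.equals(other.frame)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def aggregate_docking_energies(runs: Iterable[DockingRuns]) -> AffinityMatrix:
    """Collapse per-cell docking-energy pools to their minima.

    Every (compound, site) cell must be supplied exactly once; the output
    keeps compounds sorted lexicographically by code and sites in first-seen
    order.
    """
    pools: dict[tuple[str, str], tuple[float, ...]] = {}
    site_order: list[str] = []
    compounds: set[str] = set()
    for r in runs:
        key = (r.compound_id, r.site_id)
        if key in pools:
            raise ValueError(f"duplicate docking pool for {key}")
        pools[key] = r.energies
        compounds.add(r.compound_id)
        if r.site_id not in site_order:
            site_order.append(r.site_id)
    if not pools:
        raise ValueError("no docking runs supplied")
    compound_order = sorted(compounds)
    missing = [
        (c, s) for c in compound_order for s in site_order if (c, s) not in pools
    ]
    if missing:
        raise ValueError(f"missing docking pools for {len(missing)} cell(s), first: {missing[:5]}")
    delta_e = np.array(
        [[min(pools[(c, s)]) for s in site_order] for c in compound_order]
    )
    return AffinityMatrix(compound_order, site_order, delta_e)


def _kmeans_1d(values: np.ndarray, k: int) -> np.ndarray:
    """Exact 1-D k-means: the optimal within-cluster-SSQ partition by
    dynamic programming over sorted values.

    Returns cluster indices 0..k-1 ordered by ascending centroid.  Exactness
    makes the result independent of any initialization seed, which restart
    heuristics only approximate.
    """
    order = np.argsort(values, kind="stable")
    xs = values[order]
    n = len(xs)
    cum = np.concatenate([[0.0], np.cumsum(xs)])
    cum2 = np.concatenate([[0.0], np.cumsum(xs * xs)])

    def cost(i: int, j: int) -> float:  # ssq of xs[i..j] inclusive
        s = cum[j + 1] - cum[i]
        s2 = cum2[j + 1] - cum2[i]
        return s2 - s * s / (j - i + 1)

    dp = np.full((k + 1, n), np.inf)
    split = np.zeros((k + 1, n), dtype=int)
    for j in range(n):
        dp[1, j] = cost(0, j)
    for m in range(2, k + 1):
        for j in range(m - 1, n):
            for i in range(m - 1, j + 1):
                c = dp[m - 1, i - 1] + cost(i, j)
                if c < dp[m, j] - 1e-12:
                    dp[m, j] = c
                    split[m, j] = i
    # recover boundaries
    labels_sorted = np.empty(n, dtype=int)
    j = n - 1
    for m in range(k, 0, -1):
        i = split[m, j] if m > 1 else 0
        labels_sorted[i : j + 1] = m - 1
        j = i - 1
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def cluster_activity_group(
    values: Sequence[float],
    k: int = 5,
    higher_is_better: bool = True,
    seed: int = 0,
) -> list[str]:
    """Grade quantitative activities of one assay group by 1-D k-means.

    Uses the exact dynamic-programming solution of 1-D k-means, so the
    grading is deterministic (``seed`` is accepted for interface stability
    but has no effect).  Clusters are ranked by centroid (direction set by
    ``higher_is_better``; potency measures such as ED50 want ``False``) and
    ranks are mapped onto the ordinal vocabulary, best cluster -> "high",
    worst -> "inactive".  If the group has fewer distinct values than ``k``,
    ``k`` is reduced with a warning.
    """
    vals = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite activity values")
    n_distinct = len(np.unique(vals))
    if n_distinct < k:
        warnings.warn(
            f"only {n_distinct} distinct values for k={k}; reducing k", stacklevel=2
        )
        k = n_distinct
    if len(vals) < k:
        raise ValueError(f"need at least k={k} values, got {len(vals)}")
    if k == 1:
        return [GRADE_ORDER[2]] * len(vals)
    assign = _kmeans_1d(vals, k)  # 0..k-1 ascending centroid
    rank = (k - 1 - assign) if higher_is_better else assign  # 0 = best cluster
    # best rank -> first vocabulary slot; k<5 spreads ranks evenly over the scale
    vocab_idx = np.round(np.linspace(0, len(GRADE_ORDER) - 1, k)).astype(int)
    return [GRADE_ORDER[vocab_idx[r]] for r in rank]


def unify_structure_labels(records: Sequence[GradedLabel]) -> GradedLabel:
    """Merge several graded records of one compound into a final level.

    Graded entries (high/moderate/low/inactive) are encoded 3/2/1/0, averaged
    and rounded half-up.  Bare "active" entries carry no level and are left
    out of the average; a compound with only "active" records stays "active".
    """
    records = list(records)
    if not records:
        raise ValueError("no records to unify")
    compound = records[0].compound_id
    if any(r.compound_id != compound for r in records):
        raise ValueError("records belong to different compounds")
    scores = [GRADE_SCORE[r.level] for r in records if r.level != "active"]
    if not scores:
        return GradedLabel(compound, "active")
    level = _SCORE_GRADE[int(round_half_up(sum(scores) / len(scores)))]
    return GradedLabel(compound, level)


def derive_combined_labels(level: str) -> CombinedLabels:
    """Nested binary gradations for one ordinal grade (h => hm => a)."""
    if level not in GRADE_ORDER:
        raise ValueError(f"unknown activity level {level!r}")
    return CombinedLabels(
        lev_h="h" if level == "high" else "nh",
        lev_hm="hm" if level in ("high", "moderate") else "nhm",
        lev_a="a" if level != "inactive" else "na",
    )


def build_sampling_plan(n: int, variants: int = 7) -> SamplingPlan:
    """Seven cyclic 5:1:1 role vectors; variant v is variant 0 shifted v rows down."""
    if n < 7:
        raise ValueError(f"need at least 7 rows for a full sampling block, got {n}")
    cols = [
        [ROLE_PATTERN[(i - v) % 7] for i in range(n)] for v in range(variants)
    ]
    return SamplingPlan(n=n, variants=cols)


def assemble_training_table(
    matrix: AffinityMatrix,
    labels: Sequence[GradedLabel],
    plan: SamplingPlan | None = None,
) -> TrainingTable:
    """Join affinity matrix, unified grades and sampling roles into one table.

    Rows are canonically sorted by compound code; the sampling plan (built
    for the row count if omitted) is applied positionally after the sort.
    """
    label_map = {l.compound_id: l.level for l in labels}
    mat_set, lab_set = set(matrix.compound_ids), set(label_map)
    if mat_set != lab_set:
        orphans = sorted(mat_set ^ lab_set)
        raise ValueError(f"compound sets differ between matrix and labels: {orphans[:10]}")
    if plan is None:
        plan = build_sampling_plan(matrix.n_compounds)
    if plan.n != matrix.n_compounds:
        raise ValueError(f"sampling plan built for n={plan.n}, table has {matrix.n_compounds} rows")

    order = np.argsort(np.asarray(matrix.compound_ids, dtype=object))
    codes = [matrix.compound_ids[i] for i in order]
    energies = matrix.delta_e[order]
    levels = [label_map[c] for c in codes]
    combined = [derive_combined_labels(lv) for lv in levels]

    data: dict[str, object] = {
        "Code": codes,
        "Level": levels,
        "LevH": [c.lev_h for c in combined],
        "LevHM": [c.lev_hm for c in combined],
        "LevA": [c.lev_a for c in combined],
    }
    for j, site in enumerate(matrix.site_ids):
        data[site] = energies[:, j]
    for v in range(plan.n_variants):
        data[f"Sample{v + 1}"] = plan.roles(v)
    return TrainingTable(pd.DataFrame(data))


def write_labels_csv(labels: Sequence[GradedLabel], path: str | Path) -> None:
    pd.DataFrame(
        {"code": [l.compound_id for l in labels], "level": [l.level for l in labels]}
    ).to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> list[GradedLabel]:
    df = pd.read_csv(path, comment="#", dtype=str)
    if not {"code", "level"} <= set(df.columns):
        raise ValueError(f"{path}: labels CSV needs 'code' and 'level' columns")
    return [GradedLabel(r.code, r.level) for r in df.itertuples()]


def read_activity_csv(path: str | Path) -> list[ActivityRecord]:
    """Read activity records: CSV with columns code,group,value,label,source."""
    df = pd.read_csv(path, comment="#", dtype={"code": str, "group": str})
    required = {"code", "group"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: activity CSV needs columns {sorted(required)}")
    records = []
    for r in df.itertuples():
        value = getattr(r, "value", None)
        value = None if value is None or (isinstance(value, float) and math.isnan(value)) else float(value)
        label = getattr(r, "label", None)
        label = None if label is None or (isinstance(label, float) and math.isnan(label)) else str(label)
        records.append(
            ActivityRecord(
                compound_id=str(r.code),
                group_id=str(r.group),
                value=value,
                label=label,
                source_ref=str(getattr(r, "source", "") or ""),
            )
        )
    return records


def read_sdf_labels(
    path: str | Path,
    name_field: str = "NAME",
    activity_field: str = "ACTIVITY_LEVEL",
) -> list[GradedLabel]:
    """Extract (compound, activity level) pairs from SDF property fields.

    Only the property block of each record is used; molecule blocks are not
    interpreted.  Requires RDKit.
    """
    try:
        from rdkit import Chem, RDLogger
    except ImportError as exc:  # pragma: no cover - rdkit is an optional extra
        raise ImportError("SDF ingestion requires the optional rdkit dependency") from exc
    RDLogger.DisableLog("rdApp.*")
    labels: list[GradedLabel] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            warnings.warn(f"unreadable SDF record #{i + 1} skipped", stacklevel=2)
            continue
        if not (mol.HasProp(name_field) and mol.HasProp(activity_field)):
            raise ValueError(
                f"SDF record #{i + 1} lacks property {name_field!r} or {activity_field!r}"
            )
        labels.append(
            GradedLabel(mol.GetProp(name_field).strip(), mol.GetProp(activity_field).strip().lower())
        )
    return labels
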