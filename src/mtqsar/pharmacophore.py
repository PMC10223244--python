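"""Consensus pharmacophore extraction from ligand-target interaction tables.

Input is a per-compound, per-target table of interaction points: a ligand
fragment label, an interaction type and the protein residue involved (as
produced by contact-diagram analysis of docking poses).  A *monotarget
pharmacophore* keeps, for one target and one compound group, the
(fragment, interaction type) points supported by at least ``min_support``
distinct compounds (default: three out of four, i.e. ceil(0.75 n)).
A *multitarget pharmacophore* superposes monotarget pharmacophores across
the key targets: fragments are pooled, and each retained fragment carries
per-target evidence (interaction types and residues) — the residue
"superscript" convention of contact-map figures.

Point identity is (fragment, interaction type) at the mono level and the
fragment alone at the multi level; residues are evidence annotations, not
identity, since different targets bind the same fragment via different
residues.
"""

from __future__ import annotations

import json
import math
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

INTERACTION_TYPES = ("hydrophobic", "hbond", "ionic", "pi", "metal", "other")

_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class InteractionPoint:
    compound_id: str
    target_id: str
    fragment: str
    interaction_type: str
    residue: str = ""
    weight: float | None = None

    def __post_init__(self) -> None:
        if not self.fragment:
            raise ValueError("interaction point with empty fragment label")
        if not self.target_id:
            raise ValueError("interaction point with empty target")
        if self.interaction_type not in INTERACTION_TYPES:
            raise ValueError(f"unknown interaction type {self.interaction_type!r}")


@dataclass
class MonoPoint:
    """One consensus point of a monotarget pharmacophore."""

    fragment: str
    interaction_type: str
    support: int
    compounds: list[str]
    residues: dict[str, int]  # residue -> number of supporting compounds


@dataclass
class MonoPharmacophore:
    target_id: str
    points: list[MonoPoint]
    group_size: int
    min_support: int


@dataclass
class MultiPoint:
    """One fragment of a multitarget pharmacophore with per-target evidence."""

    fragment: str
    evidence: dict[str, dict]  # target -> {"interaction_types": [...], "residues": [...]}


@dataclass
class MultiPharmacophore:
    points: list[MultiPoint]
    targets: list[str]
    min_targets: int


def read_interaction_table(path: str | Path) -> list[InteractionPoint]:
    """Read and validate a TSV of interaction points.

    Required columns: compound, target, fragment, interaction_type, residue.
    Unknown interaction types map to "other" with a warning; duplicated rows
    collapse to one point (set semantics).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    required = ["compound", "target", "fragment", "interaction_type", "residue"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    points: list[InteractionPoint] = []
    seen: set[InteractionPoint] = set()
    for i, row in df.iterrows():
        itype = row["interaction_type"].strip().lower()
        if itype not in INTERACTION_TYPES:
            warnings.warn(
                f"{path}: line {i + 2}: unknown interaction type {itype!r} mapped to 'other'",
                stacklevel=2,
            )
            itype = "other"
        try:
            p = InteractionPoint(
                compound_id=row["compound"].strip(),
                target_id=row["target"].strip(),
                fragment=row["fragment"].strip(),
                interaction_type=itype,
                residue=row["residue"].strip(),
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from exc
        if p not in seen:
            seen.add(p)
            points.append(p)
    return points


def monotarget_consensus(
    points: Iterable[InteractionPoint],
    target: str,
    compounds: Sequence[str],
    min_support: int | None = None,
) -> MonoPharmacophore:
    """Consensus points of one compound group at one target.

    A (fragment, interaction type) point is retained iff it occurs for at
    least ``min_support`` distinct compounds of the group; residues are
    aggregated as a union with per-residue compound counts.
    """
    compounds = list(compounds)
    if not compounds:
        raise ValueError("empty compound group")
    if min_support is None:
        min_support = math.ceil(0.75 * len(compounds))
    if min_support > len(compounds):
        raise ValueError(f"min_support {min_support} exceeds group size {len(compounds)}")

    group = set(compounds)
    relevant = [p for p in points if p.target_id == target and p.compound_id in group]
    if not relevant:
        warnings.warn(f"no interaction points for target {target!r}", stacklevel=2)

    by_point: dict[tuple[str, str], list[InteractionPoint]] = {}
    for p in relevant:
        by_point.setdefault((p.fragment, p.interaction_type), []).append(p)

    out: list[MonoPoint] = []
    for (fragment, itype), plist in sorted(by_point.items()):
        supporters = sorted({p.compound_id for p in plist})
        if len(supporters) < min_support:
            continue
        residues = Counter()
        for res in {(p.compound_id, p.residue) for p in plist if p.residue}:
            residues[res[1]] += 1
        out.append(
            MonoPoint(
                fragment=fragment,
                interaction_type=itype,
                support=len(supporters),
                compounds=supporters,
                residues=dict(sorted(residues.items())),
            )
        )
    return MonoPharmacophore(
        target_id=target, points=out, group_size=len(compounds), min_support=min_support
    )


def multitarget_superposition(
    monos: Sequence[MonoPharmacophore],
    min_targets: int = 1,
) -> MultiPharmacophore:
    """Superpose monotarget pharmacophores into one multitarget pharmacophore.

    Default (``min_targets=1``) is the annotated union; higher values give
    support-filtered intersections (a fragment must appear in at least that
    many monotarget pharmacophores).
    """
    if not monos:
        raise ValueError("need at least one monotarget pharmacophore")
    targets = [m.target_id for m in monos]
    if len(set(targets)) != len(targets):
        raise ValueError("duplicate targets among monotarget pharmacophores")

    by_fragment: dict[str, dict[str, dict]] = {}
    for mono in monos:
        for pt in mono.points:
            ev = by_fragment.setdefault(pt.fragment, {}).setdefault(
                mono.target_id, {"interaction_types": [], "residues": []}
            )
            if pt.interaction_type not in ev["interaction_types"]:
                ev["interaction_types"].append(pt.interaction_type)
            for res in pt.residues:
                if res not in ev["residues"]:
                    ev["residues"].append(res)

    points = [
        MultiPoint(fragment=frag, evidence={t: by_fragment[frag][t] for t in sorted(by_fragment[frag])})
        for frag in sorted(by_fragment)
        if len(by_fragment[frag]) >= min_targets
    ]
    return MultiPharmacophore(points=points, targets=targets, min_targets=min_targets)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _to_doc(p: MonoPharmacophore | MultiPharmacophore) -> dict:
    if isinstance(p, MonoPharmacophore):
        return {
            "schema_version": _SCHEMA_VERSION,
            "kind": "mono",
            "target_id": p.target_id,
            "group_size": p.group_size,
            "min_support": p.min_support,
            "points": [
                {
                    "fragment": pt.fragment,
                    "interaction_type": pt.interaction_type,
                    "support": pt.support,
                    "compounds": pt.compounds,
                    "residues": pt.residues,
                }
                for pt in sorted(p.points, key=lambda q: (q.fragment, q.interaction_type))
            ],
        }
    return {
        "schema_version": _SCHEMA_VERSION,
        "kind": "multi",
        "targets": p.targets,
        "min_targets": p.min_targets,
        "points": [
            {"fragment": pt.fragment, "evidence": pt.evidence}
            for pt in sorted(p.points, key=lambda q: q.fragment)
        ],
    }


def write_pharmacophore(p: MonoPharmacophore | MultiPharmacophore, path: str | Path) -> None:
    """Serialize to canonical JSON (sorted keys, deterministic bytes)."""
    try:
        Path(path).write_text(json.dumps(_to_doc(p), sort_keys=True, indent=1) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write pharmacophore to {path}: {exc}") from exc


def load_pharmacophore(path: str | Path) -> MonoPharmacophore | MultiPharmacophore:
    doc = json.loads(Path(path).read_text())
    if doc.get("kind") == "mono":
        return MonoPharmacophore(
            target_id=doc["target_id"],
            group_size=int(doc["group_size"]),
            min_support=int(doc["min_support"]),
            points=[
                MonoPoint(
                    fragment=d["fragment"],
                    interaction_type=d["interaction_type"],
                    support=int(d["support"]),
                    compounds=list(d["compounds"]),
                    residues={k: int(v) for k, v in d["residues"].items()},
                )
                for d in doc["points"]
            ],
        )
    if doc.get("kind") == "multi":
        return MultiPharmacophore(
            targets=list(doc["targets"]),
            min_targets=int(doc["min_targets"]),
            points=[
                MultiPoint(fragment=d["fragment"], evidence=d["evidence"])
                for d in doc["points"]
            ],
        )
    raise ValueError(f"{path}: not a pharmacophore file")
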