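"""Anatomical label scheme for the anterior visual pathway (aVP).

The pathway is modeled as ten integer classes: background plus nine
structures — each optic nerve split into intraorbital (iOrb),
intracanalicular (iCan) and intracranial (iCran) segments, the chiasm
(ONC), and the two optic tracts (OTL/OTR).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

import numpy as np

__all__ = [
    "LabelScheme",
    "DEFAULT_SCHEME",
    "ConflictStats",
    "merge_union_gt",
    "aggregate",
    "GROUPS",
]

# integer codes are fixed for deterministic file interchange
_DEFAULT_NAMES: Tuple[Tuple[int, str], ...] = (
    (0, "background"),
    (1, "ONR_iOrb"),
    (2, "ONR_iCan"),
    (3, "ONR_iCran"),
    (4, "ONL_iOrb"),
    (5, "ONL_iCan"),
    (6, "ONL_iCran"),
    (7, "ONC"),
    (8, "OTR"),
    (9, "OTL"),
)

_SIDES: Mapping[str, str] = {
    "ONR_iOrb": "right",
    "ONR_iCan": "right",
    "ONR_iCran": "right",
    "ONL_iOrb": "left",
    "ONL_iCan": "left",
    "ONL_iCran": "left",
    "ONC": "midline",
    "OTR": "right",
    "OTL": "left",
}

# named aggregation groups: union of member labels (Table-style reporting)
GROUPS: Mapping[str, Tuple[str, ...]] = {
    "whole_aVP": tuple(n for _, n in _DEFAULT_NAMES[1:]),
    "ONR": ("ONR_iOrb", "ONR_iCan", "ONR_iCran"),
    "ONL": ("ONL_iOrb", "ONL_iCan", "ONL_iCran"),
    "ONC": ("ONC",),
    "OTR": ("OTR",),
    "OTL": ("OTL",),
    "iOrb": ("ONR_iOrb", "ONL_iOrb"),
    "iCan": ("ONR_iCan", "ONL_iCan"),
    "iCran": ("ONR_iCran", "ONL_iCran"),
}


@dataclass(frozen=True)
class LabelScheme:
    """Ordered id -> name mapping with per-label side and chain order.

    Invariants: ids are contiguous 0..n-1 with background = 0; every
    non-background label has exactly one side; the anatomical chain per
    side runs iOrb -> iCan -> iCran -> ONC -> OT.
    """

    names: Tuple[Tuple[int, str], ...] = _DEFAULT_NAMES
    sides: Mapping[str, str] = field(default_factory=lambda: dict(_SIDES))

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.names]
        if ids != list(range(len(ids))):
            raise ValueError(f"label ids must be contiguous from 0, got {ids}")
        if self.names[0][1] != "background":
            raise ValueError("label 0 must be background")
        for _, name in self.names[1:]:
            if name not in self.sides:
                raise ValueError(f"label {name!r} has no side assignment")

    @property
    def num_classes(self) -> int:
        return len(self.names)

    @property
    def id_of(self) -> Dict[str, int]:
        return {name: i for i, name in self.names}

    @property
    def name_of(self) -> Dict[int, str]:
        return dict(self.names)

    def side(self, label: "int | str") -> str:
        name = label if isinstance(label, str) else self.name_of[label]
        if name == "background":
            raise KeyError("background has no side")
        return self.sides[name]

    def chain(self, side: str) -> List[int]:
        """Anatomical chain of label ids for one side, nerve to tract."""
        if side == "right":
            names = ["ONR_iOrb", "ONR_iCan", "ONR_iCran", "ONC", "OTR"]
        elif side == "left":
            names = ["ONL_iOrb", "ONL_iCan", "ONL_iCran", "ONC", "OTL"]
        else:
            raise ValueError(f"side must be 'left' or 'right', got {side!r}")
        return [self.id_of[n] for n in names]

    def contralateral(self, label_id: int) -> int:
        """Mirror a sided label id; midline labels map to themselves."""
        name = self.name_of[label_id]
        if name == "ONC" or name == "background":
            return label_id
        swapped = name.replace("ONR", "@").replace("ONL", "ONR").replace("@", "ONL")
        swapped = swapped.replace("OTR", "@").replace("OTL", "OTR").replace("@", "OTL")
        return self.id_of[swapped]

    def group_ids(self, group: str) -> Tuple[int, ...]:
        if group in self.id_of:
            return (self.id_of[group],)
        if group not in GROUPS:
            raise KeyError(f"unknown label group {group!r}")
        return tuple(self.id_of[n] for n in GROUPS[group])

    def to_json(self) -> str:
        return json.dumps(
            {
                "labels": {str(i): n for i, n in self.names},
                "sides": dict(self.sides),
            },
            indent=2,
        )


DEFAULT_SCHEME = LabelScheme()


@dataclass
class ConflictStats:
    """Bookkeeping of multiclass disagreements during union-GT merging."""

    n_conflicts: int = 0
    by_pair: Dict[Tuple[int, int], int] = field(default_factory=dict)


def merge_union_gt(r1, r2):
    """Merge two reader label maps into a union ground truth.

    The merged foreground is exactly the union of both readers'
    foregrounds.  A voxel labeled by only one reader takes that reader's
    label; where both agree the label is kept; where they disagree the
    first reader's label wins and the conflict is counted.

    Parameters
    ----------
    r1, r2 : LabelMap
        Reader segmentations sharing shape and scheme.

    Returns
    -------
    (LabelMap, ConflictStats)
    """
    from .volume import LabelMap  # local import to avoid cycle

    if r1.data.shape != r2.data.shape:
        raise ValueError(
            f"reader shapes differ: {r1.data.shape} vs {r2.data.shape}"
        )
    if r1.scheme.names != r2.scheme.names:
        raise ValueError("reader label schemes differ")

    a = r1.data
    b = r2.data
    out = a.copy()
    only_b = (a == 0) & (b != 0)
    out[only_b] = b[only_b]

    conflict = (a != 0) & (b != 0) & (a != b)
    stats = ConflictStats(n_conflicts=int(conflict.sum()))
    if stats.n_conflicts:
        pairs, counts = np.unique(
            np.stack([a[conflict], b[conflict]], axis=1), axis=0, return_counts=True
        )
        stats.by_pair = {
            (int(p[0]), int(p[1])): int(c) for p, c in zip(pairs, counts)
        }
    return (
        LabelMap(out, spacing=r1.spacing, affine=r1.affine, scheme=r1.scheme,
                 subject_id=r1.subject_id),
        stats,
    )


def aggregate(label_map, group: str) -> np.ndarray:
    """Binary mask for a named structure group (union of member labels)."""
    ids = label_map.scheme.group_ids(group)
    return np.isin(label_map.data, ids)
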