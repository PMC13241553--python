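"""Spatial similarity metrics for binary and multiclass segmentations.

Overlap metrics (DSC, Jaccard, precision, recall, volumetric similarity)
follow the standard set-cardinality formulas.  Surface-distance metrics
(HD, HD95, ASSD) are computed in mm between surface voxel centers, where
a surface voxel is a mask voxel with at least one 6-neighbor outside the
mask (voxels at the image border count as surface).  Distances use a
Euclidean distance transform of each surface, which is exact for
voxel-center-to-voxel-center distances.

Conventions for degenerate inputs:

* both masks empty -> DSC, Jaccard, VS = 1.0; precision/recall = 1.0
* exactly one mask empty -> overlap metrics = 0.0
* distance metrics require both masks nonempty and raise otherwise
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .labels import GROUPS, aggregate

__all__ = [
    "MaskPair",
    "dsc",
    "jaccard",
    "precision",
    "recall",
    "volumetric_similarity",
    "hausdorff",
    "assd",
    "surface_mask",
    "surface_distances",
    "compute_all",
    "evaluate_subject",
    "METRIC_NAMES",
]

METRIC_NAMES = ("dsc", "jaccard", "precision", "recall", "vs",
                "hd", "hd95", "assd")


@dataclass
class MaskPair:
    """Test mask A vs reference mask B on a common grid with mm spacing."""

    a: np.ndarray
    b: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=bool)
        self.b = np.asarray(self.b, dtype=bool)
        if self.a.shape != self.b.shape:
            raise ValueError(f"mask shapes differ: {self.a.shape} vs {self.b.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")


def _counts(p: MaskPair) -> Tuple[int, int, int]:
    na = int(p.a.sum())
    nb = int(p.b.sum())
    ni = int((p.a & p.b).sum())
    return na, nb, ni


def dsc(p: MaskPair) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|)."""
    na, nb, ni = _counts(p)
    if na + nb == 0:
        return 1.0
    return 2.0 * ni / (na + nb)


def jaccard(p: MaskPair) -> float:
    """Jaccard index |A∩B| / |A∪B|."""
    na, nb, ni = _counts(p)
    union = na + nb - ni
    if union == 0:
        return 1.0
    return ni / union


def precision(p: MaskPair) -> float:
    """|A∩B| / |A| (empty A with empty B -> 1.0, otherwise 0.0)."""
    na, nb, ni = _counts(p)
    if na == 0:
        return 1.0 if nb == 0 else 0.0
    return ni / na


def recall(p: MaskPair) -> float:
    """|A∩B| / |B| (empty B with empty A -> 1.0, otherwise 0.0)."""
    na, nb, ni = _counts(p)
    if nb == 0:
        return 1.0 if na == 0 else 0.0
    return ni / nb


def volumetric_similarity(p: MaskPair) -> float:
    """VS = 1 - ||A|-|B|| / (|A|+|B|); symmetric in A and B."""
    na, nb, _ = _counts(p)
    if na + nb == 0:
        return 1.0
    return 1.0 - abs(na - nb) / (na + nb)


def surface_mask(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with >= 1 six-neighbor outside the mask.

    The image border is treated as outside, so voxels touching the edge
    of the grid are surface voxels.
    """
    mask = np.asarray(mask, dtype=bool)
    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1),
        border_value=0)
    return mask & ~interior


def surface_distances(p: MaskPair) -> Tuple[np.ndarray, np.ndarray]:
    """Directed nearest-surface distances (mm): A->B and B->A."""
    if not p.a.any():
        raise ValueError("test mask A is empty; surface distances undefined")
    if not p.b.any():
        raise ValueError("reference mask B is empty; surface distances undefined")
    sa = surface_mask(p.a)
    sb = surface_mask(p.b)
    # EDT of the complement of each surface gives distance to the nearest
    # surface voxel center, scaled anisotropically by spacing.
    dist_to_b = ndimage.distance_transform_edt(~sb, sampling=p.spacing)
    dist_to_a = ndimage.distance_transform_edt(~sa, sampling=p.spacing)
    return dist_to_b[sa], dist_to_a[sb]


def hausdorff(p: MaskPair, percentile: float = 100.0) -> float:
    """(Percentile) Hausdorff distance in mm.

    HD is the max over both directed maxima; HD95 takes the max of the
    directed 95th percentiles to reduce outlier sensitivity.
    """
    d_ab, d_ba = surface_distances(p)
    if percentile >= 100.0:
        return float(max(d_ab.max(), d_ba.max()))
    return float(max(np.percentile(d_ab, percentile),
                     np.percentile(d_ba, percentile)))


def assd(p: MaskPair) -> float:
    """Average symmetric surface distance: mean of pooled directed distances."""
    d_ab, d_ba = surface_distances(p)
    return float(np.concatenate([d_ab, d_ba]).mean())


def compute_all(p: MaskPair) -> Dict[str, Optional[float]]:
    """All eight metrics; distance metrics are None when a mask is empty."""
    out: Dict[str, Optional[float]] = {
        "dsc": dsc(p),
        "jaccard": jaccard(p),
        "precision": precision(p),
        "recall": recall(p),
        "vs": volumetric_similarity(p),
    }
    if p.a.any() and p.b.any():
        d_ab, d_ba = surface_distances(p)
        out["hd"] = float(max(d_ab.max(), d_ba.max()))
        out["hd95"] = float(max(np.percentile(d_ab, 95),
                                np.percentile(d_ba, 95)))
        out["assd"] = float(np.concatenate([d_ab, d_ba]).mean())
    else:
        out["hd"] = out["hd95"] = out["assd"] = None
    return out


DEFAULT_GROUPS = tuple(GROUPS)  # whole_aVP, ONR, ONL, ONC, OTR, OTL, iOrb, iCan, iCran


def evaluate_subject(pred, gt, groups: Sequence[str] = DEFAULT_GROUPS
                     ) -> List[Dict[str, object]]:
    """Per-group metric rows for one predicted/reference label-map pair.

    Returns a list of dicts with keys ``structure``, the eight metric
    names, and ``note`` recording why distance metrics were skipped
    (empty group in either map).
    """
    if pred.data.shape != gt.data.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.data.shape} vs gt {gt.data.shape}")
    if pred.scheme.names != gt.scheme.names:
        raise ValueError("prediction and reference use different label schemes")
    rows = []
    for group in groups:
        pair = MaskPair(aggregate(pred, group), aggregate(gt, group),
                        spacing=gt.spacing)
        vals = compute_all(pair)
        note = ""
        if vals["hd"] is None:
            empty = []
            if not pair.a.any():
                empty.append("prediction")
            if not pair.b.any():
                empty.append("reference")
            note = f"empty {'+'.join(empty)} mask: distance metrics skipped"
        row: Dict[str, object] = {"structure": group, "note": note}
        row.update(vals)
        rows.append(row)
    return rows
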