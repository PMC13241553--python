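"""Anatomically-aware corrections applied after ensemble voting.

Four operators, composed in a fixed order: cluster removal (keep the
largest connected component per label), side-aware label enforcement
(components of sided labels on the wrong side of the chiasm midline are
relabeled to the contralateral label), gap interpolation (directional
morphological closing along each label's principal axis), and continuity
correction (short background gaps between consecutive chain segments are
bridged with a 1-voxel line).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .volume import LabelMap

__all__ = ["PostprocessConfig", "PostprocessReport", "remove_clusters",
           "enforce_sides", "interpolate_gaps", "enforce_continuity",
           "postprocess"]


@dataclass(frozen=True)
class PostprocessConfig:
    connectivity: int = 26
    closing_length_vox: int = 5
    bridge_max_mm: float = 6.0
    midline_x_vox: Optional[float] = None   # override; default = ONC centroid

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.closing_length_vox < 0 or self.bridge_max_mm < 0:
            raise ValueError("lengths must be >= 0")


@dataclass
class PostprocessReport:
    """Diagnostics of every correction applied."""

    components_removed: Dict[int, int] = field(default_factory=dict)
    voxels_removed: int = 0
    side_flips: List[Tuple[int, int, int]] = field(default_factory=list)
    voxels_filled: Dict[int, int] = field(default_factory=dict)
    bridges_drawn: List[dict] = field(default_factory=list)
    bridges_skipped: List[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "components_removed": {str(k): v for k, v
                                   in self.components_removed.items()},
            "voxels_removed": self.voxels_removed,
            "side_flips": [list(f) for f in self.side_flips],
            "voxels_filled": {str(k): v for k, v in self.voxels_filled.items()},
            "bridges_drawn": self.bridges_drawn,
            "bridges_skipped": self.bridges_skipped,
        }


def _structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, rank)


def remove_clusters(lmap: LabelMap, cfg: PostprocessConfig = PostprocessConfig(),
                    report: Optional[PostprocessReport] = None) -> LabelMap:
    """Keep only the largest connected component of each label.

    Size ties are broken by the component whose centroid is closest to
    the image center.
    """
    data = lmap.data.copy()
    struct = _structure(cfg.connectivity)
    center = (np.array(data.shape) - 1) / 2.0
    for lid in np.unique(data):
        if lid == 0:
            continue
        mask = data == lid
        comp, n = ndimage.label(mask, structure=struct)
        if n <= 1:
            continue
        sizes = ndimage.sum_labels(np.ones_like(comp), comp,
                                   index=np.arange(1, n + 1))
        best_size = sizes.max()
        candidates = np.flatnonzero(sizes == best_size) + 1
        if len(candidates) > 1:
            cents = ndimage.center_of_mass(mask, comp, candidates)
            d = [np.linalg.norm(np.array(c) - center) for c in cents]
            keep = candidates[int(np.argmin(d))]
        else:
            keep = candidates[0]
        drop = mask & (comp != keep)
        data[drop] = 0
        if report is not None:
            report.components_removed[int(lid)] = n - 1
            report.voxels_removed += int(drop.sum())
    return lmap.replace(data=data)


def _midline_x(lmap: LabelMap, cfg: PostprocessConfig) -> float:
    if cfg.midline_x_vox is not None:
        return float(cfg.midline_x_vox)
    onc = lmap.data == lmap.scheme.id_of["ONC"]
    if not onc.any():
        raise ValueError("ONC label absent and no explicit midline configured")
    return float(np.argwhere(onc)[:, 0].mean())


def _x_side(affine: np.ndarray) -> float:
    """Sign of the world-x direction of voxel axis 0 (+1 when axis 0
    points to the subject's right, RAS convention)."""
    return 1.0 if affine[0, 0] >= 0 else -1.0


def enforce_sides(lmap: LabelMap, cfg: PostprocessConfig = PostprocessConfig(),
                  report: Optional[PostprocessReport] = None) -> LabelMap:
    """Relabel components of sided labels lying strictly on the wrong
    side of the midline sagittal plane through the ONC centroid."""
    data = lmap.data.copy()
    scheme = lmap.scheme
    mid = _midline_x(lmap, cfg)
    sign = _x_side(lmap.affine)
    struct = _structure(cfg.connectivity)
    for lid in np.unique(data):
        if lid == 0 or scheme.side(int(lid)) == "midline":
            continue
        expected = scheme.side(int(lid))
        comp, n = ndimage.label(data == lid, structure=struct)
        for ci in range(1, n + 1):
            cmask = comp == ci
            cx = float(np.argwhere(cmask)[:, 0].mean())
            offset = (cx - mid) * sign          # >0 -> right of midline
            actual = "right" if offset > 0 else ("left" if offset < 0
                                                 else expected)
            if actual != expected:
                target = scheme.contralateral(int(lid))
                data[cmask] = target
                if report is not None:
                    report.side_flips.append((int(lid), target,
                                              int(cmask.sum())))
    return lmap.replace(data=data)


def _line_structure(direction: np.ndarray, length: int) -> np.ndarray:
    """Rasterize a centered line of ``length`` voxels along ``direction``."""
    length = max(int(length) | 1, 1)          # odd so the line is centered
    half = length // 2
    ts = np.linspace(-half, half, 2 * length + 1)
    pts = np.rint(ts[:, None] * direction[None, :]).astype(int)
    lo = pts.min(axis=0)
    shape = pts.max(axis=0) - lo + 1
    se = np.zeros(shape, dtype=bool)
    se[tuple((pts - lo).T)] = True
    return se


# the 13 canonical digital directions (axis, face-diagonal, body-diagonal)
_CANONICAL_DIRS = np.array(
    [d for d in np.ndindex(3, 3, 3)
     if (v := np.array(d) - 1).any() and tuple(-v) < tuple(v)],
    dtype=float) - 1.0


def _principal_axis(mask: np.ndarray) -> np.ndarray:
    """Principal axis of a mask, snapped to the nearest digital direction
    so the rasterized structuring element is stable across reapplication."""
    coords = np.argwhere(mask).astype(float)
    if len(coords) < 2:
        return np.array([1.0, 0.0, 0.0])
    coords -= coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    axis = vt[0] / np.linalg.norm(vt[0])
    units = _CANONICAL_DIRS / np.linalg.norm(_CANONICAL_DIRS, axis=1,
                                             keepdims=True)
    k = int(np.argmax(np.abs(units @ axis)))
    return units[k]


def interpolate_gaps(lmap: LabelMap, cfg: PostprocessConfig = PostprocessConfig(),
                     report: Optional[PostprocessReport] = None) -> LabelMap:
    """Fill short gaps in each label by directional morphological closing.

    The structuring element is a line of ``closing_length_vox`` voxels
    oriented along the label's principal axis.  Only background voxels
    are filled; other labels are never overwritten.  Labels already
    forming a single connected component are left untouched, so the
    operator is the identity on intact anatomy.
    """
    if cfg.closing_length_vox < 2:
        return lmap
    data = lmap.data.copy()
    struct = _structure(cfg.connectivity)
    for lid in np.unique(data):
        if lid == 0:
            continue
        mask = data == lid
        if ndimage.label(mask, structure=struct)[1] <= 1:
            continue
        se = _line_structure(_principal_axis(mask), cfg.closing_length_vox)
        closed = ndimage.binary_closing(mask, structure=se)
        fill = closed & (data == 0)
        data[fill] = lid
        if report is not None and fill.any():
            report.voxels_filled[int(lid)] = int(fill.sum())
    return lmap.replace(data=data)


def _nearest_pair(a_mask: np.ndarray, b_mask: np.ndarray, spacing
                  ) -> Tuple[np.ndarray, np.ndarray, float]:
    """Closest surface-voxel pair between two masks and their distance."""
    dist, idx = ndimage.distance_transform_edt(~b_mask, sampling=spacing,
                                               return_indices=True)
    a_idx = np.argwhere(a_mask)
    d_at_a = dist[tuple(a_idx.T)]
    k = int(np.argmin(d_at_a))
    pa = a_idx[k]
    pb = np.array([idx[ax][tuple(pa)] for ax in range(3)])
    return pa, pb, float(d_at_a[k])


def enforce_continuity(lmap: LabelMap,
                       cfg: PostprocessConfig = PostprocessConfig(),
                       report: Optional[PostprocessReport] = None) -> LabelMap:
    """Bridge short background gaps between consecutive chain segments.

    For each adjacent pair in each side's iOrb->iCan->iCran->ONC->OT
    chain whose components are not 26-adjacent, a 1-voxel-thick straight
    bridge is drawn between the nearest voxel pair, passing only through
    background, labeled by the nearer segment up to the midpoint.  Gaps
    longer than ``bridge_max_mm`` are reported but left alone.
    """
    data = lmap.data.copy()
    scheme = lmap.scheme
    struct = _structure(26)
    for side in ("right", "left"):
        chain = scheme.chain(side)
        for a, b in zip(chain[:-1], chain[1:]):
            am = data == a
            bm = data == b
            if not am.any() or not bm.any():
                continue
            if (ndimage.binary_dilation(am, structure=struct) & bm).any():
                continue
            pa, pb, gap = _nearest_pair(am, bm, lmap.spacing)
            entry = {"labels": [int(a), int(b)], "gap_mm": round(gap, 3)}
            if gap > cfg.bridge_max_mm:
                if report is not None:
                    report.bridges_skipped.append(entry)
                continue
            n_steps = int(np.ceil(np.abs(pb - pa).max())) * 2 + 1
            ts = np.linspace(0.0, 1.0, n_steps)
            pts = np.unique(np.rint(pa[None] + ts[:, None] * (pb - pa)[None]
                                    ).astype(int), axis=0)
            for pt in pts:
                if data[tuple(pt)] == 0:
                    t = (np.linalg.norm((pt - pa) * lmap.spacing)
                         / max(gap, 1e-9))
                    data[tuple(pt)] = a if t <= 0.5 else b
            if report is not None:
                report.bridges_drawn.append(entry)
    return lmap.replace(data=data)


def postprocess(lmap: LabelMap, cfg: PostprocessConfig = PostprocessConfig()
                ) -> Tuple[LabelMap, PostprocessReport]:
    """Compose the four corrections in order; returns map + diagnostics."""
    report = PostprocessReport()
    out = remove_clusters(lmap, cfg, report)
    try:
        out = enforce_sides(out, cfg, report)
    except ValueError:
        # no ONC and no configured midline: side enforcement is undefined
        pass
    if report.side_flips:
        # a flip can hand a label a second component; re-consolidate so the
        # composite postcondition (<= 1 component per label) holds
        out = remove_clusters(out, cfg, report)
    out = interpolate_gaps(out, cfg, report)
    out = enforce_continuity(out, cfg, report)
    return out, report
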