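"""Synthetic CISS-like phantoms of the anterior visual pathway.

Each phantom contains two thin tubular optic nerves swept along cubic
Bezier curves from the orbits to a midline ellipsoidal chiasm, and two
tubular tracts diverging posteriorly.  The image models the contrast
that the segmentation task actually relies on — a bright fluid sheath
around a darker nerve — plus orbital fat, a dark bony shell around the
canalicular segment, Gaussian noise, and an optional multiplicative
signal-drop zone mimicking field inhomogeneity in the optic canal.

Simulated "reader" masks are produced by perturbing the ground truth
only at label boundaries and segment transitions, so the union-GT
workflow can be exercised without real annotations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .labels import DEFAULT_SCHEME, LabelScheme
from .volume import LabelMap, Volume

__all__ = [
    "PhantomSpec",
    "ReaderPerturbation",
    "PhantomSubject",
    "generate_phantom",
    "perturb_reader",
    "make_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one synthetic subject."""

    shape: Tuple[int, int, int] = (64, 64, 32)
    spacing: Tuple[float, float, float] = (0.6, 0.6, 0.6)
    nerve_radius_mm: float = 1.5
    # arc-length fractions of the nerve assigned to iOrb / iCan / iCran
    segment_fractions: Tuple[float, float, float] = (0.5, 0.2, 0.3)
    chiasm_half_widths_mm: Tuple[float, float, float] = (4.0, 2.5, 1.5)
    tract_length_mm: float = 10.0
    tract_radius_mm: float = 1.3
    orbit_offset_mm: Tuple[float, float, float] = (10.0, -14.0, -1.0)
    sheath_thickness_mm: float = 1.0
    intensities: Dict[str, float] = field(default_factory=lambda: {
        "nerve": 0.35, "fluid": 0.85, "fat": 0.9, "bone": 0.05,
        "background": 0.4,
    })
    noise_sd: float = 0.03
    canal_shading: float = 0.0       # multiplicative signal-drop factor in [0,1)
    canal_shading_extent_mm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.segment_fractions) - 1.0) > 1e-9:
            raise ValueError("segment fractions must sum to 1")
        if self.nerve_radius_mm <= 0:
            raise ValueError("nerve radius must be positive")
        if not (0 <= self.canal_shading < 1):
            raise ValueError("canal_shading must be in [0, 1)")
        # geometry must fit the grid
        half_extent = [s * n / 2 for s, n in zip(self.spacing, self.shape)]
        ox, oy, oz = self.orbit_offset_mm
        margin = self.nerve_radius_mm + self.sheath_thickness_mm
        if (abs(ox) + margin > half_extent[0]
                or abs(oy) + margin > half_extent[1]
                or abs(oz) + margin > half_extent[2]
                or self.tract_length_mm + margin > half_extent[1]):
            raise ValueError("phantom geometry exceeds the grid extent")

    def replace(self, **kw) -> "PhantomSpec":
        return dataclasses.replace(self, **kw)

    @classmethod
    def fit_grid(cls, shape: Tuple[int, int, int],
                 spacing: Tuple[float, float, float] = (0.6, 0.6, 0.6),
                 **kw) -> "PhantomSpec":
        """Spec with anatomy scaled to fit an arbitrary grid extent."""
        ext = [s * n for s, n in zip(spacing, shape)]
        margin = 4.0
        orbit = (min(10.0, ext[0] / 2 - margin),
                 -(ext[1] / 2 - margin),
                 max(-1.0, -(ext[2] / 2 - margin)))
        tract = min(10.0, ext[1] / 2 - margin)
        return cls(shape=tuple(shape), spacing=tuple(spacing),
                   orbit_offset_mm=orbit, tract_length_mm=tract, **kw)


@dataclass(frozen=True)
class ReaderPerturbation:
    """Boundary-level noise model for a simulated manual reader."""

    dilate_prob: float = 0.25
    erode_prob: float = 0.25
    transition_jitter_mm: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.dilate_prob, self.erode_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("perturbation probabilities must be in [0,1]")
        if self.transition_jitter_mm < 0:
            raise ValueError("transition jitter must be >= 0")


@dataclass
class PhantomSubject:
    subject_id: str
    volume: Volume
    gt: LabelMap
    reader1: LabelMap
    reader2: LabelMap
    spec: PhantomSpec


def _bezier(p0, p1, p2, p3, n: int = 240) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return ((1 - t) ** 3 * p0 + 3 * (1 - t) ** 2 * t * p1
            + 3 * (1 - t) * t ** 2 * p2 + t ** 3 * p3)


def _arc_params(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return s / s[-1]


def _world_coords(shape, spacing) -> List[np.ndarray]:
    """Per-axis world coordinates (mm) with the origin at the grid center."""
    return [
        (np.arange(n) - (n - 1) / 2.0) * s
        for n, s in zip(shape, spacing)
    ]


def _tube_fields(shape, spacing, points: np.ndarray, radius: float
                 ) -> Tuple[np.ndarray, np.ndarray]:
    """Distance to polyline and arc parameter of nearest point, on a bbox.

    Returns full-grid arrays (distance inf outside the bounding box).
    """
    coords = _world_coords(shape, spacing)
    lo = points.min(axis=0) - (radius + 2.0)
    hi = points.max(axis=0) + (radius + 2.0)
    sl = tuple(
        slice(int(np.searchsorted(c, l)),
              min(len(c), int(np.searchsorted(c, h)) + 1))
        for c, l, h in zip(coords, lo, hi))
    axes = np.meshgrid(*(c[s] for c, s in zip(coords, sl)), indexing="ij")
    vox = np.stack([a.ravel() for a in axes], axis=1)  # (N, 3)
    # chunked nearest-point search keeps memory bounded
    params = _arc_params(points)
    best_d = np.full(vox.shape[0], np.inf, dtype=np.float32)
    best_t = np.zeros(vox.shape[0], dtype=np.float32)
    step = 200_000 // max(len(points), 1) * 16
    step = max(step, 1024)
    for i in range(0, vox.shape[0], step):
        d2 = ((vox[i:i + step, None, :] - points[None, :, :]) ** 2).sum(-1)
        j = d2.argmin(axis=1)
        dmin = np.sqrt(d2[np.arange(len(j)), j]).astype(np.float32)
        best_d[i:i + step] = dmin
        best_t[i:i + step] = params[j]
    dist = np.full(shape, np.inf, dtype=np.float32)
    tpar = np.zeros(shape, dtype=np.float32)
    bshape = axes[0].shape
    dist[sl] = best_d.reshape(bshape)
    tpar[sl] = best_t.reshape(bshape)
    return dist, tpar


def _nerve_curve(spec: PhantomSpec, sign: float) -> np.ndarray:
    ox, oy, oz = spec.orbit_offset_mm
    ax, ay, az = spec.chiasm_half_widths_mm
    p0 = np.array([sign * ox, oy, oz])
    p1 = np.array([sign * ox, oy * 0.45, oz * 0.4])
    p2 = np.array([sign * ox * 0.5, -ay * 1.6, 0.0])
    p3 = np.array([sign * ax * 0.55, -ay * 0.6, 0.0])  # ends inside the chiasm
    return _bezier(p0, p1, p2, p3)


def _tract_curve(spec: PhantomSpec, sign: float) -> np.ndarray:
    ax, ay, az = spec.chiasm_half_widths_mm
    L = spec.tract_length_mm
    p0 = np.array([sign * ax * 0.55, ay * 0.6, 0.0])   # starts inside the chiasm
    p3 = np.array([sign * (ax * 0.55 + L * 0.45), ay * 0.6 + L * 0.85, 1.2])
    p1 = p0 + (p3 - p0) * 0.33
    p2 = p0 + (p3 - p0) * 0.66
    return _bezier(p0, p1, p2, p3, n=160)


def nerve_arc_length_mm(spec: PhantomSpec) -> float:
    """Analytic-polyline arc length of one optic nerve centerline."""
    pts = _nerve_curve(spec, +1.0)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def generate_phantom(spec: PhantomSpec,
                     scheme: LabelScheme = DEFAULT_SCHEME,
                     subject_id: str = "phantom") -> Tuple[Volume, LabelMap]:
    """Render one phantom volume and its ground-truth label map.

    Deterministic given ``spec.seed``.  All nine structure labels are
    present; sided labels lie strictly on their side of the midline
    sagittal plane and each side's nerve-chiasm-tract chain is connected.
    """
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.shape, spec.spacing
    ids = scheme.id_of

    labels = np.zeros(shape, dtype=np.uint8)
    f1, f2, _ = spec.segment_fractions
    canal_curves = []

    for sign, prefix, tract in ((+1.0, "ONR", "OTR"), (-1.0, "ONL", "OTL")):
        n_pts = _nerve_curve(spec, sign)
        dist, tpar = _tube_fields(shape, spacing, n_pts, spec.nerve_radius_mm)
        in_tube = dist <= spec.nerve_radius_mm
        labels[in_tube & (tpar < f1)] = ids[f"{prefix}_iOrb"]
        labels[in_tube & (tpar >= f1) & (tpar < f1 + f2)] = ids[f"{prefix}_iCan"]
        labels[in_tube & (tpar >= f1 + f2)] = ids[f"{prefix}_iCran"]
        params = _arc_params(n_pts)
        canal_curves.append(n_pts[(params >= f1) & (params < f1 + f2)])

        t_pts = _tract_curve(spec, sign)
        tdist, _ = _tube_fields(shape, spacing, t_pts, spec.tract_radius_mm)
        labels[(tdist <= spec.tract_radius_mm) & (labels == 0)] = ids[tract]

    # chiasm ellipsoid wins over tube ends -> chain connectivity via overlap
    cx = _world_coords(shape, spacing)
    X, Y, Z = np.meshgrid(*cx, indexing="ij")
    ax, ay, az = spec.chiasm_half_widths_mm
    chiasm = (X / ax) ** 2 + (Y / ay) ** 2 + (Z / az) ** 2 <= 1.0
    labels[chiasm] = ids["ONC"]

    # --- image synthesis -------------------------------------------------
    inten = spec.intensities
    img = np.full(shape, inten["background"], dtype=np.float32)

    # orbital fat occupies the anterior compartment
    fat_y = spec.orbit_offset_mm[1] * 0.55
    img[Y < fat_y] = inten["fat"]

    # bony shell around the canalicular course
    canal_pts = np.concatenate(canal_curves, axis=0)
    cdist, _ = _tube_fields(shape, spacing, canal_pts, spec.nerve_radius_mm)
    r_out = spec.nerve_radius_mm + spec.sheath_thickness_mm
    img[(cdist > r_out) & (cdist <= r_out + 1.2)] = inten["bone"]

    # bright fluid sheath immediately around every structure
    fg = labels != 0
    d_fg = ndimage.distance_transform_edt(~fg, sampling=spacing)
    img[(d_fg > 0) & (d_fg <= spec.sheath_thickness_mm)] = inten["fluid"]
    img[fg] = inten["nerve"]

    if spec.canal_shading > 0:
        sigma = spec.canal_shading_extent_mm / 2.0
        shade = spec.canal_shading * np.exp(-cdist ** 2 / (2 * sigma ** 2))
        img *= 1.0 - shade

    img += rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)
    np.clip(img, 0.0, 1.5, out=img)

    vol = Volume(img, spacing=spacing, subject_id=subject_id)
    gt = LabelMap(labels, spacing=spacing, scheme=scheme,
                  subject_id=subject_id)
    return vol, gt


def _shift_transition(labels: np.ndarray, src: int, dst: int,
                      delta_mm: float, spacing) -> None:
    """Move the src->dst transition by relabeling src voxels near dst."""
    dst_mask = labels == dst
    if not dst_mask.any():
        return
    d = ndimage.distance_transform_edt(~dst_mask, sampling=spacing)
    labels[(labels == src) & (d <= delta_mm)] = dst


def perturb_reader(gt: LabelMap, p: ReaderPerturbation) -> LabelMap:
    """Simulate a manual reader by jittering boundaries of the GT.

    Changes are confined to label boundaries and segment transitions:
    segment-transition surfaces shift along the anatomical chain by a
    random amount up to ``transition_jitter_mm``, surface voxels erode
    with ``erode_prob`` and adjacent background voxels accrete with
    ``dilate_prob``.  Deterministic given ``p.seed``.
    """
    rng = np.random.default_rng(p.seed)
    labels = gt.data.copy()
    scheme = gt.scheme
    spacing = gt.spacing

    if p.transition_jitter_mm > 0:
        for side in ("right", "left"):
            chain = scheme.chain(side)
            for a, b in zip(chain[:-1], chain[1:]):
                delta = rng.uniform(-p.transition_jitter_mm,
                                    p.transition_jitter_mm)
                if delta > 0:
                    _shift_transition(labels, a, b, delta, spacing)
                elif delta < 0:
                    _shift_transition(labels, b, a, -delta, spacing)
    else:
        # keep the random stream aligned across configurations
        rng.uniform(-1, 1, size=8)

    struct = ndimage.generate_binary_structure(3, 1)
    fg = labels != 0
    if p.erode_prob > 0 and fg.any():
        interior = ndimage.binary_erosion(fg, structure=struct, border_value=0)
        surface = fg & ~interior
        erased = surface & (rng.random(labels.shape) < p.erode_prob)
        labels[erased] = 0
    if p.dilate_prob > 0 and fg.any():
        _, idx = ndimage.distance_transform_edt(
            labels == 0, sampling=spacing, return_indices=True)
        ring = (labels == 0) & ndimage.binary_dilation(
            labels != 0, structure=struct)
        grow = ring & (rng.random(labels.shape) < p.dilate_prob)
        nearest = gt.data[tuple(i[grow] for i in idx)]
        src = labels[tuple(i[grow] for i in idx)]
        # accrete with the nearest current label (fall back to original GT)
        take = np.where(src != 0, src, nearest[...])
        labels[grow] = take
    return gt.replace(data=labels)


def make_cohort(n: int,
                template: Optional[PhantomSpec] = None,
                radius_range_mm: Tuple[float, float] = (1.2, 1.8),
                tract_length_scale_range: Tuple[float, float] = (0.85, 1.15),
                reader: Optional[ReaderPerturbation] = None,
                seed: int = 0,
                scheme: LabelScheme = DEFAULT_SCHEME) -> List[PhantomSubject]:
    """Generate ``n`` phantom subjects with randomized geometry.

    Each subject carries the rendered volume, the true label map, and two
    simulated reader masks produced with independent sub-seeds.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    template = template or PhantomSpec()
    reader = reader or ReaderPerturbation()
    ss = np.random.SeedSequence(seed)
    subject_seeds = ss.generate_state(4 * n).reshape(n, 4)
    rng = np.random.default_rng(ss.spawn(1)[0])
    subjects = []
    for i in range(n):
        radius = float(rng.uniform(*radius_range_mm))
        tract_len = template.tract_length_mm * float(
            rng.uniform(*tract_length_scale_range))
        spec = template.replace(
            nerve_radius_mm=radius, tract_length_mm=tract_len,
            seed=int(subject_seeds[i, 0]))
        sid = f"sub-{i + 1:03d}"
        vol, gt = generate_phantom(spec, scheme=scheme, subject_id=sid)
        r1 = perturb_reader(
            gt, dataclasses.replace(reader, seed=int(subject_seeds[i, 1])))
        r2 = perturb_reader(
            gt, dataclasses.replace(reader, seed=int(subject_seeds[i, 2])))
        subjects.append(PhantomSubject(sid, vol, gt, r1.replace(subject_id=sid),
                                       r2.replace(subject_id=sid), spec))
    return subjects
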