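"""Volume and label-map containers with NIfTI I/O and standardization.

Images are held as 3D arrays in canonical RAS orientation with voxel
spacing in mm.  Label maps are unsigned 8-bit and carry their
:class:`~avpseg.labels.LabelScheme`; a JSON sidecar documenting the
scheme is written next to every saved label map.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import nibabel as nib
import numpy as np

from .labels import DEFAULT_SCHEME, LabelScheme

__all__ = [
    "Volume",
    "LabelMap",
    "read_volume",
    "read_label_map",
    "write_volume",
    "write_label_map",
    "standardize",
    "normalize_intensity",
]


def _default_affine(spacing: Tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class Volume:
    """A 3D scalar image with spacing (mm) and affine orientation metadata."""

    data: np.ndarray
    spacing: Tuple[float, float, float] = (0.6, 0.6, 0.6)
    affine: Optional[np.ndarray] = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite values")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        else:
            self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    def replace(self, **kw) -> "Volume":
        return dataclasses.replace(self, **kw)


@dataclass
class LabelMap:
    """A 3D integer map aligned to a Volume, valued in a LabelScheme."""

    data: np.ndarray
    spacing: Tuple[float, float, float] = (0.6, 0.6, 0.6)
    affine: Optional[np.ndarray] = None
    scheme: LabelScheme = dataclasses.field(default_factory=lambda: DEFAULT_SCHEME)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label map must be 3D, got {self.data.ndim}D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"label map must be integer-typed, got {self.data.dtype}")
        self.data = self.data.astype(np.uint8, copy=False)
        hi = int(self.data.max(initial=0))
        if hi >= self.scheme.num_classes:
            raise ValueError(
                f"label value {hi} outside scheme (max id "
                f"{self.scheme.num_classes - 1})"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        else:
            self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    def replace(self, **kw) -> "LabelMap":
        return dataclasses.replace(self, **kw)


def _load_nifti(path) -> tuple[np.ndarray, Tuple[float, float, float], np.ndarray]:
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D image, got {data.ndim} dimensions "
            f"(shape {data.shape})"
        )
    # zooms are float32 in the header; round away representation noise so
    # write-then-read round-trips mm-scale spacings exactly
    spacing = tuple(round(float(z), 6) for z in img.header.get_zooms()[:3])
    return data, spacing, np.asarray(img.affine, dtype=float)


def read_volume(path, subject_id: str = "") -> Volume:
    """Read a 3D NIfTI-1/-2 image, reoriented to canonical RAS."""
    data, spacing, affine = _load_nifti(path)
    data = np.asarray(data, dtype=np.float32)
    if not np.isfinite(data).all():
        raise ValueError(f"{path}: image contains non-finite voxels")
    return Volume(data, spacing=spacing, affine=affine,
                  subject_id=subject_id or Path(path).name.split(".")[0])


def read_label_map(path, scheme: LabelScheme = DEFAULT_SCHEME,
                   subject_id: str = "") -> LabelMap:
    """Read a label map NIfTI; values are validated against the scheme."""
    data, spacing, affine = _load_nifti(path)
    rounded = np.rint(data)
    if not np.allclose(data, rounded, atol=1e-6):
        raise ValueError(f"{path}: label map has non-integer values")
    return LabelMap(rounded.astype(np.uint8), spacing=spacing, affine=affine,
                    scheme=scheme,
                    subject_id=subject_id or Path(path).name.split(".")[0])


def write_volume(vol: Volume, path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def write_label_map(lmap: LabelMap, path) -> None:
    img = nib.Nifti1Image(lmap.data.astype(np.uint8), lmap.affine)
    img.header.set_zooms(lmap.spacing)
    nib.save(img, str(path))
    sidecar = Path(str(path).replace(".nii.gz", "").replace(".nii", "")
                   ).with_suffix(".json")
    sidecar.write_text(lmap.scheme.to_json())


def _crop_pad_1d(n: int, target: int) -> tuple[slice, slice]:
    """Source and destination slices for a center crop / symmetric pad."""
    if n >= target:
        lo = (n - target) // 2
        return slice(lo, lo + target), slice(0, target)
    lo = (target - n) // 2
    return slice(0, n), slice(lo, lo + n)


def standardize(obj, target_shape: Tuple[int, int, int]):
    """Center-crop and/or symmetrically zero-pad to ``target_shape``.

    Works on both Volume and LabelMap; spacing is unchanged.  Identity
    when the input already matches the target (same array returned).
    """
    target_shape = tuple(int(t) for t in target_shape)
    if any(t <= 0 for t in target_shape):
        raise ValueError(f"target shape must be positive, got {target_shape}")
    if obj.data.shape == target_shape:
        return obj
    src, dst = zip(*(_crop_pad_1d(n, t)
                     for n, t in zip(obj.data.shape, target_shape)))
    out = np.zeros(target_shape, dtype=obj.data.dtype)
    out[dst[0], dst[1], dst[2]] = obj.data[src[0], src[1], src[2]]
    return obj.replace(data=out)


def normalize_intensity(vol: Volume, clip: float = 5.0) -> Volume:
    """Z-score over nonzero voxels, clipped to ``[-clip, clip]``.

    If the nonzero voxels have zero spread only the mean is subtracted.
    """
    data = np.asarray(vol.data, dtype=np.float64)
    mask = data != 0
    if not mask.any():
        raise ValueError("cannot normalize an all-zero volume")
    mu = data[mask].mean()
    sd = data[mask].std()
    out = data - mu
    if sd > 0:
        out /= sd
    np.clip(out, -clip, clip, out=out)
    return vol.replace(data=out.astype(np.float32))
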