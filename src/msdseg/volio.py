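"""Volumetric image I/O, preprocessing and augmentation.

Volumes are held as :class:`VolumeImage` (scalar grid + voxel spacing in mm +
affine) and binary masks as :class:`LabelMask`.  Files are NIfTI, read and
written with nibabel.  Conventions: the in-slice plane of the (sagittal)
acquisition is spanned by array axes 0 and 1; slices stack along axis 2
(``SLICE_AXIS``).  Rotations used for augmentation act in that in-slice
plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

#: axis along which acquisition slices stack; rotations act in the
#: orthogonal (in-slice) plane spanned by ``ROTATION_AXES``.
SLICE_AXIS = 2
ROTATION_AXES = (0, 1)

_ALLOWED_ANGLES = (90, 180, 270)


def _default_affine(spacing):
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class VolumeImage:
    """A 3D scalar image with voxel spacing in mm and an affine."""

    data: np.ndarray
    spacing: tuple
    affine: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite voxels")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)

    @property
    def shape(self):
        return self.data.shape

    @property
    def physical_extent(self):
        """Edge lengths of the volume in mm."""
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing))


@dataclass
class LabelMask:
    """A binary 3D grid aligned with a :class:`VolumeImage`."""

    data: np.ndarray
    spacing: tuple
    affine: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {self.data.shape}")
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask values must be exactly 0 or 1, got {vals}")
        self.data = self.data.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)

    @property
    def shape(self):
        return self.data.shape

    def foreground_count(self):
        return int(self.data.sum())


def _load(path):
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise FileNotFoundError(f"file not found: {path}")
    except Exception as exc:  # corrupt header etc.
        raise IOError(f"cannot read NIfTI file {path}: {exc}")
    data = np.asarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing, np.asarray(img.affine)


def read_volume(path) -> VolumeImage:
    """Load a NIfTI scalar volume; non-finite voxels are an error."""
    data, spacing, affine = _load(path)
    return VolumeImage(data.astype(np.float32), spacing, affine)


def read_mask(path) -> LabelMask:
    """Load a NIfTI binary mask (integer-typed files accepted)."""
    data, spacing, affine = _load(path)
    return LabelMask(np.rint(data).astype(np.uint8), spacing, affine)


def write_volume(vol: VolumeImage, path):
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def write_mask(mask: LabelMask, path):
    """Masks are stored as unsigned 8-bit."""
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def normalize_volume(v: VolumeImage) -> VolumeImage:
    """Rescale to zero mean and unit variance over all voxels."""
    if v.data.size < 2:
        raise ValueError("need at least 2 voxels to normalize")
    mean = float(v.data.mean(dtype=np.float64))
    sd = float(v.data.std(dtype=np.float64))
    if sd < 1e-12 * max(1.0, abs(mean)) or sd == 0.0:
        raise ValueError("zero-variance volume cannot be normalized "
                         "(constant input; likely corrupt)")
    out = ((v.data - mean) / sd).astype(np.float32)
    return VolumeImage(out, v.spacing, v.affine.copy())


def crop_physical(v, size_mm, center_offset_mm=(0.0, 0.0, 0.0)):
    """Crop a centered block of physical size ``size_mm`` (per-axis mm).

    The voxel count per axis is ``round(size_mm / spacing)`` with
    round-half-even; the crop is centered on the volume center, shifted by
    ``center_offset_mm``.  Requests exceeding the physical extent raise.
    Works on :class:`VolumeImage` and :class:`LabelMask` alike.
    """
    size_mm = np.asarray(size_mm, dtype=float)
    if size_mm.shape != (3,) or np.any(size_mm <= 0):
        raise ValueError("size_mm must be 3 positive lengths")
    spacing = np.asarray(v.spacing)
    shape = np.asarray(v.data.shape)
    nvox = np.rint(size_mm / spacing).astype(int)  # numpy rounds half to even
    if np.any(nvox > shape):
        raise ValueError(
            f"requested crop {tuple(size_mm)} mm -> {tuple(nvox)} voxels exceeds "
            f"volume shape {tuple(shape)}; no implicit padding")
    offset_vox = np.rint(np.asarray(center_offset_mm, dtype=float) / spacing).astype(int)
    start = (shape - nvox) // 2 + offset_vox
    if np.any(start < 0) or np.any(start + nvox > shape):
        raise ValueError("crop with requested center offset leaves the volume")
    sl = tuple(slice(int(s), int(s + n)) for s, n in zip(start, nvox))
    return type(v)(v.data[sl].copy(), v.spacing, v.affine.copy())


def _rot_spacing(spacing, angle):
    if angle in (90, 270):
        a0, a1 = ROTATION_AXES
        sp = list(spacing)
        sp[a0], sp[a1] = sp[a1], sp[a0]
        return tuple(sp)
    return tuple(spacing)


def rotate_sagittal(v: VolumeImage, m: LabelMask, angle: int):
    """Rotate volume and mask identically in the in-slice (sagittal) plane.

    Only 90/180/270 degrees are allowed — these are exact voxel
    permutations, so intensities and the mask foreground count are
    preserved.
    """
    if angle not in _ALLOWED_ANGLES:
        raise ValueError(f"angle must be one of {_ALLOWED_ANGLES}, got {angle}")
    if v.data.shape != m.data.shape:
        raise ValueError("volume and mask shapes differ")
    k = angle // 90
    sp = _rot_spacing(v.spacing, angle)
    vd = np.ascontiguousarray(np.rot90(v.data, k, axes=ROTATION_AXES))
    md = np.ascontiguousarray(np.rot90(m.data, k, axes=ROTATION_AXES))
    return VolumeImage(vd, sp), LabelMask(md, sp)
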