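"""Synthetic tumor phantoms for exercising the segmentation pipeline.

Real pelvic T2-weighted MRI of colorectal tumors is restricted data; the
generator here emulates its statistical structure instead: one connected
tumor whose cross-section varies from slice to slice (a perturbed
ellipsoid), embedded in a textured background, with tumor/background
intensity contrast that overlaps, a smooth multiplicative intensity
inhomogeneity (bias field), additive Gaussian noise, and anisotropic voxel
spacing.  It also produces degraded probability maps — blurred and noised
versions of a ground-truth mask — used as fixtures for the level-set
refinement.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volio import LabelMask, VolumeImage, write_mask, write_volume

_SIX_CONN = ndimage.generate_binary_structure(3, 1)


@dataclass
class PhantomConfig:
    """Geometry and intensity model of the synthetic study volumes.

    Defaults follow the coarsest acquisition spacing of the emulated study
    (0.6 x 0.6 x 1.2 mm) on a desk-scale 64 x 64 x 48 grid.  Intensities
    are in arbitrary units; the tumor is brighter than background (as for
    fluid-rich tumor tissue on T2w contrast) with overlapping distributions.
    """

    shape: tuple = (64, 64, 48)
    spacing: tuple = (0.6, 0.6, 1.2)
    #: in-plane semi-axis range (mm) for both in-plane directions
    semi_axes_inplane_mm: tuple = (5.0, 9.0)
    #: through-slice semi-axis range (mm)
    semi_axis_axial_mm: tuple = (8.0, 14.0)
    #: per-slice sinusoidal boundary perturbation, fraction of radius
    perturbation_amplitude: float = 0.25
    #: angular lobes of the boundary perturbation
    perturbation_lobes: int = 3
    #: tumor center jitter around the grid center (mm)
    center_jitter_mm: float = 3.0
    background_mean: float = 100.0
    background_sd: float = 20.0
    tumor_mean: float = 150.0
    tumor_sd: float = 15.0
    #: multiplicative bias-field amplitude (fraction of unity)
    bias_amplitude: float = 0.2
    #: additive Gaussian noise standard deviation
    noise_sd: float = 10.0
    #: correlation length of the background/tumor texture (voxels)
    texture_sigma_vox: float = 4.0

    def validate(self):
        if any(n < 4 for n in self.shape):
            raise ValueError("grid too small")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        for lo, hi in (self.semi_axes_inplane_mm, self.semi_axis_axial_mm):
            if not 0 < lo <= hi:
                raise ValueError("semi-axis ranges must be positive and ordered")
        if not 0.0 <= self.perturbation_amplitude <= 0.5:
            raise ValueError("perturbation amplitude must be in [0, 0.5]")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        # the largest admissible tumor (with perturbation and jitter) must fit
        ext = [n * s for n, s in zip(self.shape, self.spacing)]
        max_inplane = (self.semi_axes_inplane_mm[1]
                       * (1 + self.perturbation_amplitude) + self.center_jitter_mm)
        max_axial = self.semi_axis_axial_mm[1] + self.center_jitter_mm
        if (max_inplane > min(ext[0], ext[1]) / 2) or (max_axial > ext[2] / 2):
            raise ValueError("configured tumor cannot fit inside the grid")
        return self


def _smooth_field(rng, shape, sigma_vox):
    """Zero-mean, unit-SD smooth random texture."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox)
    sd = f.std()
    return f / sd if sd > 0 else f


def _bias_field(rng, shape, spacing, amplitude):
    """Low-order polynomial multiplicative inhomogeneity, mean ~1."""
    coords = [np.linspace(-1, 1, n) for n in shape]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    coef = rng.uniform(-1, 1, size=9)
    f = (coef[0] * xx + coef[1] * yy + coef[2] * zz
         + coef[3] * xx * yy + coef[4] * xx * zz + coef[5] * yy * zz
         + coef[6] * xx ** 2 + coef[7] * yy ** 2 + coef[8] * zz ** 2)
    peak = np.abs(f).max()
    if peak > 0:
        f = f / peak
    return 1.0 + amplitude * f


def generate_phantom(cfg: PhantomConfig, seed: int):
    """Generate one (volume, mask) pair; bit-reproducible from ``seed``.

    The tumor is an ellipsoid whose in-plane radius is modulated per slice
    by a sinusoid of smoothly drifting phase, so the cross-section changes
    shape and size from slice to slice while staying a single 6-connected
    component.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    shape, spacing = cfg.shape, cfg.spacing

    a = rng.uniform(*cfg.semi_axes_inplane_mm)
    b = rng.uniform(*cfg.semi_axes_inplane_mm)
    c = rng.uniform(*cfg.semi_axis_axial_mm)
    center = (np.array([n * s for n, s in zip(shape, spacing)]) / 2
              + rng.uniform(-cfg.center_jitter_mm, cfg.center_jitter_mm, 3))
    phase0 = rng.uniform(0, 2 * np.pi)
    drift = rng.uniform(-0.5, 0.5)  # rad per mm of slice position

    # physical voxel-center coordinates
    coords = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    dx = (coords[0] - center[0])[:, None, None]
    dy = (coords[1] - center[1])[None, :, None]
    dz = (coords[2] - center[2])[None, None, :]
    theta = np.arctan2(dy / b, dx / a)
    zpos = coords[2][None, None, :]
    r_eff = 1.0 + cfg.perturbation_amplitude * np.sin(
        cfg.perturbation_lobes * theta + phase0 + drift * zpos)
    inplane = (dx / a) ** 2 + (dy / b) ** 2
    mask = (inplane / r_eff ** 2 + (dz / c) ** 2 <= 1.0)

    if not mask.any():
        raise ValueError("drawn tumor produced an empty mask")
    _, ncomp = ndimage.label(mask, structure=_SIX_CONN)
    if ncomp != 1:
        raise ValueError("drawn tumor is not a single connected component")

    vol = cfg.background_mean + cfg.background_sd * _smooth_field(
        rng, shape, cfg.texture_sigma_vox)
    tumor_tex = cfg.tumor_mean + cfg.tumor_sd * _smooth_field(
        rng, shape, cfg.texture_sigma_vox)
    vol[mask] = tumor_tex[mask]
    if cfg.bias_amplitude > 0:
        vol *= _bias_field(rng, shape, spacing, cfg.bias_amplitude)
    if cfg.noise_sd > 0:
        vol += cfg.noise_sd * rng.standard_normal(shape)

    return (VolumeImage(vol.astype(np.float32), spacing),
            LabelMask(mask.astype(np.uint8), spacing))


def analytic_tumor_volume_mm3(a, b, c):
    """Continuum volume of the unperturbed ellipsoid (4/3 pi abc)."""
    return 4.0 / 3.0 * np.pi * a * b * c


def degrade_to_probability(mask: LabelMask, blur_sigma_mm: float,
                           noise_sd: float, seed: int) -> np.ndarray:
    """Turn a ground-truth mask into an imperfect foreground probability map.

    Gaussian blur (sigma in mm, spacing-aware) softens the boundary and
    additive noise perturbs it; values are clipped to [0, 1].  With zero
    blur and noise the mask itself is returned as probabilities.
    """
    if mask.foreground_count() == 0:
        raise ValueError("cannot degrade an empty mask")
    p = mask.data.astype(np.float64)
    if blur_sigma_mm > 0:
        sig = [blur_sigma_mm / s for s in mask.spacing]
        p = ndimage.gaussian_filter(p, sig)
    if noise_sd > 0:
        p = p + np.random.default_rng(seed).normal(0.0, noise_sd, p.shape)
    return np.clip(p, 0.0, 1.0)


def make_dataset(n_train: int, n_test: int, cfg: PhantomConfig, seed: int,
                 out_dir) -> pd.DataFrame:
    """Write ``n_train + n_test`` phantom pairs plus a manifest CSV.

    Each phantom gets its own child seed derived from the master seed, so
    the whole dataset is reproducible and cases are independent.  Returns
    the manifest (columns: case, path_volume, path_mask, split, seed).
    """
    if n_train < 1 or n_test < 1:
        raise ValueError("need at least one phantom per split")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n_train + n_test)
    rows = []
    for i, s in enumerate(seeds):
        split = "train" if i < n_train else "test"
        vol, mask = generate_phantom(cfg, int(s))
        pv = out_dir / f"case{i:03d}_volume.nii.gz"
        pm = out_dir / f"case{i:03d}_mask.nii.gz"
        write_volume(vol, pv)
        write_mask(mask, pm)
        rows.append({"case": f"case{i:03d}", "path_volume": str(pv),
                     "path_mask": str(pm), "split": split, "seed": int(s)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
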