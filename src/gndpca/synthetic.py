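"""Seeded liver-like phantom cohorts.

The generator emulates the situation the texture-modeling pipeline is built
for: a small cohort of segmented, position-normalized abdominal volumes that
share a smooth organ shape (with per-subject shape variation removable by
registration) and a rich, smooth texture whose variability is far higher-
dimensional than the number of available samples.  Abnormal subjects carry
focal tumor-like lesions of elevated intensity.

Each sample is built in a fixed template space and then pushed through a
random smooth free-form deformation:

    intensity(x) = template(x) + sum_k c_k mode_k(x) [+ lesions] ,
    sample       = warp by a seeded B-spline field,  + masked noise.

* ``template`` is a superellipsoid "liver" with a smoothly varying base
  intensity around 100 (arbitrary CT-like units) and background 0.
* the K texture modes are shared, smooth, unit-RMS random fields; per-sample
  coefficients are i.i.d. normal.  K defaults to 60 — deliberately larger
  than the 15-ish training cohorts used downstream, so no 15-sample
  vectorized PCA can span the texture space, while the modes' smoothness is
  exactly what per-mode subspaces generalize.
* lesions are smooth spherical bumps (default two per abnormal volume,
  radius 6-9 voxels, contrast +15% of the foreground mean), inserted in
  template space so they deform with the shape.
* the shape deformation jitters a coarse control lattice (default 4x4x3
  intervals, 1.5-voxel coefficient spread).

Everything is reproducible bit-for-bit from ``(spec.seed, index)``; the
ground-truth deformation, texture coefficients and lesion geometry are
retrievable for recovery tests, and the texture modes themselves are
exported so subspace recovery can be measured end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .registration import BSplineGrid, CompositeTransform, make_lattice, warp
from .volume import Volume, write_volume

__all__ = [
    "LesionSpec",
    "CohortSpec",
    "SampleTruth",
    "make_template",
    "texture_modes",
    "sample_volume",
    "sample_truth",
    "write_cohort",
]

# rng stream tags (arbitrary fixed constants)
_TAG_MODES = 11
_TAG_TEXTURE = 12
_TAG_SHAPE = 13
_TAG_LESION = 14
_TAG_NOISE = 15


@dataclass
class LesionSpec:
    """Tumor-like lesion model for abnormal samples."""

    count: int = 2
    radius: tuple[float, float] = (6.0, 9.0)   # voxels
    contrast: float = 0.15                     # fraction of foreground mean


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_normal: int = 19
    n_abnormal: int = 4
    shape: tuple[int, int, int] = (64, 64, 32)
    spacing: tuple[float, float, float] = (1.25, 1.25, 2.5)
    n_texture_modes: int = 60
    texture_sd: float = 0.65
    shape_deform_sd: float = 1.5               # voxels, control-point jitter
    shape_grid: tuple[int, int, int] = (4, 4, 3)
    lesion: LesionSpec = field(default_factory=LesionSpec)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_normal < 0 or self.n_abnormal < 0:
            raise ValueError("cohort counts must be >= 0")
        for name in ("texture_sd", "shape_deform_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def size(self) -> int:
        return self.n_normal + self.n_abnormal


@dataclass
class SampleTruth:
    """A generated sample together with its generating parameters."""

    volume: Volume
    ffd: BSplineGrid
    texture_coeffs: np.ndarray
    lesion_centers: np.ndarray   # (L, 3) voxel coords; empty for normal
    lesion_radii: np.ndarray
    abnormal: bool


def _superellipsoid_field(shape) -> np.ndarray:
    """Implicit field f with f<=1 inside; symmetric about each mid-plane."""
    nx, ny, nz = shape
    ax = [np.linspace(-1.0, 1.0, n) for n in (nx, ny, nz)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    a, b, c, p = 0.80, 0.68, 0.72, 2.5
    return (np.abs(gx / a) ** p + np.abs(gy / b) ** p + np.abs(gz / c) ** p)


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def make_template(shape=(64, 64, 32),
                  spacing=(1.25, 1.25, 2.5)) -> Volume:
    """Deterministic liver-like template: a superellipsoid foreground with a
    smoothly varying base intensity (~100 units), background 0."""
    f = _superellipsoid_field(shape)
    edge = _smoothstep((1.0 - f) / 0.15)       # soft boundary, ~4 voxel ramp
    nx, ny, nz = shape
    ax = [np.linspace(-1.0, 1.0, n) for n in shape]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    base = 100.0 + 8.0 * np.sin(1.3 * gx) + 6.0 * np.cos(1.1 * gy + 0.4) \
        + 5.0 * np.sin(0.9 * gz + 0.8)
    return Volume(edge * base, spacing=spacing)


def _foreground_mask(shape) -> np.ndarray:
    return _superellipsoid_field(shape) <= 1.0


def texture_modes(spec: CohortSpec) -> np.ndarray:
    """The cohort's K shared texture modes, (K, nx, ny, nz), unit RMS over
    the foreground, zero outside."""
    rng = np.random.default_rng([spec.seed, _TAG_MODES])
    mask = _foreground_mask(spec.shape)
    edge = _smoothstep((1.0 - _superellipsoid_field(spec.shape)) / 0.15)
    # smoothing scale in voxels, halved along z (coarser slices)
    sigma = (4.0, 4.0, 2.0)
    modes = np.empty((spec.n_texture_modes,) + tuple(spec.shape))
    for k in range(spec.n_texture_modes):
        m = ndimage.gaussian_filter(rng.standard_normal(spec.shape), sigma)
        m *= edge
        rms = np.sqrt(np.mean(m[mask] ** 2))
        modes[k] = m / rms
    return modes


def _lesion_field(spec: CohortSpec, index: int, template: Volume) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Additive lesion intensity in template space, plus centers/radii."""
    rng = np.random.default_rng([spec.seed, _TAG_LESION, index])
    mask = _foreground_mask(spec.shape)
    fg_mean = float(template.data[mask].mean())
    dist = ndimage.distance_transform_edt(mask)   # voxel units
    nx, ny, nz = spec.shape
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in spec.shape), indexing="ij")
    add = np.zeros(spec.shape)
    centers, radii = [], []
    lo, hi = spec.lesion.radius
    for _ in range(spec.lesion.count):
        r = float(rng.uniform(lo, hi))
        candidates = np.argwhere(dist >= r)
        if len(candidates) == 0:
            raise ValueError(
                f"lesion of radius {r:.1f} voxels cannot fit inside the "
                f"foreground (max inscribed radius {dist.max():.1f})"
            )
        c = candidates[rng.integers(len(candidates))]
        d = np.sqrt((ii - c[0]) ** 2 + (jj - c[1]) ** 2 + (kk - c[2]) ** 2)
        add += spec.lesion.contrast * fg_mean * _smoothstep((r - d) / 1.5)
        centers.append(c)
        radii.append(r)
    return add, np.asarray(centers, dtype=float), np.asarray(radii)


def _shape_ffd(spec: CohortSpec, index: int, template: Volume) -> BSplineGrid:
    rng = np.random.default_rng([spec.seed, _TAG_SHAPE, index])
    grid = make_lattice(template, spec.shape_grid)
    jitter = rng.standard_normal(grid.coeffs.shape)
    coeffs = jitter * spec.shape_deform_sd * np.asarray(spec.spacing)
    return BSplineGrid(rho=grid.rho, origin=grid.origin, coeffs=coeffs)


def sample_truth(spec: CohortSpec, index: int, abnormal: bool = False) -> SampleTruth:
    """Generate sample ``index`` with its ground-truth parameters."""
    if not (0 <= index < spec.size):
        raise ValueError(f"index {index} out of range for cohort of size {spec.size}")
    template = make_template(spec.shape, spec.spacing)
    edge = _smoothstep((1.0 - _superellipsoid_field(spec.shape)) / 0.15)
    modes = texture_modes(spec)
    rng_tex = np.random.default_rng([spec.seed, _TAG_TEXTURE, index])
    coeffs = rng_tex.normal(0.0, spec.texture_sd, size=spec.n_texture_modes)
    intensity = template.data + edge * np.tensordot(coeffs, modes, axes=(0, 0))
    if abnormal:
        lesion_add, centers, radii = _lesion_field(spec, index, template)
        intensity = intensity + lesion_add
    else:
        centers = np.empty((0, 3))
        radii = np.empty(0)
    ffd = _shape_ffd(spec, index, template)
    textured = template.like(intensity)
    warped = warp(textured, CompositeTransform(ffd=ffd), template)
    # noise only inside the deformed foreground, as in a segmented volume
    wmask = warp(template.like(edge), CompositeTransform(ffd=ffd), template).data > 0.5
    rng_noise = np.random.default_rng([spec.seed, _TAG_NOISE, index])
    noisy = warped.data + wmask * rng_noise.normal(0.0, spec.noise_sd, size=spec.shape)
    return SampleTruth(
        volume=template.like(noisy),
        ffd=ffd,
        texture_coeffs=coeffs,
        lesion_centers=centers,
        lesion_radii=radii,
        abnormal=abnormal,
    )


def sample_volume(spec: CohortSpec, index: int, abnormal: bool = False) -> Volume:
    """Generate sample ``index`` (volume only)."""
    return sample_truth(spec, index, abnormal).volume


def write_cohort(spec: CohortSpec, out_dir) -> dict:
    """Write the cohort as NIfTI volumes plus a JSON manifest.

    Normal samples take indices 0..n_normal-1, abnormal samples the rest.
    Ground-truth deformations/coefficients go to per-sample ``.npz`` files
    and the shared texture modes to ``texture_modes.npz``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for index in range(spec.size):
        abnormal = index >= spec.n_normal
        truth = sample_truth(spec, index, abnormal)
        label = "abnormal" if abnormal else "normal"
        stem = f"{label}_{index:03d}"
        write_volume(truth.volume, out / f"{stem}.nii.gz")
        np.savez(
            out / f"{stem}_truth.npz",
            ffd_rho=truth.ffd.rho,
            ffd_origin=truth.ffd.origin,
            ffd_coeffs=truth.ffd.coeffs,
            texture_coeffs=truth.texture_coeffs,
            lesion_centers=truth.lesion_centers,
            lesion_radii=truth.lesion_radii,
        )
        rows.append(
            {
                "file": f"{stem}.nii.gz",
                "truth": f"{stem}_truth.npz",
                "label": label,
                "index": index,
            }
        )
    np.savez(out / "texture_modes.npz", modes=texture_modes(spec))
    manifest = {
        "seed": spec.seed,
        "shape": list(spec.shape),
        "spacing": list(spec.spacing),
        "n_normal": spec.n_normal,
        "n_abnormal": spec.n_abnormal,
        "n_texture_modes": spec.n_texture_modes,
        "texture_sd": spec.texture_sd,
        "shape_deform_sd": spec.shape_deform_sd,
        "noise_sd": spec.noise_sd,
        "lesion": {
            "count": spec.lesion.count,
            "radius": list(spec.lesion.radius),
            "contrast": spec.lesion.contrast,
        },
        "texture_modes_file": "texture_modes.npz",
        "samples": rows,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
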