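"""3D shape normalization: rigid + cubic-B-spline free-form deformation.

A volume is aligned to a fixed reference by the additive composite transform

    T(x) = T_global(x) + T_local(x)

where ``T_global(x) = R (x - c) + c + t`` is a rigid transform (rotation
``R = Rz Ry Rx`` about the fixed volume's physical center ``c``) and
``T_local`` is a free-form deformation driven by a regular lattice of control
points with spacing ``rho``:

    T_local(x) = sum_ijk  lambda_ijk  b3((x - phi_x)/rho_x)
                                      b3((y - phi_y)/rho_y)
                                      b3((z - phi_z)/rho_z)

with ``b3`` the centered cubic B-spline kernel (support [-2, 2]) and
``phi_ijk`` the control-point positions.  Both terms are evaluated at the
reference coordinate ``x``; the warped image samples the moving volume at
``T(x)`` by trilinear interpolation.

Registration minimizes the sum of squared intensity differences (SSD) —
appropriate for same-modality data — rigid parameters first (Powell, on a
lightly smoothed pair, then refined), then the lattice coefficients with an
analytic-gradient quasi-Newton method (L-BFGS-B).  The coefficient gradient
is computed by the exact adjoint of the separable B-spline weighting, so no
Kronecker products or per-voxel loops are formed.

Lattice convention: ``grid_dims`` counts control *intervals* across the fixed
image extent per axis, so ``rho = extent / grid_dims``; one padding control
layer is added on each side (plus one to close the last interval), giving
``grid_dims + 3`` control points per axis and a full 4x4x4 support
neighborhood for every voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

from .model import normalized_correlation
from .volume import Volume

__all__ = [
    "RigidParams",
    "BSplineGrid",
    "CompositeTransform",
    "RegistrationConfig",
    "bspline_kernel",
    "rotation_matrix",
    "euler_angles",
    "rigid_apply",
    "rigid_inverse",
    "ffd_displacement",
    "composite_apply",
    "make_lattice",
    "warp",
    "register_rigid",
    "register_bspline",
    "normalize_to",
    "roundtrip_check",
    "transform_to_dict",
    "transform_from_dict",
    "save_transform",
    "load_transform",
]


# ---------------------------------------------------------------------------
# transform types


@dataclass
class RigidParams:
    """Six-parameter rigid transform: rotation angles (rad) and translation
    (mm), rotating about ``center`` (the fixed volume's physical center)."""

    theta: np.ndarray = field(default_factory=lambda: np.zeros(3))
    t: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float).reshape(3)
        self.t = np.asarray(self.t, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if not (np.all(np.isfinite(self.theta)) and np.all(np.isfinite(self.t))):
            raise ValueError("rigid parameters must be finite")

    @property
    def matrix(self) -> np.ndarray:
        return rotation_matrix(self.theta)


@dataclass
class BSplineGrid:
    """Control-point lattice of a cubic-B-spline FFD.

    ``coeffs[i, j, k]`` is the 3-vector displacement coefficient (mm) of the
    control point at physical position ``origin + (i, j, k) * rho``; the
    lattice includes one padding layer on each side of the image extent.
    """

    rho: np.ndarray
    origin: np.ndarray
    coeffs: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if np.any(self.rho <= 0):
            raise ValueError(f"control-point spacing must be positive, got {self.rho}")
        if self.coeffs.ndim != 4 or self.coeffs.shape[-1] != 3:
            raise ValueError("coeffs must have shape (nx, ny, nz, 3)")
        if any(d < 4 for d in self.coeffs.shape[:3]):
            raise ValueError("lattice needs at least 4 control points per axis")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.coeffs.shape[:3]  # type: ignore[return-value]


@dataclass
class CompositeTransform:
    """Additive global + local transform; either part may be absent."""

    rigid: Optional[RigidParams] = None
    ffd: Optional[BSplineGrid] = None


@dataclass
class RegistrationConfig:
    """Optimizer and interpolation settings.

    smoothing_sigma : Gaussian presmoothing (voxels) for the coarse rigid
        stage; the rigid fit is refined on the unsmoothed pair.
    rigid_subsample : stride used when evaluating the rigid SSD.
    bspline_max_iter : L-BFGS-B iteration cap for the FFD stage.
    bspline_gtol_rel : gradient-norm stop relative to the initial gradient.
    regularization : optional coefficient-magnitude penalty weight (off by
        default; the SSD term alone matches the method as stated).
    interp_order : interpolation order for warping (1 = trilinear).
    """

    smoothing_sigma: float = 1.5
    rigid_subsample: int = 2
    rigid_xtol: float = 1e-3
    rigid_maxfev: int = 4000
    bspline_max_iter: int = 200
    bspline_gtol_rel: float = 1e-5
    regularization: float = 0.0
    interp_order: int = 1
    skip_rigid: bool = False
    foreground_threshold: float = 0.0
    erode_voxels: int = 1


# ---------------------------------------------------------------------------
# kernels and point-wise transforms


def bspline_kernel(a):
    """Centered cubic B-spline kernel b3, support [-2, 2].

    b3(0) = 2/3, b3(+-1) = 1/6, b3(+-2) = 0; nonnegative, C2, and the integer
    shifts form a partition of unity.
    """
    a = np.abs(np.asarray(a, dtype=float))
    out = np.zeros_like(a)
    near = a < 1
    mid = (a >= 1) & (a < 2)
    out[near] = 2.0 / 3.0 - a[near] ** 2 + 0.5 * a[near] ** 3
    out[mid] = (2.0 - a[mid]) ** 3 / 6.0
    if out.ndim == 0:
        return float(out)
    return out


def rotation_matrix(theta) -> np.ndarray:
    """R = Rz(tz) @ Ry(ty) @ Rx(tx)."""
    tx, ty, tz = np.asarray(theta, dtype=float)
    cx, sx = np.cos(tx), np.sin(tx)
    cy, sy = np.cos(ty), np.sin(ty)
    cz, sz = np.cos(tz), np.sin(tz)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def euler_angles(r: np.ndarray) -> np.ndarray:
    """Angles (tx, ty, tz) with R = Rz Ry Rx (gimbal-safe for |ty| < pi/2)."""
    r = np.asarray(r, dtype=float)
    ty = -np.arcsin(np.clip(r[2, 0], -1.0, 1.0))
    tx = np.arctan2(r[2, 1], r[2, 2])
    tz = np.arctan2(r[1, 0], r[0, 0])
    return np.array([tx, ty, tz])


def rigid_apply(p, params: RigidParams) -> np.ndarray:
    """Apply ``R (p - c) + c + t`` to points of shape (..., 3)."""
    p = np.asarray(p, dtype=float)
    q = (p - params.center) @ params.matrix.T + params.center + params.t
    return q


def rigid_inverse(params: RigidParams) -> RigidParams:
    """Parameters of the inverse rigid transform (same center)."""
    rinv = params.matrix.T
    return RigidParams(theta=euler_angles(rinv), t=-(rinv @ params.t), center=params.center)


def _lattice_coords(p, grid: BSplineGrid) -> np.ndarray:
    return (np.asarray(p, dtype=float) - grid.origin) / grid.rho


def ffd_displacement(p, grid: BSplineGrid, outside: str = "error") -> np.ndarray:
    """FFD displacement at physical points ``p`` of shape (..., 3).

    Sums the 4x4x4 active control points per point.  Points outside the
    lattice support raise by default; ``outside="zero"`` returns a zero
    displacement there instead.
    """
    p = np.asarray(p, dtype=float)
    scalar = p.ndim == 1
    pts = np.atleast_2d(p)
    s = _lattice_coords(pts, grid)
    dims = np.asarray(grid.dims)
    inside = np.all((s >= 1.0 - 1e-9) & (s <= dims - 2.0 + 1e-9), axis=1)
    if not np.all(inside):
        if outside == "error":
            bad = pts[~inside][0]
            raise ValueError(
                f"point {bad} lies outside the B-spline lattice support; "
                f"pass outside='zero' to treat it as undeformed"
            )
    base = np.clip(np.floor(s).astype(int) - 1, 0, dims - 4)  # (n, 3)
    offs = np.arange(4)
    # per-axis weights (n, 4)
    w = [bspline_kernel(s[:, d, None] - (base[:, d, None] + offs[None, :])) for d in range(3)]
    gathered = grid.coeffs[
        base[:, 0, None, None, None] + offs[None, :, None, None],
        base[:, 1, None, None, None] + offs[None, None, :, None],
        base[:, 2, None, None, None] + offs[None, None, None, :],
    ]  # (n, 4, 4, 4, 3)
    disp = np.einsum("ni,nj,nk,nijkd->nd", w[0], w[1], w[2], gathered)
    disp[~inside] = 0.0
    return disp[0] if scalar else disp.reshape(p.shape)


def composite_apply(p, transform: CompositeTransform) -> np.ndarray:
    """T(x) = T_global(x) + T_local(x); both terms evaluated at ``p``."""
    p = np.asarray(p, dtype=float)
    q = rigid_apply(p, transform.rigid) if transform.rigid is not None else p.copy()
    if transform.ffd is not None:
        q = q + ffd_displacement(p, transform.ffd)
    return q


# ---------------------------------------------------------------------------
# dense (grid) evaluation — separable weight matrices and their adjoint


def make_lattice(fixed: Volume, grid_dims) -> BSplineGrid:
    """Zero-coefficient lattice covering ``fixed`` with ``grid_dims`` control
    intervals per axis plus one padding layer per side."""
    grid_dims = np.asarray(grid_dims, dtype=int).reshape(3)
    if np.any(grid_dims < 1):
        raise ValueError(f"grid_dims must be >= 1 per axis, got {grid_dims}")
    rho = fixed.extent / grid_dims
    origin = fixed.origin - rho
    dims = tuple(int(d) + 3 for d in grid_dims)
    return BSplineGrid(rho=rho, origin=origin, coeffs=np.zeros(dims + (3,)))


def _axis_weight_matrix(n_vox: int, vox_origin: float, vox_spacing: float,
                        lat_origin: float, rho: float, n_ctrl: int) -> np.ndarray:
    """Dense (n_vox, n_ctrl) matrix of kernel weights along one axis."""
    s = (vox_origin + np.arange(n_vox) * vox_spacing - lat_origin) / rho
    return bspline_kernel(s[:, None] - np.arange(n_ctrl)[None, :])


def _weight_matrices(reference: Volume, grid: BSplineGrid) -> list[np.ndarray]:
    return [
        _axis_weight_matrix(
            reference.shape[d], reference.origin[d], reference.spacing[d],
            grid.origin[d], grid.rho[d], grid.dims[d],
        )
        for d in range(3)
    ]


def _dense_displacement(weights: list[np.ndarray], coeffs: np.ndarray) -> np.ndarray:
    """Displacement field (nx, ny, nz, 3) from separable weights."""
    bx, by, bz = weights
    out = np.tensordot(bx, coeffs, axes=(1, 0))        # (nx, cy, cz, 3)
    out = np.tensordot(by, out, axes=(1, 1))           # (ny, nx, cz, 3)
    out = np.tensordot(bz, out, axes=(1, 2))           # (nz, ny, nx, 3)
    return out.transpose(2, 1, 0, 3)


def _dense_adjoint(weights: list[np.ndarray], fld: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`_dense_displacement`: (cx, cy, cz, 3) from a field."""
    bx, by, bz = weights
    out = np.tensordot(bx, fld, axes=(0, 0))           # (cx, ny, nz, 3)
    out = np.tensordot(by, out, axes=(0, 1))           # (cy, cx, nz, 3)
    out = np.tensordot(bz, out, axes=(0, 2))           # (cz, cy, cx, 3)
    return out.transpose(2, 1, 0, 3)


def _physical_grid(v: Volume) -> np.ndarray:
    axes = [v.origin[d] + np.arange(v.shape[d]) * v.spacing[d] for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.stack([gx, gy, gz], axis=-1)


def warp(moving: Volume, transform: CompositeTransform, reference: Volume,
         order: int = 1, cval: float = 0.0) -> Volume:
    """Resample ``moving`` onto the reference grid through ``transform``.

    Intensity at reference voxel x is ``moving(T(x))`` by trilinear (or, with
    ``order=3``, cubic) interpolation; samples falling outside the moving
    volume get the background value ``cval``.
    """
    pts = _physical_grid(reference)
    if transform.rigid is not None:
        q = rigid_apply(pts, transform.rigid)
    else:
        q = pts.copy()
    if transform.ffd is not None:
        weights = _weight_matrices(reference, transform.ffd)
        q = q + _dense_displacement(weights, transform.ffd.coeffs)
    vox = (q - moving.origin) / moving.spacing
    data = ndimage.map_coordinates(
        moving.data, [vox[..., 0], vox[..., 1], vox[..., 2]],
        order=order, cval=cval, mode="constant",
    )
    return reference.like(data)


# ---------------------------------------------------------------------------
# registration


def _check_nondegenerate(moving: Volume, fixed: Volume) -> None:
    if float(np.ptp(moving.data)) == 0.0 or float(np.ptp(fixed.data)) == 0.0:
        raise ValueError("cannot register constant (zero-variance) volumes")


def _rigid_ssd_factory(moving: Volume, fixed: Volume, stride: int, order: int):
    sl = (slice(None, None, stride),) * 3
    pts = _physical_grid(fixed)[sl]
    ref = fixed.data[sl]
    center = fixed.center

    def ssd(x: np.ndarray) -> float:
        params = RigidParams(theta=x[:3], t=x[3:], center=center)
        q = rigid_apply(pts, params)
        vox = (q - moving.origin) / moving.spacing
        m = ndimage.map_coordinates(
            moving.data, [vox[..., 0], vox[..., 1], vox[..., 2]],
            order=order, cval=0.0, mode="constant",
        )
        d = m - ref
        return float(np.mean(d * d))

    return ssd


def register_rigid(moving: Volume, fixed: Volume,
                   config: RegistrationConfig | None = None) -> RigidParams:
    """Estimate the 6 rigid parameters minimizing SSD to ``fixed``.

    Two deterministic Powell stages: a coarse pass on Gaussian-smoothed
    volumes for capture range, then refinement on the originals.
    """
    config = config or RegistrationConfig()
    _check_nondegenerate(moving, fixed)
    # step scales: ~1 degree of rotation, ~half a voxel of translation
    scales = np.concatenate([np.full(3, 0.02), 0.5 * fixed.spacing])

    def solve(mov: Volume, fix: Volume, x0: np.ndarray) -> np.ndarray:
        f = _rigid_ssd_factory(mov, fix, config.rigid_subsample, config.interp_order)
        res = minimize(
            lambda z: f(z * scales), x0 / scales, method="Powell",
            options={"xtol": config.rigid_xtol, "ftol": 1e-10,
                     "maxfev": config.rigid_maxfev},
        )
        return res.x * scales

    x = np.zeros(6)
    if config.smoothing_sigma > 0:
        mov_s = moving.like(ndimage.gaussian_filter(moving.data, config.smoothing_sigma))
        fix_s = fixed.like(ndimage.gaussian_filter(fixed.data, config.smoothing_sigma))
        x = solve(mov_s, fix_s, x)
    x = solve(moving, fixed, x)
    return RigidParams(theta=x[:3], t=x[3:], center=fixed.center)


def register_bspline(moving: Volume, fixed: Volume, grid_dims,
                     config: RegistrationConfig | None = None,
                     rigid: RigidParams | None = None) -> BSplineGrid:
    """Estimate FFD coefficients minimizing SSD to ``fixed``.

    ``rigid``, if given, is composed additively during optimization exactly
    as the final transform applies it (global part evaluated at x).  The SSD
    gradient with respect to the coefficients is analytic: the intensity
    residual times the moving gradient sampled at T(x), pushed back through
    the adjoint of the separable B-spline weighting.  L-BFGS-B guarantees the
    final SSD never exceeds the initial one; hitting the iteration cap is
    recorded in ``result.meta`` rather than raised.
    """
    config = config or RegistrationConfig()
    _check_nondegenerate(moving, fixed)
    grid = make_lattice(fixed, grid_dims)
    weights = _weight_matrices(fixed, grid)
    pts = _physical_grid(fixed)
    base = rigid_apply(pts, rigid) if rigid is not None else pts
    grads = np.gradient(moving.data, *moving.spacing)
    shape = grid.coeffs.shape

    def fg(x: np.ndarray) -> tuple[float, np.ndarray]:
        coeffs = x.reshape(shape)
        q = base + _dense_displacement(weights, coeffs)
        vox = [(q[..., d] - moving.origin[d]) / moving.spacing[d] for d in range(3)]
        m = ndimage.map_coordinates(moving.data, vox, order=1, cval=0.0)
        r = m - fixed.data
        val = float(np.sum(r * r))
        fld = np.stack(
            [2.0 * r * ndimage.map_coordinates(g, vox, order=1, cval=0.0) for g in grads],
            axis=-1,
        )
        grad = _dense_adjoint(weights, fld)
        if config.regularization > 0:
            val += config.regularization * float(np.sum(coeffs**2))
            grad = grad + 2.0 * config.regularization * coeffs
        return val, grad.ravel()

    x0 = np.zeros(int(np.prod(shape)))
    f0, g0 = fg(x0)
    gtol = config.bspline_gtol_rel * max(float(np.max(np.abs(g0))), 1e-300)
    res = minimize(
        fg, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": config.bspline_max_iter, "gtol": gtol, "ftol": 1e-12},
    )
    final = float(res.fun)
    coeffs = res.x.reshape(shape)
    if final > f0:  # pathological line-search failure: keep the identity
        coeffs = np.zeros(shape)
        final = f0
    grid = BSplineGrid(rho=grid.rho, origin=grid.origin, coeffs=coeffs)
    grid.meta = {
        "initial_ssd": f0,
        "final_ssd": final,
        "n_iter": int(res.nit),
        "converged": bool(res.success),
        "message": str(res.message),
    }
    if not res.success:
        grid.meta["warning"] = f"optimizer stopped early: {res.message}"
    return grid


def normalize_to(moving: Volume, fixed: Volume, grid_dims,
                 config: RegistrationConfig | None = None
                 ) -> tuple[Volume, CompositeTransform]:
    """Full shape normalization: rigid, then FFD, then warp onto ``fixed``."""
    config = config or RegistrationConfig()
    rigid = None if config.skip_rigid else register_rigid(moving, fixed, config)
    ffd = register_bspline(moving, fixed, grid_dims, config, rigid=rigid)
    transform = CompositeTransform(rigid=rigid, ffd=ffd)
    return warp(moving, transform, fixed, order=config.interp_order), transform


def transform_to_dict(transform: CompositeTransform) -> dict:
    """JSON-serializable form: rigid angles/translation/center plus the
    lattice spacing, origin and coefficient array."""
    out: dict = {}
    if transform.rigid is not None:
        out["rigid"] = {
            "theta": transform.rigid.theta.tolist(),
            "t": transform.rigid.t.tolist(),
            "center": transform.rigid.center.tolist(),
        }
    if transform.ffd is not None:
        out["ffd"] = {
            "rho": transform.ffd.rho.tolist(),
            "origin": transform.ffd.origin.tolist(),
            "coeffs": transform.ffd.coeffs.tolist(),
        }
    return out


def transform_from_dict(d: dict) -> CompositeTransform:
    rigid = None
    if "rigid" in d:
        r = d["rigid"]
        rigid = RigidParams(theta=r["theta"], t=r["t"], center=r["center"])
    ffd = None
    if "ffd" in d:
        f = d["ffd"]
        ffd = BSplineGrid(rho=f["rho"], origin=f["origin"], coeffs=np.asarray(f["coeffs"]))
    return CompositeTransform(rigid=rigid, ffd=ffd)


def save_transform(transform: CompositeTransform, path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(transform_to_dict(transform), fh)


def load_transform(path) -> CompositeTransform:
    import json

    with open(path) as fh:
        return transform_from_dict(json.load(fh))


def roundtrip_check(original: Volume, fixed: Volume, grid_dims,
                    config: RegistrationConfig | None = None) -> float:
    """Texture-preservation probe: normalize ``original`` to ``fixed``, then
    normalize the result back to ``original`` and return the normalized
    correlation with the original over its (slightly eroded) foreground."""
    config = config or RegistrationConfig()
    forward, _ = normalize_to(original, fixed, grid_dims, config)
    back, _ = normalize_to(forward, original, grid_dims, config)
    mask = original.data > config.foreground_threshold
    if config.erode_voxels > 0:
        mask = ndimage.binary_erosion(mask, iterations=config.erode_voxels)
    return normalized_correlation(back.data[mask], original.data[mask])
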