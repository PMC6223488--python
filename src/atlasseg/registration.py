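"""Rigid registration on 2-D projections and dual-force Demons registration.

Step 1 registers mean-intensity sagittal and coronal projections of the two
volumes with a normalized-cross-correlation criterion (coarse search, then
local simplex refinement), recovering translations along all three axes and
rotations about x and y.  Rotation about z is unobservable from these two
projections and is fixed at zero.

Step 2 is an intensity-driven multi-resolution Demons loop using the
symmetric "dual force" increment built from the gradients of both the fixed
and the warped moving image, with Gaussian regularization of the field after
every iteration.  The registration is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.optimize import minimize

from .volumes import (
    DisplacementField,
    ImageVolume,
    RigidTransform3D,
    apply_rigid,
)

__all__ = [
    "RigidConfig",
    "DemonsConfig",
    "register_rigid_projections",
    "demons_force",
    "gaussian_regularize",
    "register_demons",
    "normalized_cross_correlation",
]


@dataclass
class RigidConfig:
    """Search bounds and discretization for the projection-based rigid step."""

    max_translation_mm: float = 15.0
    max_rotation_deg: float = 10.0
    coarse_angle_step_deg: float = 1.0
    refine: bool = True
    sweeps: int = 3   # alternating sagittal/coronal estimation passes
    eval_margin_mm: float = 20.0   # boundary band excluded from the 2-D NCC

    def __post_init__(self):
        if self.max_translation_mm <= 0 or self.max_rotation_deg <= 0:
            raise ValueError("search bounds must be positive")


@dataclass
class DemonsConfig:
    """Parameters of the dual-force Demons loop.

    levels : resolution levels, each downsampled x2 from the previous.
    iterations : maximum iterations per level.
    sigma_mm : Gaussian regularization width applied to the field (mm).
    alpha : normalization constant in the force denominator; the
        denominator is |grad|^2 + alpha^2 d^2, so larger alpha damps the
        step where the intensity mismatch d is large.
    clamp_hu : intensities are clipped to this range before registration.
    tolerance : convergence threshold on the relative change of the mean
        squared intensity difference (3 consecutive iterations below it).
    """

    levels: int = 3
    iterations: int = 50
    sigma_mm: float = 2.0
    alpha: float = 1.0
    clamp_hu: tuple[float, float] = (-1000.0, 1500.0)
    tolerance: float = 1e-4
    # update damping: the dual-force increment sums two first-order
    # corrections, so a full step systematically overshoots
    step_factor: float = 0.5
    # both images are blurred by this sigma (voxels) before the force is
    # evaluated: resampling the moving image blurs it relative to the fixed
    # one, and the resulting edge-profile mismatch would otherwise drive
    # spurious boundary deformation; a common blur also suppresses
    # noise-chasing drift
    presmooth_vox: float = 1.0

    def __post_init__(self):
        if self.levels < 1 or self.iterations < 1:
            raise ValueError("levels and iterations must be >= 1")
        if self.sigma_mm <= 0 or self.alpha <= 0:
            raise ValueError("sigma_mm and alpha must be positive")


def normalized_cross_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two equally shaped arrays (NCC)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a ** 2).sum() * (b ** 2).sum())
    if denom < 1e-12:
        return 0.0
    return float((a * b).sum() / denom)


# ---------------------------------------------------------------------------
# 2-D rigid registration of projections


def _warp_2d(moving: np.ndarray, spacing, angle_deg: float, shift_mm, fill: float):
    """Resample a 2-D image under an in-plane rigid motion (backward map).

    The motion maps moving into the fixed frame: rotation by angle about the
    image centre then translation by shift (mm, in the two in-plane axes).
    Returns ``(warped, valid)`` where valid marks pixels whose backward
    sample fell inside the moving image domain.
    """
    su, sv = spacing
    nu, nv = moving.shape
    cu, cv = (nu - 1) * su / 2.0, (nv - 1) * sv / 2.0
    uu, vv = np.meshgrid(np.arange(nu) * su, np.arange(nv) * sv, indexing="ij")
    th = np.deg2rad(angle_deg)
    # backward: fixed point -> subtract shift -> rotate by -angle about centre
    du = uu - shift_mm[0] - cu
    dv = vv - shift_mm[1] - cv
    u2 = (np.cos(th) * du + np.sin(th) * dv + cu) / su
    v2 = (-np.sin(th) * du + np.cos(th) * dv + cv) / sv
    valid = (u2 >= 0) & (u2 <= nu - 1) & (v2 >= 0) & (v2 <= nv - 1)
    warped = map_coordinates(moving, np.stack([u2, v2]), order=1, mode="constant", cval=fill)
    return warped, valid


def _register_2d(fixed: np.ndarray, moving: np.ndarray, spacing, cfg: RigidConfig):
    """Recover (angle_deg, shift_mm[2]) mapping moving onto fixed, max NCC.

    The NCC is evaluated on a fixed interior region (a boundary band of
    ``cfg.eval_margin_mm`` is excluded): content rotating or translating
    through the image boundary would otherwise bias the similarity peak
    away from the true motion.  Keeping the region fixed - rather than
    intersecting with the moving domain - avoids the degenerate optimum
    of shrinking the overlap.
    """
    if fixed.std() < 1e-9 or moving.std() < 1e-9:
        raise ValueError("constant projection: no gradient information to register")
    fill = float(np.percentile(moving, 1))
    mu = min(int(np.ceil(cfg.eval_margin_mm / spacing[0])), (fixed.shape[0] - 4) // 2)
    mv = min(int(np.ceil(cfg.eval_margin_mm / spacing[1])), (fixed.shape[1] - 4) // 2)
    region = np.zeros(fixed.shape, dtype=bool)
    region[max(mu, 0): fixed.shape[0] - mu or None, max(mv, 0): fixed.shape[1] - mv or None] = True
    if fixed[region].std() < 1e-9:
        region[:] = True

    def score(params):
        ang, tu, tv = params
        warped, _ = _warp_2d(moving, spacing, ang, (tu, tv), fill)
        return -normalized_cross_correlation(fixed[region], warped[region])

    # coarse: sweep angles; per angle, pick best translation on a grid
    t_step = min(spacing)
    ts = np.arange(-cfg.max_translation_mm, cfg.max_translation_mm + 1e-9, t_step)
    angles = np.arange(-cfg.max_rotation_deg, cfg.max_rotation_deg + 1e-9, cfg.coarse_angle_step_deg)
    best = (0.0, 0.0, 0.0)
    best_val = np.inf
    for ang in angles:
        rot, _ = _warp_2d(moving, spacing, ang, (0.0, 0.0), fill)
        # translation via FFT cross-correlation of mean-removed images
        f0 = fixed - fixed.mean()
        m0 = rot - rot.mean()
        corr = np.real(np.fft.ifft2(np.fft.fft2(f0) * np.conj(np.fft.fft2(m0))))
        corr = np.fft.fftshift(corr)
        peak = np.unravel_index(np.argmax(corr), corr.shape)
        shift_vox = np.asarray(peak) - np.asarray(corr.shape) // 2
        tu, tv = shift_vox * np.asarray(spacing)
        if abs(tu) > cfg.max_translation_mm or abs(tv) > cfg.max_translation_mm:
            continue
        val = score((ang, tu, tv))
        if val < best_val:
            best_val = val
            best = (float(ang), float(tu), float(tv))
    if not np.isfinite(best_val):
        best, best_val = (0.0, 0.0, 0.0), score((0.0, 0.0, 0.0))

    if cfg.refine:
        res = minimize(
            score,
            np.asarray(best),
            method="Nelder-Mead",
            options={"xatol": 0.01, "fatol": 1e-7, "maxiter": 400},
        )
        if res.fun <= best_val:
            best = tuple(float(v) for v in res.x)
    return best


def register_rigid_projections(
    fixed: ImageVolume, moving: ImageVolume, cfg: RigidConfig | None = None
) -> RigidTransform3D:
    """Projection-based 3-D rigid registration.

    Sagittal (collapse x) projections recover (t_y, t_z) and rotation about
    x; coronal (collapse y) projections recover (t_x, t_z) and rotation
    about y; the two z-translation estimates are averaged and rotation
    about z is fixed at 0.  The returned transform maps the moving frame
    into the fixed frame, with the rotation centre at the fixed-volume
    centre.  If the transform does not improve the 3-D NCC over the
    identity, the identity is returned.
    """
    from .volumes import project_mean

    cfg = cfg or RigidConfig()
    sag_f, sag_sp = project_mean(fixed, "sagittal")
    cor_f, cor_sp = project_mean(fixed, "coronal")
    center = fixed.origin + (np.asarray(fixed.shape) - 1) * fixed.spacing / 2.0
    t = RigidTransform3D(center_mm=center)
    if not fixed.same_geometry(moving):
        # e.g. a shorter scan extent: rebase onto the fixed grid (world-aware,
        # air fill) so the projections are commensurate
        moving = apply_rigid(moving, RigidTransform3D(center_mm=center), target=fixed)

    # Alternate the two plane estimates: a rotation about x deforms the
    # coronal projection (and vice versa), so each pass corrects the moving
    # volume with the current estimate before measuring the other plane.
    for sweep in range(max(1, cfg.sweeps)):
        mov = moving if t.is_identity() else apply_rigid(moving, t, target=fixed)
        # sagittal plane axes are (y, z); in-plane rotation = rotation about +x
        sag_m, _ = project_mean(mov, "sagittal")
        ang_x, ty, tz = _register_2d(sag_f, sag_m, sag_sp, cfg)
        t = RigidTransform3D((ang_x, 0.0, 0.0), (0.0, ty, tz), center).compose(t)

        mov = apply_rigid(moving, t, target=fixed)
        # coronal plane axes are (x, z); in-plane rotation about the y axis
        # has the opposite handedness in the (x, z) frame: Ry rotates z to x
        cor_m, _ = project_mean(mov, "coronal")
        ang_cor, tx, tz = _register_2d(cor_f, cor_m, cor_sp, cfg)
        t = RigidTransform3D((0.0, -ang_cor, 0.0), (tx, 0.0, tz), center).compose(t)

    # the two-projection design cannot observe rotation about z: zero it out
    # (small residuals can appear through composition of x/y corrections)
    t = RigidTransform3D(
        rotation_deg=(t.rotation_deg[0], t.rotation_deg[1], 0.0),
        translation_mm=t.translation_mm,
        center_mm=center,
    )

    pre = normalized_cross_correlation(fixed.data, moving.data)
    warped = apply_rigid(moving, t, target=fixed)
    post = normalized_cross_correlation(fixed.data, warped.data)
    if post < pre:
        return RigidTransform3D(center_mm=center)
    return t


# ---------------------------------------------------------------------------
# dual-force Demons


def demons_force(
    fixed: ImageVolume, warped_moving: ImageVolume, cfg: DemonsConfig | None = None
) -> DisplacementField:
    """Dual-force Demons increment (mm) on the fixed grid.

    Per voxel, with d = m - f and central-difference gradients g_f, g_m
    scaled by the voxel spacing::

        u = d g_f / (|g_f|^2 + a^2 d^2) + d g_m / (|g_m|^2 + a^2 d^2)

    Components whose denominator falls below 1e-9 are set to zero (the
    regularized limit at vanishing gradient and mismatch).
    """
    cfg = cfg or DemonsConfig()
    if not fixed.same_geometry(warped_moving):
        raise ValueError("fixed and warped moving images must share a grid")
    f = fixed.data.astype(float)
    m = warped_moving.data.astype(float)
    d = m - f
    u = np.zeros(f.shape + (3,))
    for img in (f, m):
        g = np.stack(np.gradient(img, *fixed.spacing), axis=-1)
        denom = (g ** 2).sum(axis=-1) + cfg.alpha ** 2 * d ** 2
        ok = denom >= 1e-9
        w = np.zeros_like(d)
        w[ok] = d[ok] / denom[ok]
        u += w[..., None] * g
    return DisplacementField(u, fixed.spacing.copy(), fixed.origin.copy())


def gaussian_regularize(fld: DisplacementField, sigma_mm: float) -> DisplacementField:
    """Componentwise Gaussian smoothing with a physical-unit width."""
    if sigma_mm <= 0:
        raise ValueError("sigma must be positive")
    sig = sigma_mm / np.asarray(fld.spacing)
    out = np.empty_like(fld.vectors)
    for c in range(3):
        out[..., c] = gaussian_filter(fld.vectors[..., c], sigma=sig, mode="nearest")
    return DisplacementField(out, fld.spacing.copy(), fld.origin.copy())


def _downsample(data: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return data
    sm = gaussian_filter(data, sigma=factor / 2.0, mode="nearest")
    return sm[::factor, ::factor, ::factor]


def _upsample_field(field_mm: np.ndarray, new_shape, ratio: float) -> np.ndarray:
    """Resample a coarse field onto a finer grid.

    Pyramid grids are origin-aligned (coarse voxel i sits at fine voxel
    i * ratio), so fine index j samples the coarse field at j / ratio; an
    endpoint-aligned resizer would stretch the field by ~(n-1)/(n-ratio)
    and bias displacements far from the origin.
    """
    coords = np.indices(tuple(new_shape), dtype=float) / ratio
    return np.stack(
        [map_coordinates(field_mm[..., c], coords, order=1, mode="nearest") for c in range(3)],
        axis=-1,
    )


def _warp_image(data: np.ndarray, vectors_vox: np.ndarray, fill: float) -> np.ndarray:
    idx = np.indices(data.shape, dtype=float)
    coords = idx + np.moveaxis(vectors_vox, -1, 0)
    return map_coordinates(data, coords, order=1, mode="constant", cval=fill)


def register_demons(
    fixed: ImageVolume,
    moving: ImageVolume,
    init: RigidTransform3D | None = None,
    cfg: DemonsConfig | None = None,
    return_trace: bool = False,
):
    """Multi-resolution dual-force Demons registration.

    Runs coarse-to-fine over ``cfg.levels`` pyramid levels; at each level
    the loop warps the (rigidly initialized) moving image through the
    current field, evaluates the dual-force increment, updates the field
    against the residual mismatch and applies Gaussian regularization.
    Iteration stops early once the relative change of the mean squared
    intensity difference stays below ``cfg.tolerance`` for 3 consecutive
    iterations.

    Returns the *total* backward displacement field on the fixed grid —
    the rigid initialization is composed in, so sampling the original
    moving image at ``x + field(x)`` reproduces the registered image.
    With ``return_trace=True`` additionally returns the per-iteration mean
    squared difference trace (list of per-level lists).
    """
    cfg = cfg or DemonsConfig()
    init = init or RigidTransform3D(
        center_mm=fixed.origin + (np.asarray(fixed.shape) - 1) * fixed.spacing / 2.0
    )
    if not (np.all(np.isfinite(fixed.data)) and np.all(np.isfinite(moving.data))):
        raise ValueError("non-finite intensities in input images")

    lo, hi = cfg.clamp_hu
    f_full = np.clip(fixed.data.astype(float), lo, hi)
    moving_init = apply_rigid(
        ImageVolume(np.clip(moving.data.astype(float), lo, hi), moving.spacing, moving.origin),
        init,
        target=fixed,
        fill=lo,
    )
    m_full = moving_init.data
    if cfg.presmooth_vox > 0:
        f_full = gaussian_filter(f_full, sigma=cfg.presmooth_vox, mode="nearest")
        m_full = gaussian_filter(m_full, sigma=cfg.presmooth_vox, mode="nearest")
    # moving-domain support on the fixed grid: where the rigidly-initialized
    # moving image is padding (e.g. a shorter scan extent), the intensity
    # mismatch is unfixable and the force there would only distort the field
    domain_full = apply_rigid(
        ImageVolume(np.ones(moving.shape), moving.spacing, moving.origin),
        init, target=fixed, fill=0.0,
    ).data > 0.5

    trace: list[list[float]] = []
    field_mm = None
    prev_factor = None
    factors = [2 ** (cfg.levels - 1 - i) for i in range(cfg.levels)]
    factors = [f for f in factors if min(np.asarray(fixed.shape) // f) >= 4]
    if not factors:
        factors = [1]
    for factor in factors:
        f_lvl = _downsample(f_full, factor)
        m_lvl = _downsample(m_full, factor)
        d_lvl = _downsample(domain_full.astype(float), factor) > 0.5
        spacing_lvl = fixed.spacing * factor
        vol_f = ImageVolume(f_lvl, spacing_lvl, fixed.origin)
        if field_mm is None:
            field_mm = np.zeros(f_lvl.shape + (3,))
        else:
            # mm values are grid-independent; only the grid is refined
            field_mm = _upsample_field(field_mm, f_lvl.shape, prev_factor / factor)
        prev_factor = factor
        lvl_trace = []
        below = 0
        prev_msd = None
        best_msd = np.inf
        best_field = field_mm
        for _ in range(cfg.iterations):
            warped = _warp_image(m_lvl, field_mm / spacing_lvl, fill=lo)
            msd = float(((warped - f_lvl)[d_lvl] ** 2).mean()) if d_lvl.any() else 0.0
            if msd > best_msd * 1.05:
                # divergence guard: a level whose similarity worsens beyond
                # 5% of its best is stopped and reverted (near-aligned inputs
                # gain nothing from further iteration at this scale)
                field_mm = best_field
                break
            lvl_trace.append(msd)
            if msd < best_msd:
                best_msd = msd
                best_field = field_mm.copy()
            force = demons_force(vol_f, ImageVolume(warped, spacing_lvl, fixed.origin), cfg)
            force.vectors[~d_lvl] = 0.0
            # the summed passive+active force is ~twice the first-order
            # correction (each term ~ d/|grad|), so an undamped update
            # overshoots and rings at crisp boundaries: damp by step_factor
            field_mm = field_mm - cfg.step_factor * force.vectors
            # regularization floored at half a voxel of the current level:
            # far below that the smoothing does nothing and the coarse-level
            # field is free to random-walk
            sig = np.maximum(cfg.sigma_mm / spacing_lvl, 0.5)
            for c in range(3):
                field_mm[..., c] = gaussian_filter(field_mm[..., c], sigma=sig, mode="nearest")
            if prev_msd is not None:
                rel = abs(prev_msd - msd) / max(prev_msd, 1e-12)
                below = below + 1 if rel < cfg.tolerance else 0
                if below >= 3:
                    break
            prev_msd = msd
        trace.append(lvl_trace)

    # upsample final field to the full fixed grid
    if field_mm.shape[:3] != fixed.shape:
        field_mm = _upsample_field(field_mm, fixed.shape, prev_factor)

    # compose the rigid initialization: total(x) = T^{-1}(x + F(x)) - x
    world = np.moveaxis(np.indices(fixed.shape, dtype=float), 0, -1) * fixed.spacing + fixed.origin
    sample = world + field_mm
    if not init.is_identity():
        sample = init.inverse().apply(sample)
    total = DisplacementField(sample - world, fixed.spacing.copy(), fixed.origin.copy())
    if return_trace:
        return total, trace
    return total
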