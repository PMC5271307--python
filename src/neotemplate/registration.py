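"""Intensity-based affine and symmetric diffeomorphic registration.

Both registrars are implemented here rather than wrapped from a toolkit.

*Affine*: 12 parameters (translation, rotation, log-scale, shear) centred on
the fixed-image centroid, optimized by Powell's method over a 3-level
multiresolution pyramid with either mutual information (32-bin joint
histogram) or Pearson cross-correlation.  Deterministic: full-grid sampling,
no stochastic subsampling.

*Diffeomorphic*: a symmetric, greedy, field-smoothed scheme.  Each direction
runs compositive demons with symmetric intensity forces and Gaussian
regularization of both the update and the total field; the two directions
are averaged (forward with the inverse of the backward) so that swapping the
input images yields the mirrored result.  The returned transform carries
paired forward/inverse displacement fields whose composition is identity to
sub-voxel tolerance and whose Jacobian determinant is positive.  For the
multimodal (MI) case the moving image is first remapped through the joint-
histogram conditional mean so that the monomodal force model applies.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage, optimize

from .metrics import mutual_information, cross_correlation
from .transforms import (AffineTransform, DiffeoTransform, apply_transform,
                         invert_displacement_field)
from .volume import Volume

__all__ = ["AffineParams", "SynParams", "affine_register", "syn_register",
           "RegistrationError"]

logger = logging.getLogger(__name__)


class RegistrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# pyramids
# ---------------------------------------------------------------------------

def _downsample(vol: Volume, factor: int, smooth_vox: float) -> Volume:
    if factor == 1 and smooth_vox == 0:
        return vol
    data = vol.data.astype(float)
    if smooth_vox > 0:
        data = ndimage.gaussian_filter(data, smooth_vox)
    if factor > 1:
        data = data[::factor, ::factor, ::factor]
        return Volume(data, vol.spacing * factor, vol.origin.copy(),
                      vol.direction.copy())
    return vol.with_data(data)


def _metric_value(fixed: Volume, warped: Volume, metric: str,
                  bins: int) -> float:
    if metric == "MI":
        return mutual_information(fixed, warped, bins=bins)
    if metric == "CC":
        try:
            return cross_correlation(fixed, warped)
        except Exception:
            return -1.0
    raise ValueError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# affine
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AffineParams:
    levels: tuple = (4, 2, 1)
    smooth_vox: tuple = (2.0, 1.0, 0.0)
    max_iter: tuple = (100, 70, 40)
    bins: int = 32
    xtol: float = 1e-4


# parameter scales: mm, radians, log-scale, shear
_P_SCALE = np.array([1.0, 1.0, 1.0, 0.01, 0.01, 0.01,
                     0.01, 0.01, 0.01, 0.01, 0.01, 0.01])


def _params_to_affine(p: np.ndarray, centre: np.ndarray) -> AffineTransform:
    t = p[:3]
    ax, ay, az = p[3:6]
    rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)],
                   [0, np.sin(ax), np.cos(ax)]])
    ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0],
                   [-np.sin(ay), 0, np.cos(ay)]])
    rz = np.array([[np.cos(az), -np.sin(az), 0],
                   [np.sin(az), np.cos(az), 0], [0, 0, 1]])
    rot = rz @ ry @ rx
    scale = np.diag(np.exp(p[6:9]))
    shear = np.eye(3)
    shear[0, 1], shear[0, 2], shear[1, 2] = p[9:12]
    m = rot @ scale @ shear
    return AffineTransform(m, centre + t - m @ centre)


def _fixed_points(fixed: Volume) -> np.ndarray:
    idx = np.indices(fixed.shape).reshape(3, -1).T.astype(float)
    return fixed.index_to_world(idx)


def _warp_affine(moving: Volume, pts: np.ndarray, shape, t: AffineTransform
                 ) -> tuple[np.ndarray, np.ndarray]:
    src = moving.world_to_index(t.map_points(pts))
    coords = [src[:, k] for k in range(3)]
    vals = ndimage.map_coordinates(moving.data.astype(float), coords,
                                   order=1, mode="constant", cval=np.nan)
    inside = ~np.isnan(vals)
    return vals, inside


def affine_register(moving: Volume, fixed: Volume, metric: str = "MI",
                    init: AffineTransform | None = None,
                    params: AffineParams | None = None) -> AffineTransform:
    """12-parameter affine registration maximizing MI or CC.

    The returned transform pulls fixed-space points to moving-space points
    and never scores below ``init`` under the chosen metric on the full-
    resolution grid.
    """
    params = params or AffineParams()
    init = init or AffineTransform.identity()

    def objective_factory(fx: Volume, mv: Volume):
        pts = _fixed_points(fx)
        fvals = fx.data.astype(float).ravel()
        centre = fx.index_to_world((np.asarray(fx.shape) - 1) / 2.0)

        def value_of(t: AffineTransform) -> float:
            vals, inside = _warp_affine(mv, pts, fx.shape, t)
            if inside.sum() < max(32, 0.01 * inside.size):
                return -np.inf
            a = fvals[inside]
            b = vals[inside]
            if metric == "MI":
                h, _, _ = np.histogram2d(a, b, bins=params.bins)
                p = h / h.sum()
                px = p.sum(1)
                py = p.sum(0)
                nz = p > 0
                return float((p[nz] * np.log2(p[nz]
                             / np.outer(px, py)[nz])).sum())
            av = a - a.mean()
            bv = b - b.mean()
            den = np.sqrt((av @ av) * (bv @ bv))
            return float(av @ bv / den) if den > 0 else -1.0

        def objective(ps: np.ndarray, base: AffineTransform) -> float:
            try:
                t = base.compose_affine(
                    _params_to_affine(ps * _P_SCALE, centre))
            except ValueError:  # non-positive determinant during search
                return np.inf
            v = value_of(t)
            return -v if np.isfinite(v) else 1e6

        return value_of, objective, centre

    # fail fast on non-overlapping fields of view at the initial transform
    coarse_f = _downsample(fixed, params.levels[0], params.smooth_vox[0])
    coarse_m = _downsample(moving, params.levels[0], params.smooth_vox[0])
    val0, _, _ = objective_factory(coarse_f, coarse_m)
    if not np.isfinite(val0(init)):
        raise RegistrationError("no field-of-view overlap at init")

    current = init
    for factor, sm, maxit in zip(params.levels, params.smooth_vox,
                                 params.max_iter):
        fx = _downsample(fixed, factor, sm)
        mv = _downsample(moving, factor, sm)
        _, objective, _ = objective_factory(fx, mv)
        res = optimize.minimize(objective, np.zeros(12), args=(current,),
                                method="Powell",
                                options={"maxiter": maxit,
                                         "xtol": params.xtol,
                                         "ftol": 1e-6})
        centre = fx.index_to_world((np.asarray(fx.shape) - 1) / 2.0)
        current = current.compose_affine(
            _params_to_affine(res.x * _P_SCALE, centre))

    # guarantee: final metric >= init metric at full resolution
    value_of, _, _ = objective_factory(fixed, moving)
    if value_of(current) < value_of(init):
        logger.warning("affine optimization did not improve; returning init")
        return init
    return current


# ---------------------------------------------------------------------------
# symmetric diffeomorphic (demons-style)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SynParams:
    levels: tuple = (4, 2, 1)
    smooth_vox: tuple = (2.0, 1.0, 0.0)
    iterations: tuple = (60, 40, 20)
    step_vox: float = 0.6           # max update magnitude, voxels
    sigma_update_vox: float = 1.0   # fluid-like regularization
    sigma_field_vox: float = 1.0    # elastic-like regularization
    bins: int = 32                  # MI remapping histogram
    mi_remap_every: int = 5
    divergence_patience: int = 5


def _conditional_mean_remap(fixed: np.ndarray, moving_aligned: np.ndarray,
                            moving: np.ndarray, bins: int) -> np.ndarray:
    """Remap moving intensities to E[fixed | moving-bin] (multimodal bridge).

    The bin-to-mean mapping is estimated from the *currently aligned* pair
    (``fixed``, ``moving_aligned``) and then applied to the un-warped moving
    image, so the force model sees pseudo-monomodal intensities that improve
    as alignment improves.
    """
    lo, hi = float(moving.min()), float(moving.max()) + 1e-9
    edges = np.linspace(lo, hi, bins + 1)
    which_al = np.clip(np.digitize(moving_aligned.ravel(), edges) - 1,
                       0, bins - 1)
    sums = np.bincount(which_al, weights=fixed.ravel(), minlength=bins)
    cnts = np.bincount(which_al, minlength=bins)
    means = np.where(cnts > 0, sums / np.maximum(cnts, 1), 0.0)
    which = np.clip(np.digitize(moving.ravel(), edges) - 1, 0, bins - 1)
    return means[which].reshape(moving.shape)


def _warp_by_field(data: np.ndarray, field: np.ndarray,
                   grid: Volume) -> np.ndarray:
    idx = np.indices(grid.shape).reshape(3, -1).T.astype(float)
    pts = grid.index_to_world(idx) + field.reshape(-1, 3)
    src = grid.world_to_index(pts)
    return ndimage.map_coordinates(data, [src[:, k] for k in range(3)],
                                   order=1, mode="nearest"
                                   ).reshape(grid.shape)


def _demons_direction(fixed: Volume, moving: Volume, metric: str,
                      params: SynParams) -> np.ndarray:
    """Greedy compositive demons moving->fixed; returns mm field on fixed grid."""
    field = None
    for factor, sm, iters in zip(params.levels, params.smooth_vox,
                                 params.iterations):
        fx = _downsample(fixed, factor, sm)
        mv = _downsample(moving, factor, sm)
        fdat = fx.data.astype(float)
        if field is None:
            field = np.zeros(tuple(fx.shape) + (3,))
        else:
            field = _upsample_field(field, prev_grid, fx)
        prev_grid = fx

        h = float(fx.spacing.min())
        max_step = params.step_vox * h
        mdat = mv.data.astype(float)
        best = (-np.inf, field.copy())
        worse = 0
        remap = mdat
        for it in range(iters):
            if metric == "MI" and it % params.mi_remap_every == 0:
                warped_raw = _warp_by_field(mdat, field, fx)
                remap = _conditional_mean_remap(fdat, warped_raw, mdat,
                                                params.bins)
            warped = _warp_by_field(remap, field, fx)
            diff = fdat - warped
            gf = np.stack(np.gradient(fdat, *fx.spacing), axis=-1)
            gw = np.stack(np.gradient(warped, *fx.spacing), axis=-1)
            grad = 0.5 * (gf + gw)
            gmag2 = (grad ** 2).sum(-1)
            denom = gmag2 + (diff / h) ** 2 + 1e-12
            upd = (diff / denom)[..., None] * grad
            mag = np.sqrt((upd ** 2).sum(-1))
            scale = np.minimum(1.0, max_step / np.maximum(mag, 1e-12))
            upd *= scale[..., None]
            for k in range(3):
                upd[..., k] = ndimage.gaussian_filter(
                    upd[..., k], params.sigma_update_vox)
            # compositive update: phi <- phi o (id + upd)
            new_field = upd.copy()
            for k in range(3):
                new_field[..., k] += _warp_by_field(field[..., k], upd, fx)
                new_field[..., k] = ndimage.gaussian_filter(
                    new_field[..., k], params.sigma_field_vox)
            field = new_field
            # divergence guard on the similarity trace
            m = _metric_value(fx, fx.with_data(_warp_by_field(remap, field,
                                                              fx)),
                              "CC" if metric == "MI" else metric, params.bins)
            if m > best[0]:
                best = (m, field.copy())
                worse = 0
            else:
                worse += 1
                if worse >= params.divergence_patience:
                    logger.warning("demons: metric worsened %d times at "
                                   "level %d; reverting to best", worse,
                                   factor)
                    field = best[1]
                    break
        field = best[1] if best[0] > -np.inf else field
    if params.levels[-1] != 1:  # schedule may stop above full resolution
        field = _upsample_field(field, prev_grid, fixed)
    return field


def _upsample_field(field: np.ndarray, coarse: Volume,
                    fine: Volume) -> np.ndarray:
    idx = np.indices(fine.shape).reshape(3, -1).T.astype(float)
    pts = fine.index_to_world(idx)
    src = coarse.world_to_index(pts)
    out = np.stack([
        ndimage.map_coordinates(field[..., k],
                                [src[:, j] for j in range(3)], order=1,
                                mode="nearest") for k in range(3)], axis=-1)
    return out.reshape(tuple(fine.shape) + (3,))


def syn_register(moving: Volume, fixed: Volume, metric: str = "CC",
                 params: SynParams | None = None) -> DiffeoTransform:
    """Symmetric diffeomorphic registration of affinely pre-aligned images.

    Runs greedy demons in both directions and averages the forward field
    with the inverse of the backward field, so exchanging the two images
    yields the mirrored transform.  The inverse field is recomputed by
    fixed-point inversion to sub-voxel consistency.
    """
    params = params or SynParams()
    if moving.shape != fixed.shape or not np.allclose(moving.spacing,
                                                      fixed.spacing):
        moving = apply_transform(moving, AffineTransform.identity(),
                                 reference=fixed,
                                 fill=float(moving.data.min()))
    u_fwd = _demons_direction(fixed, moving, metric, params)
    u_bwd = _demons_direction(moving, fixed, metric, params)
    inv_bwd = invert_displacement_field(u_bwd, fixed)
    forward = 0.5 * (u_fwd + inv_bwd)
    inverse = invert_displacement_field(forward, fixed)
    return DiffeoTransform(forward, inverse, fixed)
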