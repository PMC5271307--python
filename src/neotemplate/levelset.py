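"""Coupled level-set extraction of the intracranial region from neonatal CT.

Two geodesic-active-contour surfaces evolve on signed-distance functions:
an *exterior* surface initialized at the head boundary that shrinks inward,
and an *interior* surface initialized deep inside the head that grows
outward.  Both are slowed by an edge-stopping function computed from the CT
gradient, so the exterior surface halts at the outer (convex) surface of the
cranial bones and the interior surface at the inner (concave) surface.
Where bone is absent — fontanels and sutures — there is no edge to stop at;
there the two surfaces approach each other and a soft coupling gate drives
their speeds to zero before they can cross, closing the intracranial
boundary smoothly across the gaps.  A hard clamp (``phi_in >= phi_out``)
guarantees non-crossing at every iteration.

The interior region of the converged interior surface, hole-filled, is the
intracranial mask.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage

from .volume import BinaryMask, Volume
from .preprocess import SegmentationError

__all__ = ["LevelSetParams", "LevelSetPair", "init_coupled_surfaces",
           "evolve_coupled_levelsets", "intracranial_mask_from_surfaces",
           "segment_intracranial"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class LevelSetParams:
    """Evolution parameters (all lengths in mm, intensities in HU)."""

    balloon_speed: float = 1.0        # outward/inward propagation speed
    curvature_weight: float = 0.3     # smoothing strength
    edge_attraction: float = 2.0      # advection toward edges (grad g term)
    edge_sigma_mm: float = 2.0        # pre-smoothing for the edge map
    edge_lambda: float = 50.0         # gradient scale in g = 1/(1+|∇I|²/λ²)
    bone_threshold_hu: float = 300.0  # region term: fronts cannot enter bone
    bone_width_hu: float = 100.0      # softness of the bone region term
    touch_mm: float | None = None     # coupling distance; default 1 voxel
    soft_mm: float = 3.0              # width of the soft coupling gate
    band_mm: float | None = None      # narrow-band half width; default 6 vox
    reinit_every: int = 10            # fast reinitialization period
    max_iters: int = 300
    min_iters: int = 20               # no convergence check before this
    tol: float = 1e-3                 # mean |Δφ| (mm) on the front band
    stable_iters: int = 12            # stop after this many sign-stable steps


@dataclasses.dataclass
class LevelSetPair:
    """Interior/exterior signed-distance functions (negative inside)."""

    phi_in: np.ndarray
    phi_out: np.ndarray
    grid: Volume
    iteration: int = 0
    touched: np.ndarray | None = None
    converged: bool = False
    history: list = dataclasses.field(default_factory=list)
    # rows: (iteration, front band change mm, touched-voxel count)

    def interior_region(self) -> np.ndarray:
        return self.phi_in < 0

    def exterior_region(self) -> np.ndarray:
        return self.phi_out < 0


def _signed_distance(region: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance in mm, negative inside ``region``."""
    inside = ndimage.distance_transform_edt(region, sampling=spacing)
    outside = ndimage.distance_transform_edt(~region, sampling=spacing)
    return outside - inside


def init_coupled_surfaces(ct: Volume, head: BinaryMask,
                          inner_erosion_mm: float = 15.0) -> LevelSetPair:
    """Initialize the pair from the head-shape prior.

    Exterior surface: the head boundary itself.  Interior surface: the head
    eroded by ``inner_erosion_mm``, chosen large enough to start inside the
    cranial cavity (beyond scalp + skull).
    """
    hb = head.as_bool()
    if not hb.any():
        raise ValueError("empty head mask")
    spacing = ct.spacing
    dist_inside = ndimage.distance_transform_edt(hb, sampling=spacing)
    interior = dist_inside > inner_erosion_mm
    if not interior.any():
        raise ValueError(
            f"inner_erosion_mm={inner_erosion_mm} erodes the head away")
    phi_out = _signed_distance(hb, spacing)
    phi_in = _signed_distance(interior, spacing)
    # non-crossing by construction; clamp anyway for exactness
    phi_in = np.maximum(phi_in, phi_out)
    return LevelSetPair(phi_in=phi_in, phi_out=phi_out, grid=ct)


def _edge_stopping(ct: Volume, params: "LevelSetParams") -> np.ndarray:
    """Combined edge/region stopping map, near 0 at and inside cranial bone.

    The gradient factor ``1/(1+|∇(G_σ*I)|²/λ²)`` vanishes at bone *edges*;
    the region factor, a soft step on the smoothed intensity, vanishes on the
    bone *plateau* itself, so a front cannot tunnel through the skull between
    its two edges.  Soft tissue (low HU, low gradient) has g ≈ 1.
    """
    sigma_vox = params.edge_sigma_mm / ct.spacing
    smoothed = ndimage.gaussian_filter(ct.data.astype(float), sigma_vox)
    grads = np.gradient(smoothed, *ct.spacing)
    gmag2 = sum(g ** 2 for g in grads)
    g_edge = 1.0 / (1.0 + gmag2 / params.edge_lambda ** 2)
    arg = np.clip((smoothed - params.bone_threshold_hu)
                  / params.bone_width_hu, -50.0, 50.0)
    g_region = 1.0 / (1.0 + np.exp(arg))
    return g_edge * g_region


def _upwind_gradnorm(phi: np.ndarray, spacing: np.ndarray,
                     positive_speed: bool) -> np.ndarray:
    """Godunov upwind |∇φ| for motion with speed of a fixed sign."""
    out = np.zeros_like(phi)
    for ax in range(3):
        h = spacing[ax]
        fwd = (np.roll(phi, -1, axis=ax) - phi) / h
        bwd = (phi - np.roll(phi, 1, axis=ax)) / h
        if positive_speed:
            out += np.maximum(bwd, 0) ** 2 + np.minimum(fwd, 0) ** 2
        else:
            out += np.minimum(bwd, 0) ** 2 + np.maximum(fwd, 0) ** 2
    return np.sqrt(out)


def _curvature_term(phi: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """κ|∇φ| via central differences (mean-curvature motion term)."""
    grads = np.gradient(phi, *spacing)
    mag = np.sqrt(sum(g ** 2 for g in grads)) + 1e-8
    div = sum(np.gradient(grads[k] / mag, spacing[k], axis=k)
              for k in range(3))
    return div * mag


def _advect(phi: np.ndarray, vel: list[np.ndarray],
            spacing: np.ndarray) -> np.ndarray:
    """Upwinded v·∇φ (edge-attraction transport term)."""
    out = np.zeros_like(phi)
    for ax in range(3):
        h = spacing[ax]
        fwd = (np.roll(phi, -1, axis=ax) - phi) / h
        bwd = (phi - np.roll(phi, 1, axis=ax)) / h
        out += np.maximum(vel[ax], 0) * bwd + np.minimum(vel[ax], 0) * fwd
    return out


def evolve_coupled_levelsets(ct: Volume, pair: LevelSetPair,
                             params: LevelSetParams | None = None
                             ) -> LevelSetPair:
    """Run the coupled evolution until convergence or the iteration cap.

    Per iteration: interior expands / exterior shrinks at speed
    ``g · gate · balloon``, regularized by curvature, attracted to edges by
    the ∇g transport term; the coupling gate vanishes as the surfaces come
    within ``touch_mm`` of each other.  Non-crossing is enforced exactly
    (``phi_in >= phi_out``).  A convergence warning (not an error) is logged
    if the cap is reached; the state is returned either way.
    """
    params = params or LevelSetParams()
    spacing = ct.spacing
    h = float(np.min(spacing))
    touch = params.touch_mm if params.touch_mm is not None else h
    band = params.band_mm if params.band_mm is not None else 6.0 * h

    g = _edge_stopping(ct, params)
    # clip the attraction velocity so a sharp edge map cannot shrink the CFL
    # step; the clip moves no stationary point of the transport term
    grad_g = [np.clip(gg, -0.5, 0.5) for gg in np.gradient(g, *spacing)]
    eta = params.edge_attraction

    phi_in = pair.phi_in.astype(float).copy()
    phi_out = pair.phi_out.astype(float).copy()

    # explicit-step CFL bound: balloon + attraction speeds in mm/iter
    vmax = params.balloon_speed + eta * max(
        float(np.abs(gg).max()) for gg in grad_g) + 1e-9
    dt = 0.45 * h / vmax
    converged = False
    stable = 0
    it = 0
    history: list = []
    for it in range(1, params.max_iters + 1):
        band_in = np.abs(phi_in) < band
        band_out = np.abs(phi_out) < band

        gate_in = np.clip(((-phi_out) - touch) / params.soft_mm, 0.0, 1.0)
        gate_out = np.clip((phi_in - touch) / params.soft_mm, 0.0, 1.0)

        # interior: expand outward (phi decreases at the front)
        speed_in = params.balloon_speed * g * gate_in
        upd_in = (-speed_in * _upwind_gradnorm(phi_in, spacing, True)
                  + params.curvature_weight * g
                  * _curvature_term(phi_in, spacing)
                  + eta * _advect(phi_in, grad_g, spacing))
        # exterior: shrink inward (phi increases at the front)
        speed_out = params.balloon_speed * g * gate_out
        upd_out = (speed_out * _upwind_gradnorm(phi_out, spacing, False)
                   + params.curvature_weight * g
                   * _curvature_term(phi_out, spacing)
                   + eta * _advect(phi_out, grad_g, spacing))

        new_in = phi_in + dt * np.where(band_in, upd_in, 0.0)
        new_out = phi_out + dt * np.where(band_out, upd_out, 0.0)
        # hard non-crossing clamp: interior region stays inside exterior
        new_in = np.maximum(new_in, new_out)

        # front change: Δφ on the 1-voxel band around either zero level,
        # plus region-membership (sign) changes anywhere
        front = (np.abs(phi_in) <= 1.5 * h) | (np.abs(phi_out) <= 1.5 * h)
        n_front = max(int(front.sum()), 1)
        delta = (float(np.abs(new_in - phi_in)[front].sum())
                 + float(np.abs(new_out - phi_out)[front].sum())) / n_front
        flips = int((((new_in < 0) != (phi_in < 0))
                     | ((new_out < 0) != (phi_out < 0))).sum())
        phi_in, phi_out = new_in, new_out

        if it % params.reinit_every == 0:
            phi_in = _signed_distance(phi_in < 0, spacing)
            phi_out = _signed_distance(phi_out < 0, spacing)
            phi_in = np.maximum(phi_in, phi_out)
        history.append((it, delta,
                        int(((np.abs(phi_in) <= h)
                             & ((phi_in - phi_out) <= touch + h)).sum())))
        stable = stable + 1 if flips == 0 else 0
        if it >= params.min_iters and (delta < params.tol
                                       or stable >= params.stable_iters):
            converged = True
            break
    if not converged:
        logger.warning("coupled level sets: iteration cap %d reached "
                       "(last band change %.2e mm)", params.max_iters, delta)

    phi_in = _signed_distance(phi_in < 0, spacing)
    phi_out = _signed_distance(phi_out < 0, spacing)
    phi_in = np.maximum(phi_in, phi_out)
    touched = (np.abs(phi_in) <= h) & ((phi_in - phi_out) <= touch + h)
    return LevelSetPair(phi_in=phi_in, phi_out=phi_out, grid=ct,
                        iteration=pair.iteration + it, touched=touched,
                        converged=converged, history=pair.history + history)


def intracranial_mask_from_surfaces(pair: LevelSetPair) -> BinaryMask:
    """Hole-filled region enclosed by the interior surface, largest component."""
    region = pair.interior_region()
    if not region.any():
        raise SegmentationError("interior surface encloses no voxels")
    region = ndimage.binary_fill_holes(region)
    lab, n = ndimage.label(region)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab,
                                   index=np.arange(1, n + 1))
        region = lab == (int(np.argmax(sizes)) + 1)
    return BinaryMask.from_bool(region, pair.grid)


def segment_intracranial(ct: Volume, head: BinaryMask,
                         params: LevelSetParams | None = None,
                         inner_erosion_mm: float = 15.0,
                         add_mask: BinaryMask | None = None,
                         remove_mask: BinaryMask | None = None
                         ) -> tuple[BinaryMask, LevelSetPair]:
    """End-to-end intracranial extraction; optional manual-style correction.

    ``add_mask``/``remove_mask`` stand in for the expert revision step:
    voxels are merged by union / subtraction after the automatic result.
    """
    pair = init_coupled_surfaces(ct, head, inner_erosion_mm)
    pair = evolve_coupled_levelsets(ct, pair, params)
    mask = intracranial_mask_from_surfaces(pair)
    region = mask.as_bool() & head.as_bool()
    if add_mask is not None:
        region |= add_mask.as_bool()
    if remove_mask is not None:
        region &= ~remove_mask.as_bool()
    return BinaryMask.from_bool(region, ct), pair
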