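"""Synthetic neonatal head CT/MR phantoms with ground truth.

The anatomy is a nest of ellipsoids — scalp, cranial bone shell, CSF rim,
cortical grey matter, white-matter core — with fontanel gaps cut through the
bone shell as angular sectors, mimicking the unfused plates of a neonatal
skull.  The CT channel uses approximate Hounsfield values (bone +1000,
water/CSF near 0–15, WM 20–30, GM 37–45, air −1000) and reproduces the two
nuisance features that make clinical neonatal CT hard to register: soft
blobs outside the head (pillow, pacifier) and an artificial −3000 HU rim
around the air.  The MR-like channel inverts the contrast (bone dark, brain
mid-bright, range 0–1023), reproducing the CT/MR modality gap.

Populations are built by perturbing a known mean anatomy with a random rigid
motion plus a smoothed random (diffeomorphic) warp, so every subject carries
its generating transform as ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
from scipy import ndimage

from .transforms import (CompositeTransform, DiffeoTransform,
                         apply_transform, invert_displacement_field,
                         jacobian_determinant)
from .volume import BinaryMask, Volume, write_volume

__all__ = ["PhantomSpec", "PhantomSet", "generate_head_phantom",
           "generate_population", "write_phantom_set"]

logger = logging.getLogger(__name__)

# integer anatomy labels
_AIR, _SCALP, _BONE, _FONTANEL, _CSF, _GM, _WM = range(7)

#: MR-like intensity per label (arbitrary units, 0-1023; bone dark,
#: brain mid-bright — the inverse of the CT contrast)
MR_MEANS = {_AIR: 10.0, _SCALP: 350.0, _BONE: 60.0, _FONTANEL: 320.0,
            _CSF: 160.0, _GM: 420.0, _WM: 520.0}


@dataclasses.dataclass
class PhantomSpec:
    """Geometry, intensities and noise of one synthetic head.

    Radii/thicknesses in mm, intensities in HU.  ``fontanel_gaps`` is a list
    of ``(direction, angular_width_deg)`` pairs; each cuts a conical sector
    out of the bone shell.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    head_radii: tuple[float, float, float] = (42.0, 50.0, 46.0)
    skull_thickness: float = 5.0
    scalp_thickness: float = 5.0
    csf_thickness: float = 4.0
    gm_thickness: float = 6.0
    fontanel_gaps: tuple = (((0.0, 0.3, 1.0), 35.0),
                            ((0.0, -1.0, 0.35), 25.0))
    tissue_hu: dict = dataclasses.field(default_factory=lambda: {
        "air": -1000.0, "csf": 15.0, "wm": 25.0, "gm": 41.0,
        "bone": 1000.0, "scalp": 30.0})
    noise_sd: float = 8.0
    rim_value: float = -3000.0
    nuisance_blobs: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        hu = np.array(list(self.tissue_hu.values()))
        if np.any(np.abs(hu) > 3100):
            raise ValueError("tissue_hu outside plausible CT range ±3100")
        if self.skull_thickness >= min(self.head_radii):
            raise ValueError("skull_thickness must be < min(head_radii)")
        for _, width in self.fontanel_gaps:
            if not 0.0 < width < 90.0:
                raise ValueError(f"fontanel width {width} not in (0, 90) deg")
        half_extent = (np.asarray(self.spacing)
                       * np.asarray(self.grid_shape)) / 2.0
        if np.any(np.asarray(self.head_radii) >= half_extent):
            raise ValueError("head_radii exceed the grid extent")


@dataclasses.dataclass
class PhantomSet:
    """One synthetic subject: CT, MR, ground-truth masks, generating transform."""

    ct: Volume
    mr: Volume
    masks: dict
    true_transform: CompositeTransform
    spec: PhantomSpec
    labels: Volume  # integer anatomy labels (ground truth)


# ---------------------------------------------------------------------------
# label-map construction
# ---------------------------------------------------------------------------

def _centered_grid(spec: PhantomSpec) -> Volume:
    shape = np.asarray(spec.grid_shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    origin = -(shape - 1) / 2.0 * spacing
    return Volume(np.zeros(spec.grid_shape), spacing, origin, np.eye(3))


def _world_coords(grid: Volume) -> np.ndarray:
    """(3, nx, ny, nz) world-mm coordinates of every voxel centre."""
    idx = np.indices(grid.shape).astype(float)
    spacing = grid.spacing
    return np.stack([idx[k] * spacing[k] + grid.origin[k] for k in range(3)])


def _inside_ellipsoid(xyz: np.ndarray, radii: np.ndarray) -> np.ndarray:
    radii = np.maximum(radii, 1e-6)
    rho2 = sum((xyz[k] / radii[k]) ** 2 for k in range(3))
    return rho2 <= 1.0


def _label_map(spec: PhantomSpec, grid: Volume) -> np.ndarray:
    xyz = _world_coords(grid)
    radii = np.asarray(spec.head_radii, dtype=float)
    head = _inside_ellipsoid(xyz, radii)
    skull_outer = _inside_ellipsoid(xyz, radii - spec.scalp_thickness)
    intracranial = _inside_ellipsoid(
        xyz, radii - spec.scalp_thickness - spec.skull_thickness)
    brain = _inside_ellipsoid(
        xyz, radii - spec.scalp_thickness - spec.skull_thickness
        - spec.csf_thickness)
    wm_core = _inside_ellipsoid(
        xyz, radii - spec.scalp_thickness - spec.skull_thickness
        - spec.csf_thickness - spec.gm_thickness)

    labels = np.full(grid.shape, _AIR, dtype=np.int16)
    labels[head] = _SCALP
    shell = skull_outer & ~intracranial
    labels[shell] = _BONE
    # fontanel sectors: conical cuts through the bone shell
    r = np.sqrt(np.maximum(sum(xyz[k] ** 2 for k in range(3)), 1e-12))
    for direction, width in spec.fontanel_gaps:
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        cosang = sum(xyz[k] * d[k] for k in range(3)) / r
        cone = cosang >= np.cos(np.deg2rad(width / 2.0))
        labels[shell & cone] = _FONTANEL
    labels[intracranial] = _CSF
    labels[brain] = _GM
    labels[wm_core] = _WM
    return labels


def _masks_from_labels(labels: np.ndarray, grid: Volume) -> dict:
    mk = lambda b: BinaryMask.from_bool(b, grid)
    return {
        "head": mk(labels != _AIR),
        "skull": mk(labels == _BONE),
        "fontanels": mk(labels == _FONTANEL),
        "intracranial": mk(labels >= _CSF),
        "brain": mk(labels >= _GM),
        "csf": mk(labels == _CSF),
    }


def _synthesize_images(labels: np.ndarray, spec: PhantomSpec, grid: Volume,
                       rng: np.random.Generator) -> tuple[Volume, Volume]:
    hu = spec.tissue_hu
    ct_means = {_AIR: hu["air"], _SCALP: hu["scalp"], _BONE: hu["bone"],
                _FONTANEL: hu["scalp"], _CSF: hu["csf"], _GM: hu["gm"],
                _WM: hu["wm"]}
    ct = np.empty(grid.shape, dtype=float)
    mr = np.empty(grid.shape, dtype=float)
    for lab, mean in ct_means.items():
        sel = labels == lab
        ct[sel] = mean
        mr[sel] = MR_MEANS[lab]

    xyz = _world_coords(grid)
    head = labels != _AIR

    # nuisance blobs (pillow / pacifier): soft-tissue spheres outside the head
    radii = np.asarray(spec.head_radii, dtype=float)
    half_extent = grid.spacing * np.asarray(grid.shape) / 2.0
    rim_radii = half_extent * 0.93
    for _ in range(spec.nuisance_blobs):
        for _attempt in range(50):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            blob_r = rng.uniform(5.0, 9.0)
            head_r = 1.0 / np.sqrt(sum((d[k] / radii[k]) ** 2
                                       for k in range(3)))
            centre = d * (head_r + blob_r + 6.0)
            rim_r = 1.0 / np.sqrt(sum((d[k] / rim_radii[k]) ** 2
                                      for k in range(3)))
            if np.linalg.norm(centre) + blob_r < rim_r - 4.0:
                break
        blob = sum((xyz[k] - centre[k]) ** 2 for k in range(3)) <= blob_r ** 2
        blob &= ~head
        ct[blob] = 60.0
        mr[blob] = 300.0

    # additive noise everywhere inside the field of view
    ct += rng.normal(0.0, spec.noise_sd, size=grid.shape)
    mr += rng.normal(0.0, max(spec.noise_sd, 1e-9) * 2.0, size=grid.shape)
    mr = np.clip(mr, 0.0, 1023.0)

    # artificial rim around the air, one voxel thick, at rim_value exactly
    rho = np.sqrt(sum((xyz[k] / rim_radii[k]) ** 2 for k in range(3)))
    mean_r = float(np.mean(rim_radii))
    rim = np.abs((rho - 1.0) * mean_r) <= float(np.min(grid.spacing)) / 1.9
    ct[rim & ~head] = spec.rim_value

    return grid.with_data(ct), grid.with_data(mr)


def generate_head_phantom(spec: PhantomSpec) -> PhantomSet:
    """Build one phantom; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    grid = _centered_grid(spec)
    labels = _label_map(spec, grid)
    ct, mr = _synthesize_images(labels, spec, grid, rng)
    return PhantomSet(ct=ct, mr=mr, masks=_masks_from_labels(labels, grid),
                      true_transform=CompositeTransform([]),
                      spec=spec, labels=grid.with_data(labels))


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------

def _rotation_matrix(angles_deg: np.ndarray) -> np.ndarray:
    ax, ay, az = np.deg2rad(angles_deg)
    rx = np.array([[1, 0, 0],
                   [0, np.cos(ax), -np.sin(ax)],
                   [0, np.sin(ax), np.cos(ax)]])
    ry = np.array([[np.cos(ay), 0, np.sin(ay)],
                   [0, 1, 0],
                   [-np.sin(ay), 0, np.cos(ay)]])
    rz = np.array([[np.cos(az), -np.sin(az), 0],
                   [np.sin(az), np.cos(az), 0],
                   [0, 0, 1]])
    return rz @ ry @ rx


def _random_subject_field(grid: Volume, rigid_sd: tuple[float, float],
                          warp_sd: float, warp_smoothness: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Displacement field of a random rigid motion plus a smooth random warp."""
    xyz = _world_coords(grid)
    mm_sd, deg_sd = rigid_sd
    rot = _rotation_matrix(rng.normal(0.0, deg_sd, size=3))
    trans = rng.normal(0.0, mm_sd, size=3)
    pts = np.stack(xyz, axis=-1)
    rigid_disp = pts @ rot.T + trans - pts

    warp = np.zeros_like(rigid_disp)
    if warp_sd > 0:
        sigma_vox = warp_smoothness / grid.spacing
        for k in range(3):
            noise = rng.normal(size=grid.shape)
            warp[..., k] = ndimage.gaussian_filter(noise, sigma_vox)
        mag = np.sqrt((warp ** 2).sum(axis=-1))
        mean_mag = mag.mean()
        if mean_mag > 0:
            warp *= warp_sd / mean_mag
    return rigid_disp + warp


def generate_population(mean_spec: PhantomSpec, n: int,
                        rigid_sd: tuple[float, float] = (3.0, 5.0),
                        warp_sd: float = 3.0, warp_smoothness: float = 12.0,
                        seed: int = 0) -> list[PhantomSet]:
    """``n`` subjects as random diffeomorphic perturbations of a mean anatomy.

    Each subject's ``true_transform`` maps its own grid onto the mean
    anatomy (pull convention), so warping any mean-anatomy image or mask
    through it reproduces the subject.  Warps are guaranteed invertible: a
    field whose Jacobian determinant is not everywhere positive is damped
    and regenerated.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    grid = _centered_grid(mean_spec)
    mean_labels = _label_map(mean_spec, grid)
    mean_label_vol = grid.with_data(mean_labels)

    subjects = []
    for i in range(n):
        sub_rng = np.random.default_rng(rng.integers(0, 2 ** 31 - 1))
        amplitude = 1.0
        while True:
            field = _random_subject_field(
                grid, (rigid_sd[0] * amplitude, rigid_sd[1] * amplitude),
                warp_sd * amplitude, warp_smoothness, sub_rng)
            if float(jacobian_determinant(field, grid).min()) > 0:
                break
            amplitude *= 0.7
            logger.warning("subject %d: folded warp, damping to %.2f",
                           i, amplitude)
        if rigid_sd == (0.0, 0.0) and warp_sd == 0.0:
            field = np.zeros_like(field)
        inverse = invert_displacement_field(field, grid)
        diffeo = DiffeoTransform(field, inverse, grid)
        true_t = CompositeTransform([diffeo])

        warped_labels = apply_transform(mean_label_vol, true_t,
                                        interp="nearest", fill=_AIR)
        labels = warped_labels.data.astype(np.int16)
        ct, mr_vol = _synthesize_images(labels, mean_spec, grid, sub_rng)
        subjects.append(PhantomSet(
            ct=ct, mr=mr_vol, masks=_masks_from_labels(labels, grid),
            true_transform=true_t, spec=mean_spec,
            labels=grid.with_data(labels)))
    return subjects


def write_phantom_set(ps: PhantomSet, out_dir: str | Path) -> None:
    """Write CT, MR and masks as NIfTI plus a JSON sidecar with spec and seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(ps.ct, out / "ct.nii.gz")
    write_volume(ps.mr, out / "mr.nii.gz")
    write_volume(ps.labels, out / "labels.nii.gz")
    for name, mask in ps.masks.items():
        write_volume(mask, out / f"mask_{name}.nii.gz")
    sidecar = dataclasses.asdict(ps.spec)
    sidecar["fontanel_gaps"] = [[list(d), w]
                                for d, w in sidecar["fontanel_gaps"]]
    (out / "phantom.json").write_text(json.dumps(sidecar, indent=2))
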