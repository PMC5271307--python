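"""3D volumes with explicit grid geometry: I/O, resampling, smoothing, rigid init.

Conventions used throughout the package
---------------------------------------
* World coordinates are RAS, in millimetres.
* Voxel indices are 0-based; the world position of voxel ``i`` is
  ``origin + direction @ diag(spacing) @ i`` (voxel *centres*, not corners).
* NIfTI-1 is the on-disk format; the header affine is honoured exactly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "resample_isotropic",
    "gaussian_smooth",
    "rigid_initialize",
    "fwhm_to_sigma",
]

#: FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a full-width-at-half-maximum to the Gaussian standard deviation."""
    return float(fwhm) / _FWHM_FACTOR


class GeometryError(ValueError):
    """Two volumes that must share a grid do not."""


class FormatError(IOError):
    """A file exists but is not a readable 3D NIfTI volume."""


class DegenerateInputError(ValueError):
    """An input lacks the variation the operation requires (e.g. constant image)."""


@dataclasses.dataclass
class Volume:
    """A 3D scalar image together with its grid geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities (HU for CT, arbitrary units for MR).
    spacing : ndarray, shape (3,)
        Voxel size in mm along each voxel axis; strictly positive.
    origin : ndarray, shape (3,)
        World (RAS, mm) position of voxel (0, 0, 0).
    direction : ndarray, shape (3, 3)
        Orthonormal matrix mapping voxel axes to world axes.
    """

    data: np.ndarray
    spacing: np.ndarray = dataclasses.field(
        default_factory=lambda: np.ones(3))
    origin: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros(3))
    direction: np.ndarray = dataclasses.field(
        default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"expected 3D data, got ndim={self.data.ndim}")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.allclose(self.direction @ self.direction.T, np.eye(3),
                           atol=1e-6):
            raise ValueError("direction matrix is not orthonormal")

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world (RAS mm) affine."""
        out = np.eye(4)
        out[:3, :3] = self.direction @ np.diag(self.spacing)
        out[:3, 3] = self.origin
        return out

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return idx @ (self.direction @ np.diag(self.spacing)).T + self.origin

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        inv = np.linalg.inv(self.direction @ np.diag(self.spacing))
        return (pts - self.origin) @ inv.T

    def same_grid(self, other: "Volume", atol: float = 1e-5) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing, atol=atol)
                and np.allclose(self.origin, other.origin, atol=atol)
                and np.allclose(self.direction, other.direction, atol=atol))

    def with_data(self, data: np.ndarray) -> "Volume":
        """New volume on this grid carrying ``data``."""
        return Volume(np.asarray(data), self.spacing.copy(),
                      self.origin.copy(), self.direction.copy())

    def copy(self) -> "Volume":
        return self.with_data(self.data.copy())


class BinaryMask(Volume):
    """A Volume whose voxels are exactly 0 or 1."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be exactly 0 or 1")
        self.data = self.data.astype(np.uint8)

    @classmethod
    def from_bool(cls, data: np.ndarray, like: Volume) -> "BinaryMask":
        return cls(np.asarray(data, dtype=bool).astype(np.uint8),
                   like.spacing.copy(), like.origin.copy(),
                   like.direction.copy())

    def as_bool(self) -> np.ndarray:
        return self.data.astype(bool)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path) -> Volume:
    """Read a 3D NIfTI volume, honouring the header geometry exactly."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        affine = np.asarray(img.affine, dtype=float)
    except Exception as exc:  # corrupt header, wrong magic, ...
        raise FormatError(f"cannot parse {path} as NIfTI: {exc}") from exc
    data = np.squeeze(data) if data.ndim > 3 and all(
        s == 1 for s in data.shape[3:]) else data
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape "
                          f"{data.shape}")
    linear = affine[:3, :3]
    spacing = np.linalg.norm(linear, axis=0)
    if np.any(spacing <= 0):
        raise FormatError(f"{path}: degenerate affine")
    direction = linear / spacing[np.newaxis, :]
    return Volume(data, spacing, affine[:3, 3], direction)


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI-1; round-trips bit-exactly through read_volume."""
    path = Path(path)
    data = vol.data
    if isinstance(vol, BinaryMask):
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_zooms(tuple(vol.spacing))
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_isotropic(vol: Volume, target_spacing: float,
                       interp: str = "linear") -> Volume:
    """Resample onto an isotropic grid of ``target_spacing`` mm.

    World-space extent is preserved within one voxel; the direction matrix
    and origin of the input frame are kept.  Linear interpolation never
    expands the intensity range; nearest keeps values exact (so binary masks
    stay binary).
    """
    if target_spacing <= 0:
        raise ValueError(f"target_spacing must be > 0, got {target_spacing}")
    if interp not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interp!r}")
    s = float(target_spacing)
    if np.allclose(vol.spacing, s, atol=1e-9):
        return vol.copy()
    extent = vol.spacing * np.asarray(vol.shape)
    new_shape = np.maximum(np.round(extent / s).astype(int), 1)
    # output voxel i sits at origin + direction @ (s * i); sample the input at
    # the equivalent input-index coordinates.
    scale = s / vol.spacing  # input index per output index, per axis
    grids = np.meshgrid(*[np.arange(n) for n in new_shape], indexing="ij")
    coords = [g * sc for g, sc in zip(grids, scale)]
    order = 1 if interp == "linear" else 0
    out = ndimage.map_coordinates(vol.data.astype(float), coords, order=order,
                                  mode="nearest")
    if interp == "nearest":
        out = out.astype(vol.data.dtype)
    result = Volume(out, np.full(3, s), vol.origin.copy(),
                    vol.direction.copy())
    if isinstance(vol, BinaryMask) and interp == "nearest":
        return BinaryMask.from_bool(result.data > 0, result)
    return result


def gaussian_smooth(vol: Volume, fwhm_mm: float) -> Volume:
    """Gaussian smoothing specified by FWHM in mm (sigma = FWHM / 2*sqrt(2 ln 2)).

    Replicate-edge boundary handling avoids darkening at the volume border;
    total intensity is conserved for structures away from the boundary.
    ``fwhm_mm == 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return vol.copy()
    sigma_vox = fwhm_to_sigma(fwhm_mm) / vol.spacing
    out = ndimage.gaussian_filter(vol.data.astype(float), sigma=sigma_vox,
                                  mode="nearest")
    return vol.with_data(out)


# ---------------------------------------------------------------------------
# Rigid initialization
# ---------------------------------------------------------------------------

def _intensity_moments(vol: Volume) -> tuple[np.ndarray, np.ndarray]:
    """Intensity-weighted centroid (world mm) and second-moment matrix."""
    w = vol.data.astype(float)
    w = w - w.min()
    total = w.sum()
    if total <= 0:
        raise DegenerateInputError("constant image: no moments")
    idx = np.indices(vol.shape).reshape(3, -1).T.astype(float)
    pts = vol.index_to_world(idx)
    wf = w.reshape(-1) / total
    c = wf @ pts
    d = pts - c
    cov = (d * wf[:, None]).T @ d
    return c, cov


def _principal_axes(cov: np.ndarray) -> np.ndarray:
    """Eigenvectors of the moment matrix as columns, largest eigenvalue first."""
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    return vecs[:, order]


def rigid_initialize(moving: Volume, fixed: Volume) -> "AffineTransform":
    """Centre-of-mass + principal-axes rigid pre-alignment.

    Serves the same "almost aligned" role as a manual rough rotation and
    translation: the returned transform is rigid (rotation + translation) and
    maps fixed-space points onto moving-space points, the resampling (pull)
    convention used by :func:`neotemplate.transforms.apply_transform`.
    """
    from .transforms import AffineTransform  # cycle avoidance

    c_m, cov_m = _intensity_moments(moving)
    c_f, cov_f = _intensity_moments(fixed)
    u_m = _principal_axes(cov_m)
    u_f = _principal_axes(cov_f)
    # Resolve eigenvector sign ambiguity: make each moving axis point the same
    # way as its fixed counterpart.
    for k in range(3):
        if u_m[:, k] @ u_f[:, k] < 0:
            u_m[:, k] = -u_m[:, k]
    rot = u_m @ u_f.T
    # Project onto the nearest proper rotation.
    uu, _, vv = np.linalg.svd(rot)
    rot = uu @ vv
    if np.linalg.det(rot) < 0:
        uu[:, -1] = -uu[:, -1]
        rot = uu @ vv
    # pull map: x_moving = R (x_fixed - c_f) + c_m
    return AffineTransform(matrix=rot, translation=c_m - rot @ c_f)
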