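"""CT preprocessing: Otsu thresholding, head-mask extraction, background
cleaning, and the invertible three-segment CT intensity transform.

The intensity transform maps the CT range onto an MR-like non-negative range
while expanding soft-tissue contrast inside the skull:

* ``[-1000, -100] -> [0, 900]``        (air to deep soft tissue; slope 1)
* ``[-99, 100]    -> [901, 3100]``     (soft tissue, expanded ~11x)
* ``v > 100       -> v + 3000``        (bone and beyond, offset)

The map is continuous, strictly increasing, hence invertible on its range.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .volume import (BinaryMask, DegenerateInputError, GeometryError, Volume)

__all__ = [
    "otsu_threshold",
    "extract_head_mask",
    "clean_background",
    "transform_ct_intensity",
    "inverse_ct_intensity",
    "SegmentationError",
    "AIR_HU",
]

logger = logging.getLogger(__name__)

AIR_HU = -1000.0

# knots of the piecewise-linear CT intensity transform
_IN_KNOTS = np.array([-1000.0, -100.0, -99.0, 100.0])
_OUT_KNOTS = np.array([0.0, 900.0, 901.0, 3100.0])
_HIGH_OFFSET = 3000.0


class SegmentationError(RuntimeError):
    """A segmentation stage failed to produce a usable region."""


# ---------------------------------------------------------------------------
# Otsu
# ---------------------------------------------------------------------------

def otsu_threshold(vol: Volume, mask: BinaryMask | None = None) -> float:
    """Threshold maximizing between-class variance, by exhaustive search.

    Every mid-point between consecutive distinct intensities is a candidate;
    ties resolve to the smallest threshold.  Exact for discrete images and
    translation-equivariant (shifting intensities by c shifts the result
    by c).
    """
    if mask is not None:
        if mask.shape != vol.shape:
            raise GeometryError("mask grid differs from image grid")
        values = vol.data[mask.as_bool()].ravel()
    else:
        values = vol.data.ravel()
    uniq, counts = np.unique(values, return_counts=True)
    if uniq.size < 2:
        raise DegenerateInputError("constant input: no threshold exists")
    w = counts.astype(float)
    total = w.sum()
    csum = np.cumsum(w)
    cmean = np.cumsum(w * uniq)
    grand = cmean[-1]
    # candidate k: class0 = values <= uniq[k], class1 = rest
    w0 = csum[:-1] / total
    w1 = 1.0 - w0
    mu0 = cmean[:-1] / csum[:-1]
    mu1 = (grand - cmean[:-1]) / (total - csum[:-1])
    between = w0 * w1 * (mu0 - mu1) ** 2
    k = int(np.argmax(between))  # first occurrence = smallest threshold
    return float((uniq[k] + uniq[k + 1]) / 2.0)


# ---------------------------------------------------------------------------
# head mask and background
# ---------------------------------------------------------------------------

def extract_head_mask(ct: Volume, opening_radius: int = 1,
                      closing_radius: int = 2,
                      min_contrast_hu: float = 100.0) -> BinaryMask:
    """Head mask: Otsu threshold, opening, largest component, closing, filling.

    Nuisance structures disconnected from the head (pillow and pacifier
    blobs, the artificial sub-air rim) are dropped by keeping only the
    largest connected component.  The result is a single hole-free
    component.

    Values below −1024 HU are non-physical (the artificial rim); they are
    clamped to air before thresholding so Otsu separates head from air
    rather than rim from everything else.
    """
    clamped = ct.with_data(np.maximum(ct.data, AIR_HU))
    thr = otsu_threshold(clamped)
    fg = clamped.data > thr
    if not fg.any():
        raise SegmentationError("no voxels above the Otsu threshold")
    lo_mean = float(ct.data[~fg].mean()) if (~fg).any() else AIR_HU
    hi_mean = float(ct.data[fg].mean())
    if hi_mean - lo_mean < min_contrast_hu:
        raise SegmentationError(
            f"air/tissue contrast too small ({hi_mean - lo_mean:.1f} HU); "
            "input appears to contain no head")
    if opening_radius > 0:
        fg = ndimage.binary_opening(fg, structure=ball(opening_radius))
    if not fg.any():
        raise SegmentationError("opening removed all foreground")
    lab, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab,
                                   index=np.arange(1, n + 1))
        fg = lab == (int(np.argmax(sizes)) + 1)
    if closing_radius > 0:
        fg = ndimage.binary_closing(fg, structure=ball(closing_radius))
    fg = ndimage.binary_fill_holes(fg)
    return BinaryMask.from_bool(fg, ct)


def clean_background(ct: Volume, head: BinaryMask) -> Volume:
    """Set every voxel outside the head mask to exactly −1000 HU (air).

    Eliminates the sub-air rim and any other extracranial artifact by fiat;
    voxels inside the head are untouched, so the operation is idempotent.
    """
    if head.shape != ct.shape:
        raise GeometryError("head mask grid differs from CT grid")
    out = ct.data.astype(float).copy()
    out[~head.as_bool()] = AIR_HU
    return ct.with_data(out)


# ---------------------------------------------------------------------------
# intensity transform
# ---------------------------------------------------------------------------

def _transform_array(v: np.ndarray) -> np.ndarray:
    if np.any(np.isnan(v)):
        raise ValueError("NaN in intensity-transform input")
    below = v < AIR_HU
    if np.any(below):
        logger.info("clamping %d values below -1000 HU before transform",
                    int(below.sum()))
        v = np.maximum(v, AIR_HU)
    out = np.interp(v, _IN_KNOTS, _OUT_KNOTS)
    high = v > _IN_KNOTS[-1]
    out = np.where(high, v + _HIGH_OFFSET, out)
    return out


def transform_ct_intensity(v):
    """Apply the three-segment CT intensity transform to a scalar or Volume.

    Inputs below −1000 HU (e.g. the −3000 artificial rim, if it survived
    preprocessing) are clamped to −1000 first and logged.
    """
    if isinstance(v, Volume):
        return v.with_data(_transform_array(v.data.astype(float)))
    return float(_transform_array(np.asarray(v, dtype=float)))


def _inverse_array(v: np.ndarray) -> np.ndarray:
    if np.any(np.isnan(v)):
        raise ValueError("NaN in inverse-transform input")
    if np.any(v < 0):
        raise ValueError("inverse transform undefined for negative inputs")
    out = np.interp(v, _OUT_KNOTS, _IN_KNOTS)
    high = v > _OUT_KNOTS[-1]
    return np.where(high, v - _HIGH_OFFSET, out)


def inverse_ct_intensity(v):
    """Invert :func:`transform_ct_intensity`; exact on the transform's range."""
    if isinstance(v, Volume):
        return v.with_data(_inverse_array(v.data.astype(float)))
    return float(_inverse_array(np.asarray(v, dtype=float)))
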