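"""Similarity and overlap measures: joint histograms, entropy, MI, CC, Dice.

Mutual information is computed from a joint intensity histogram as

    I(X, Y) = sum_xy p(x, y) log[ p(x, y) / (p(x) p(y)) ]

with 0·log 0 := 0.  When the two images are identical the MI equals the
entropy of either image; when they are independent it tends to zero (up to
finite-sample bias).  Logs are base 2 by default, so values are in bits.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .volume import BinaryMask, DegenerateInputError, GeometryError, Volume

__all__ = [
    "JointHistogram",
    "joint_histogram",
    "entropy",
    "mutual_information",
    "cross_correlation",
    "dice",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class JointHistogram:
    """B×B joint intensity count table with its bin edges."""

    counts: np.ndarray
    edges_x: np.ndarray
    edges_y: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def joint_prob(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    def marginal_x(self) -> np.ndarray:
        return self.joint_prob().sum(axis=1)

    def marginal_y(self) -> np.ndarray:
        return self.joint_prob().sum(axis=0)


def _paired_values(x: Volume, y: Volume,
                   mask: BinaryMask | None) -> tuple[np.ndarray, np.ndarray]:
    if x.shape != y.shape:
        raise GeometryError(f"grid mismatch: {x.shape} vs {y.shape}")
    if mask is not None:
        if mask.shape != x.shape:
            raise GeometryError("mask grid differs from image grid")
        sel = mask.as_bool()
        return x.data[sel].ravel(), y.data[sel].ravel()
    return x.data.ravel(), y.data.ravel()


def joint_histogram(x: Volume, y: Volume, bins: int = 64,
                    mask: BinaryMask | None = None) -> JointHistogram:
    """Joint intensity histogram over paired voxels (within ``mask`` if given)."""
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    xv, yv = _paired_values(x, y, mask)
    counts, ex, ey = np.histogram2d(xv.astype(float), yv.astype(float),
                                    bins=bins)
    return JointHistogram(counts, ex, ey)


def entropy(hist: np.ndarray, base: float = 2.0) -> float:
    """Shannon entropy of a histogram or probability vector.

    Zero-count bins contribute nothing; a single-bin distribution has zero
    entropy.
    """
    h = np.asarray(hist, dtype=float).ravel()
    total = h.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    p = h[h > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def mutual_information(x: Volume, y: Volume, bins: int = 64,
                       mask: BinaryMask | None = None,
                       base: float = 2.0) -> float:
    """Histogram mutual information between two volumes, in log-``base`` units."""
    jh = joint_histogram(x, y, bins=bins, mask=mask)
    p = jh.joint_prob()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    outer = np.outer(px, py)
    mi = (p[nz] * (np.log(p[nz] / outer[nz]) / np.log(base))).sum()
    return float(max(mi, 0.0))


def mutual_information_from_joint(p: np.ndarray, base: float = 2.0) -> float:
    """MI of an explicit joint probability table (rows: x, cols: y)."""
    p = np.asarray(p, dtype=float)
    p = p / p.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    outer = np.outer(px, py)
    return float((p[nz] * (np.log(p[nz] / outer[nz]) / np.log(base))).sum())


def cross_correlation(x: Volume, y: Volume,
                      mask: BinaryMask | None = None) -> float:
    """Global Pearson correlation of paired voxel intensities, in [-1, 1]."""
    xv, yv = _paired_values(x, y, mask)
    xv = xv.astype(float)
    yv = yv.astype(float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise DegenerateInputError("constant input: correlation undefined")
    xv = xv - xv.mean()
    yv = yv - yv.mean()
    return float(np.clip((xv @ yv)
                         / np.sqrt((xv @ xv) * (yv @ yv)), -1.0, 1.0))


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); two empty masks count as identical."""
    if a.shape != b.shape:
        raise GeometryError(f"grid mismatch: {a.shape} vs {b.shape}")
    av = a.as_bool()
    bv = b.as_bool()
    denom = av.sum() + bv.sum()
    if denom == 0:
        logger.info("dice of two empty masks: defined as 1")
        return 1.0
    return float(2.0 * np.logical_and(av, bv).sum() / denom)
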