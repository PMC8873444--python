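"""Fuzzy interpretation of overlapping fragment predictions into an ROI mask.

Because the evaluation grid's stride is smaller than the window, every pixel
is covered by many windows (up to (w/s)^2 = 36 for a 96 px window and 16 px
stride).  Each pixel's tumor-cluster membership degree is the fraction of
covering windows predicted positive; defuzzification thresholds that degree
(argmax between the linear "tumor" and "irrelevant" membership functions,
equivalent to a 0.5 cutoff) to produce a crisp binary ROI mask.

Coverage is counted per pixel rather than assumed constant, so border pixels
— covered by fewer windows than the interior — can still reach membership 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Protocol

import numpy as np
from PIL import Image

from ki67pi.fragments import FragmentGrid


class _LabeledGrid(Protocol):
    """Anything carrying per-origin binary labels on a fragment grid."""

    grid: FragmentGrid
    labels: np.ndarray


@dataclass
class MembershipMap:
    """Per-pixel positive-window counts, coverage, and membership degree."""

    counts: np.ndarray  # (H, W) int32: positive windows covering the pixel
    coverage: np.ndarray  # (H, W) int32: all windows covering the pixel
    mu: np.ndarray  # (H, W) float64 in [0, 1]; 0 where uncovered

    @property
    def uncovered(self) -> np.ndarray:
        """Boolean mask of pixels outside every window (image margins)."""
        return self.coverage == 0


@dataclass
class ROIMask:
    """Binary tumor-cluster mask for one slide."""

    mask: np.ndarray  # (H, W) bool
    empty: bool

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.empty = not bool(self.mask.any())

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    def to_png(self, path: str | Path) -> None:
        Image.fromarray((self.mask * 255).astype(np.uint8)).save(path)

    @classmethod
    def from_png(cls, path: str | Path) -> "ROIMask":
        arr = np.asarray(Image.open(path).convert("L"))
        return cls(mask=arr > 127, empty=False)


def max_overlap(window: int, stride: int) -> int:
    """Maximum number of windows that can cover a single interior pixel.

    For a 96 px window sliding with a 16 px stride this is 6 x 6 = 36, the
    membership-count ceiling any pixel can reach.  When the stride does not
    divide the window the interior maximum is ceil(w/s)^2, attained at
    pixels aligned with the stride lattice; computed by enumeration for
    safety.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if window < stride:
        raise ValueError("window must be >= stride")
    if window % stride == 0:
        return (window // stride) ** 2
    # enumerate covering windows of a deep-interior pixel over one stride period
    best = 0
    for phase in range(stride):
        # deep-interior pixel p; covering origins o = i*stride satisfy
        # o <= p < o + window, i.e. i in [ceil((p-window+1)/stride), floor(p/stride)]
        p = 10 * window + phase
        lo = -(-(p - window + 1) // stride)
        hi = p // stride
        best = max(best, hi - lo + 1)
    return best * best


def accumulate(pred: _LabeledGrid) -> MembershipMap:
    """Per-pixel sum of positive predictions over all covering windows.

    ``pred`` is any object with a ``grid`` (:class:`FragmentGrid`) and
    per-origin binary ``labels`` — fragment labels from annotations or a
    classifier's prediction map.  Pixels outside every window (right/bottom
    margins narrower than the window) get membership 0 and coverage 0.
    """
    grid = pred.grid
    labels = np.asarray(pred.labels).reshape(grid.n_rows, grid.n_cols)
    H, W, w = grid.image_height, grid.image_width, grid.window

    counts = np.zeros((H, W), dtype=np.int32)
    coverage = np.zeros((H, W), dtype=np.int32)
    # box-accumulate via the summed-area trick: add +1/-1 at window corners,
    # then integrate; O(pixels) regardless of overlap depth
    d_counts = np.zeros((H + 1, W + 1), dtype=np.int32)
    d_cov = np.zeros((H + 1, W + 1), dtype=np.int32)
    origins = grid.origins
    rows, cols = origins[:, 0], origins[:, 1]
    lab = labels.ravel()
    np.add.at(d_cov, (rows, cols), 1)
    np.add.at(d_cov, (rows + w, cols + w), 1)
    np.add.at(d_cov, (rows, cols + w), -1)
    np.add.at(d_cov, (rows + w, cols), -1)
    np.add.at(d_counts, (rows, cols), lab)
    np.add.at(d_counts, (rows + w, cols + w), lab)
    np.add.at(d_counts, (rows, cols + w), -lab)
    np.add.at(d_counts, (rows + w, cols), -lab)
    coverage = d_cov.cumsum(axis=0).cumsum(axis=1)[:H, :W]
    counts = d_counts.cumsum(axis=0).cumsum(axis=1)[:H, :W]

    mu = np.zeros((H, W), dtype=np.float64)
    covered = coverage > 0
    mu[covered] = counts[covered] / coverage[covered]
    return MembershipMap(counts=counts, coverage=coverage, mu=mu)


def defuzzify(membership: MembershipMap, cutoff: float = 0.5) -> ROIMask:
    """Crisp ROI mask: pixels whose tumor membership exceeds ``cutoff``.

    With the two linear membership functions mu_tumor = counts/coverage and
    mu_irrelevant = 1 - mu_tumor, assigning each pixel to its best class is
    exactly the mu > 0.5 rule.  Ties (mu == cutoff) go to background, which
    favors rejecting stain artifacts over including them.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"cutoff must be in (0, 1), got {cutoff}")
    mask = membership.mu > cutoff
    return ROIMask(mask=mask, empty=not bool(mask.any()))


def overlay_roi(pixels: np.ndarray, roi: ROIMask, alpha: float = 0.35) -> np.ndarray:
    """Blend a translucent cyan ROI highlight over an RGB raster (for reports)."""
    out = pixels.astype(np.float64).copy()
    tint = np.array([0.0, 200.0, 200.0])
    out[roi.mask] = (1 - alpha) * out[roi.mask] + alpha * tint
    return out.astype(np.uint8)
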