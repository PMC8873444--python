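"""Sliding-window tiling of a slide and annotation-derived fragment labels.

A slide is tiled with a square window of side ``w`` moved with stride ``s``.
For classifier evaluation the stride is small (default 16 px) so windows
overlap heavily; for training the stride equals the window size so fragments
are disjoint.  A fragment is labeled positive when at least one annotated
tumor nucleus center (of either stain class) falls inside it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ki67pi.io_annotations import AnnotationSet, SlideImage

#: Window side lengths studied for the fragment classifier, in pixels.
WINDOW_PRESETS = (48, 96, 192)
#: Evaluation-grid stride in pixels.
EVAL_STRIDE = 16


@dataclass(frozen=True)
class FragmentGrid:
    """Row-major list of window origins fully inside an image."""

    window: int
    stride: int
    image_height: int
    image_width: int

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError(f"stride must be >= 1, got {self.stride}")
        if self.window < 1:
            raise ValueError(f"window must be >= 1, got {self.window}")
        if self.window > min(self.image_height, self.image_width):
            raise ValueError(
                f"window {self.window} exceeds image "
                f"{self.image_height}x{self.image_width}"
            )

    @property
    def n_rows(self) -> int:
        return (self.image_height - self.window) // self.stride + 1

    @property
    def n_cols(self) -> int:
        return (self.image_width - self.window) // self.stride + 1

    def __len__(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def origins(self) -> np.ndarray:
        """(N, 2) array of (row, col) upper-left corners, row-major."""
        rows = np.arange(self.n_rows) * self.stride
        cols = np.arange(self.n_cols) * self.stride
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        return np.stack([rr.ravel(), cc.ravel()], axis=1)


@dataclass
class FragmentLabels:
    """Per-origin binary labels (1 = contains >= 1 relevant cell)."""

    grid: FragmentGrid
    labels: np.ndarray  # (N,) of {0, 1}

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8).ravel()
        if self.labels.shape[0] != len(self.grid):
            raise ValueError(
                f"{self.labels.shape[0]} labels for {len(self.grid)} grid origins"
            )
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")


def build_grid(
    image_height: int, image_width: int, window: int, stride: int
) -> FragmentGrid:
    """Tile an image with a square sliding window.

    Origins are every (i*stride, j*stride) whose window fits fully inside
    the image; right/bottom margins narrower than the window are not tiled.
    """
    return FragmentGrid(
        window=window, stride=stride, image_height=image_height, image_width=image_width
    )


def label_fragments(grid: FragmentGrid, annotations: AnnotationSet) -> FragmentLabels:
    """Label each window 1 iff >= 1 annotated nucleus center lies inside it.

    Window membership uses half-open intervals [row, row+w) x [col, col+w),
    so a nucleus on a shared boundary belongs to exactly one side of it.
    Both stain classes count: the classifier detects tumor-cell presence,
    not Ki-67 status.
    """
    labels = np.zeros((grid.n_rows, grid.n_cols), dtype=np.int8)
    w, s = grid.window, grid.stride
    for p in annotations.points:
        if not (0 <= p.x < grid.image_width and 0 <= p.y < grid.image_height):
            raise ValueError(
                f"annotation ({p.x}, {p.y}) outside image "
                f"{grid.image_width}x{grid.image_height}"
            )
        # windows with origin o satisfy o <= coord < o + w, i.e.
        # o in (coord - w, coord], intersected with the grid lattice
        i_lo = max(0, -(-(p.y - w + 1) // s))  # ceil((y - w + 1) / s)
        i_hi = min(grid.n_rows - 1, p.y // s)
        j_lo = max(0, -(-(p.x - w + 1) // s))
        j_hi = min(grid.n_cols - 1, p.x // s)
        if i_lo <= i_hi and j_lo <= j_hi:
            labels[i_lo : i_hi + 1, j_lo : j_hi + 1] = 1
    return FragmentLabels(grid=grid, labels=labels.ravel())


def extract_fragment(image: SlideImage, grid: FragmentGrid, index: int) -> np.ndarray:
    """Exact pixel copy of window ``index`` as a (w, w, 3) uint8 array."""
    if not 0 <= index < len(grid):
        raise IndexError(f"fragment index {index} out of range [0, {len(grid)})")
    if image.height != grid.image_height or image.width != grid.image_width:
        raise ValueError("grid was built for a different image size")
    row, col = grid.origins[index]
    w = grid.window
    return image.pixels[row : row + w, col : col + w].copy()


def extract_all_fragments(image: SlideImage, grid: FragmentGrid) -> np.ndarray:
    """All fragments stacked as an (N, w, w, 3) uint8 array."""
    if image.height != grid.image_height or image.width != grid.image_width:
        raise ValueError("grid was built for a different image size")
    w = grid.window
    out = np.empty((len(grid), w, w, 3), dtype=np.uint8)
    for k, (row, col) in enumerate(grid.origins):
        out[k] = image.pixels[row : row + w, col : col + w]
    return out


def write_labels_csv(labels: FragmentLabels, path: str | Path) -> None:
    """Cache labels as ``origin_row,origin_col,label`` rows."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["origin_row", "origin_col", "label"])
        for (row, col), lab in zip(labels.grid.origins, labels.labels):
            writer.writerow([row, col, int(lab)])


def read_labels_csv(grid: FragmentGrid, path: str | Path) -> FragmentLabels:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        rows = list(reader)
    if len(rows) != len(grid):
        raise ValueError(f"{path}: {len(rows)} rows for {len(grid)} grid origins")
    labels = np.empty(len(grid), dtype=np.int8)
    for k, ((row, col), rec) in enumerate(zip(grid.origins, rows)):
        if int(rec["origin_row"]) != row or int(rec["origin_col"]) != col:
            raise ValueError(f"{path}: origin mismatch at row {k}")
        labels[k] = int(rec["label"])
    return FragmentLabels(grid=grid, labels=labels)
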