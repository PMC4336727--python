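"""Sliding-window detection and connected-block region counting.

A test image is tiled by non-overlapping square windows (140 px by default;
partial tiles at the right/bottom edges are discarded). Every window is
classified from the BoVW histogram of the dense-SIFT grid points that fall
inside it, yielding a boolean block map. Two counts summarize a map:

* FBN — the number of blocks judged to contain flowering panicle parts;
* FCBN — the number of connected components of those blocks, a proxy for
  the number of flowering panicles (8-connectivity by default, so a panicle
  crossing a window corner does not split its region).

Grid points are assigned to the window containing them; a descriptor may
draw support pixels from beyond the window edge, so classifying windows
independently is exactly equivalent to one global dense pass restricted to
each window's points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .classifier import FlowerModel
from .features import GridSpec, dense_multiscale_sift
from .image_io import Image
from .vocabulary import Codebook, assign_words

__all__ = [
    "BlockMap",
    "DetectionResult",
    "slide_windows",
    "classify_blocks",
    "connected_regions",
    "summarize_detection",
    "detect",
    "render_overlay",
]

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass
class BlockMap:
    """Boolean verdict grid: one cell per non-overlapping window."""

    verdicts: np.ndarray  # (n_rows, n_cols) bool
    window_px: int
    image_ref: str = ""

    def __post_init__(self) -> None:
        self.verdicts = np.asarray(self.verdicts, dtype=bool)
        if self.verdicts.ndim != 2:
            raise ValueError("verdicts must be a 2-D grid")

    @property
    def n_rows(self) -> int:
        return self.verdicts.shape[0]

    @property
    def n_cols(self) -> int:
        return self.verdicts.shape[1]


@dataclass
class DetectionResult:
    """FBN, FCBN and the region bounding boxes of one image."""

    fbn: int
    fcbn: int
    regions: list[tuple[int, int, int, int]]  # (x_min, y_min, x_max, y_max), half-open
    block_map: BlockMap = field(repr=False)


def slide_windows(width: int, height: int, window_px: int) -> list[tuple[int, int, int, int]]:
    """Non-overlapping window rectangles in row-major order.

    Each is (x_min, y_min, x_max, y_max), half-open; partial tiles at the
    right and bottom edges are discarded.
    """
    if window_px < 1:
        raise ValueError(f"window_px must be >= 1, got {window_px}")
    n_cols = width // window_px
    n_rows = height // window_px
    return [
        (c * window_px, r * window_px, (c + 1) * window_px, (r + 1) * window_px)
        for r in range(n_rows)
        for c in range(n_cols)
    ]


def classify_blocks(img: Image, model: FlowerModel, codebook: Codebook,
                    grid: GridSpec | None = None) -> BlockMap:
    """Classify every window of an image into a boolean block map.

    Windows whose interior contains no grid point are judged background.
    Images smaller than one window yield an empty (0 x 0) map.
    """
    from .classifier import kernel_map_matrix  # local import to avoid cycle at module load

    grid = grid or GridSpec()
    wpx = model.window_px
    n_rows = img.height // wpx
    n_cols = img.width // wpx
    if n_rows == 0 or n_cols == 0:
        return BlockMap(
            verdicts=np.zeros((n_rows, n_cols), dtype=bool),
            window_px=wpx,
            image_ref=img.source_path,
        )
    dset = dense_multiscale_sift(img.luminance, grid)
    n_windows = n_rows * n_cols
    counts = np.zeros((n_windows, codebook.k))
    has_points = np.zeros(n_windows, dtype=bool)
    if dset.n_points > 0:
        xs = dset.points[:, 0]
        ys = dset.points[:, 1]
        cols = xs // wpx
        rows = ys // wpx
        inside = (cols < n_cols) & (rows < n_rows)
        win_of_point = rows * n_cols + cols
        has_points[win_of_point[inside]] = True
        flat = dset.flat()  # (n_points * n_radii, 128)
        n_radii = dset.descriptors.shape[1]
        win_of_desc = np.repeat(win_of_point, n_radii)
        desc_inside = np.repeat(inside, n_radii)
        nonzero = np.any(flat != 0.0, axis=1)
        keep = desc_inside & nonzero
        if np.any(keep):
            words = assign_words(flat[keep], codebook)
            np.add.at(counts, (win_of_desc[keep], words), 1.0)
    totals = counts.sum(axis=1)
    norm = np.where(totals > 0, totals, 1.0)
    hists = counts / norm[:, None]
    phi = kernel_map_matrix(hists, n=model.map_order_n, L=model.map_period_L)
    scores = phi @ model.weights + model.bias
    verdicts = (scores > 0) & has_points
    return BlockMap(
        verdicts=verdicts.reshape(n_rows, n_cols),
        window_px=wpx,
        image_ref=img.source_path,
    )


def connected_regions(bm: BlockMap, connectivity: int = 8) -> list[np.ndarray]:
    """Maximal connected components of true blocks.

    Each component is an (m, 2) array of (row, col) block indices; components
    are ordered by their first true block in row-major order.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    labels, n = ndimage.label(bm.verdicts, structure=_STRUCTURES[connectivity])
    return [np.argwhere(labels == i) for i in range(1, n + 1)]


def summarize_detection(bm: BlockMap, connectivity: int = 8) -> DetectionResult:
    """FBN, connected regions and their pixel bounding boxes for a block map."""
    components = connected_regions(bm, connectivity)
    wpx = bm.window_px
    regions = []
    for comp in components:
        r_min, c_min = comp.min(axis=0)
        r_max, c_max = comp.max(axis=0)
        regions.append(
            (int(c_min) * wpx, int(r_min) * wpx,
             (int(c_max) + 1) * wpx, (int(r_max) + 1) * wpx)
        )
    return DetectionResult(
        fbn=int(bm.verdicts.sum()),
        fcbn=len(components),
        regions=regions,
        block_map=bm,
    )


def detect(img: Image, model: FlowerModel, codebook: Codebook,
           grid: GridSpec | None = None, connectivity: int = 8) -> DetectionResult:
    """Full single-image detection: block classification + region counting."""
    return summarize_detection(classify_blocks(img, model, codebook, grid), connectivity)


def render_overlay(img: Image, result: DetectionResult,
                   tint=(199, 21, 133), outline=(255, 0, 0)) -> np.ndarray:
    """Overlay raster: detected blocks tinted violet, regions outlined red."""
    out = img.pixels.astype(np.float64).copy()
    wpx = result.block_map.window_px
    tint_arr = np.asarray(tint, dtype=np.float64)
    for r, c in np.argwhere(result.block_map.verdicts):
        y0, y1 = r * wpx, (r + 1) * wpx
        x0, x1 = c * wpx, (c + 1) * wpx
        out[y0:y1, x0:x1] = 0.55 * out[y0:y1, x0:x1] + 0.45 * tint_arr
    w = 3  # outline width in px
    for x0, y0, x1, y1 in result.regions:
        out[y0:y0 + w, x0:x1] = outline
        out[max(y1 - w, 0):y1, x0:x1] = outline
        out[y0:y1, x0:x0 + w] = outline
        out[y0:y1, max(x1 - w, 0):x1] = outline
    return np.clip(np.round(out), 0, 255).astype(np.uint8)
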