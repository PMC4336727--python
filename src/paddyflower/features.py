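"""Dense multi-scale SIFT descriptors on a regular grid.

Local texture is described by classic 128-dimensional SIFT descriptors
(4x4 spatial patches x 8 orientation bins), computed not at detected
keypoints but at every node of a regular grid overlaid on the image, and at
four support scales per node (circular supports of radius 4, 6, 8 and 10
pixels by default). Each scale's descriptor square (side ``4*radius``) is
rotated to that scale's dominant gradient orientation, so the representation
is robust to panicle pose.

Numerical conventions (all deliberate, see the methods note):

* gradients by central differences on the raw luminance, no pre-smoothing;
* pixels outside the image contribute zero luminance (zero padding);
* hard assignment to spatial patches and to the 8 orientation bins;
* dominant orientation from a 36-bin, Gaussian-weighted (sigma = radius/2)
  gradient histogram over the circular support; the returned angle is the
  peak bin's center, ties broken toward the lowest bin, flat supports map
  to 0.0;
* descriptors are L2-normalized, clipped at 0.2 and re-normalized; a
  support with no gradient energy yields the exact zero vector.

The heavy per-point loops are JIT-compiled with numba; every public
operation, including the single-point ones, runs through the same kernel so
that per-window recomputation is bitwise identical to a global pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "GridSpec",
    "DescriptorSet",
    "make_grid",
    "dominant_orientation",
    "sift_descriptor",
    "dense_multiscale_sift",
]

TWO_PI = 2.0 * math.pi
N_ORIENT_BINS = 36  # dominant-orientation histogram
N_DESC_BINS = 8     # per-patch orientation bins
DESC_DIM = 128


@dataclass(frozen=True)
class GridSpec:
    """Dense sampling layout: grid spacing M and the support radii."""

    spacing: int = 15
    radii: tuple[int, ...] = (4, 6, 8, 10)

    def __post_init__(self) -> None:
        if self.spacing < 1:
            raise ValueError(f"grid spacing must be >= 1, got {self.spacing}")
        radii = tuple(int(r) for r in self.radii)
        if not radii or any(r < 1 for r in radii):
            raise ValueError(f"radii must all be >= 1, got {radii}")
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError(f"radii must be strictly increasing, got {radii}")
        object.__setattr__(self, "radii", radii)


@dataclass
class DescriptorSet:
    """Descriptors for every grid point at every support scale.

    Attributes
    ----------
    points : ndarray of int, shape (n_points, 2)
        (x, y) pixel coordinates, row-major grid order.
    descriptors : ndarray of float64, shape (n_points, n_radii, 128)
    grid : GridSpec
    """

    points: np.ndarray
    descriptors: np.ndarray
    grid: GridSpec = field(default_factory=GridSpec)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def flat(self) -> np.ndarray:
        """All descriptors as one (n_points * n_radii, 128) matrix."""
        return self.descriptors.reshape(-1, DESC_DIM)


def make_grid(width: int, height: int, spacing: int) -> np.ndarray:
    """Regular grid points (i*spacing, j*spacing), i, j >= 1, inside the image.

    Returned as an (n, 2) int array of (x, y) coordinates in row-major order
    (y outer, x inner). Empty images smaller than one spacing yield an empty
    array.
    """
    if width < 1 or height < 1 or spacing < 1:
        raise ValueError("width, height and spacing must all be >= 1")
    xs = np.arange(spacing, width, spacing, dtype=np.int64)
    ys = np.arange(spacing, height, spacing, dtype=np.int64)
    if xs.size == 0 or ys.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


# ---------------------------------------------------------------------------
# Precomputed per-radius geometry
# ---------------------------------------------------------------------------

def _circle_offsets(radius: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integer offsets within the circular support plus Gaussian weights."""
    r = int(radius)
    dd = np.arange(-r, r + 1)
    dx, dy = np.meshgrid(dd, dd)
    mask = dx * dx + dy * dy <= r * r
    dx, dy = dx[mask], dy[mask]
    sigma = r / 2.0
    w = np.exp(-(dx * dx + dy * dy) / (2.0 * sigma * sigma))
    return dx.astype(np.int64), dy.astype(np.int64), w.astype(np.float64)


def _square_offsets(radius: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample offsets of the 4r x 4r descriptor square and their patch slots.

    Samples sit at pixel resolution, centered on the point; slot index is
    (patch row * 4 + patch col) * 8, i.e. the base of that patch's 8
    orientation bins in the 128-vector (patch-major, bin-minor order).
    """
    side = 4 * int(radius)
    idx = np.arange(side)
    u, v = np.meshgrid(idx, idx)  # u: x within square, v: y within square
    ox = (u - side / 2.0 + 0.5).ravel()
    oy = (v - side / 2.0 + 0.5).ravel()
    patch = ((v // radius) * 4 + (u // radius)).ravel() * N_DESC_BINS
    return ox.astype(np.float64), oy.astype(np.float64), patch.astype(np.int64)


def _pad_for(radii: tuple[int, ...]) -> int:
    # farthest rotated sample: half-diagonal of the 4r square, plus rounding slack
    return int(math.ceil(2.0 * math.sqrt(2.0) * max(radii))) + 2


def _gradient_fields(lum: np.ndarray, pad: int) -> tuple[np.ndarray, np.ndarray]:
    """Zero-pad the luminance and return gradient magnitude and angle fields.

    The angle field is atan2(d/dy, d/dx) remapped to [0, 2*pi); y grows
    downward in image coordinates.
    """
    lum = np.asarray(lum, dtype=np.float64)
    padded = np.zeros((lum.shape[0] + 2 * pad, lum.shape[1] + 2 * pad))
    padded[pad:pad + lum.shape[0], pad:pad + lum.shape[1]] = lum
    gx = np.zeros_like(padded)
    gy = np.zeros_like(padded)
    gx[:, 1:-1] = (padded[:, 2:] - padded[:, :-2]) / 2.0
    gy[1:-1, :] = (padded[2:, :] - padded[:-2, :]) / 2.0
    mag = np.hypot(gx, gy)
    ang = np.arctan2(gy, gx)
    ang[ang < 0] += TWO_PI
    return mag, ang


@njit(cache=True)
def _sift_at_points(mag, ang, pxs, pys, cdx, cdy, cw,
                    sqx, sqy, slot, thetas_in, use_thetas,
                    out_desc, out_theta):  # pragma: no cover - jitted
    n = pxs.shape[0]
    for i in range(n):
        x = pxs[i]
        y = pys[i]
        if use_thetas:
            theta = thetas_in[i]
        else:
            hist = np.zeros(N_ORIENT_BINS)
            total = 0.0
            for j in range(cdx.shape[0]):
                m = mag[y + cdy[j], x + cdx[j]]
                if m > 0.0:
                    b = int(ang[y + cdy[j], x + cdx[j]] * (N_ORIENT_BINS / TWO_PI))
                    if b >= N_ORIENT_BINS:
                        b = N_ORIENT_BINS - 1
                    hist[b] += cw[j] * m
                    total += cw[j] * m
            if total > 0.0:
                theta = (np.argmax(hist) + 0.5) * (TWO_PI / N_ORIENT_BINS)
            else:
                theta = 0.0
        out_theta[i] = theta
        c = math.cos(theta)
        s = math.sin(theta)
        d = out_desc[i]
        for j in range(sqx.shape[0]):
            dx = c * sqx[j] - s * sqy[j]
            dy = s * sqx[j] + c * sqy[j]
            yy = y + int(round(dy))
            xx = x + int(round(dx))
            m = mag[yy, xx]
            if m > 0.0:
                rel = ang[yy, xx] - theta
                if rel < 0.0:
                    rel += TWO_PI
                b = int(rel * (N_DESC_BINS / TWO_PI))
                if b >= N_DESC_BINS:
                    b = N_DESC_BINS - 1
                d[slot[j] + b] += m
        norm = 0.0
        for t in range(DESC_DIM):
            norm += d[t] * d[t]
        if norm > 0.0:
            norm = math.sqrt(norm)
            clipped = 0.0
            for t in range(DESC_DIM):
                v = d[t] / norm
                if v > 0.2:
                    v = 0.2
                d[t] = v
                clipped += v * v
            clipped = math.sqrt(clipped)
            for t in range(DESC_DIM):
                d[t] /= clipped


def _run_kernel(lum: np.ndarray, points: np.ndarray, radius: int,
                thetas: np.ndarray | None, pad: int) -> tuple[np.ndarray, np.ndarray]:
    mag, ang = _gradient_fields(lum, pad)
    return _run_kernel_on_fields(mag, ang, points, radius, thetas, pad)


def _run_kernel_on_fields(mag, ang, points, radius, thetas, pad):
    n = points.shape[0]
    cdx, cdy, cw = _circle_offsets(radius)
    sqx, sqy, slot = _square_offsets(radius)
    out_desc = np.zeros((n, DESC_DIM))
    out_theta = np.zeros(n)
    if thetas is None:
        thetas_in = np.zeros(n)
        use = False
    else:
        thetas_in = np.asarray(thetas, dtype=np.float64)
        use = True
    _sift_at_points(
        mag, ang,
        points[:, 0].astype(np.int64) + pad,
        points[:, 1].astype(np.int64) + pad,
        cdx, cdy, cw, sqx, sqy, slot, thetas_in, use,
        out_desc, out_theta,
    )
    return out_desc, out_theta


def dominant_orientation(lum: np.ndarray, center: tuple[int, int], radius: int) -> float:
    """Dominant gradient orientation of the circular support, in [0, 2*pi).

    Flat (zero-gradient) supports return 0.0 by convention.
    """
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    points = np.array([[center[0], center[1]]], dtype=np.int64)
    pad = _pad_for((radius,))
    _, theta = _run_kernel(np.asarray(lum, dtype=np.float64), points, radius, None, pad)
    return float(theta[0])


def sift_descriptor(lum: np.ndarray, center: tuple[int, int], radius: int,
                    orientation: float) -> np.ndarray:
    """One 128-dim SIFT descriptor at the given support scale and frame angle."""
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    points = np.array([[center[0], center[1]]], dtype=np.int64)
    pad = _pad_for((radius,))
    desc, _ = _run_kernel(
        np.asarray(lum, dtype=np.float64), points, radius,
        np.array([float(orientation)]), pad,
    )
    return desc[0]


def dense_multiscale_sift(lum: np.ndarray, grid: GridSpec | None = None,
                          points: np.ndarray | None = None) -> DescriptorSet:
    """Descriptors at every grid point and every support radius.

    Parameters
    ----------
    lum : (H, W) luminance plane.
    grid : sampling layout; defaults to M=15, radii (4, 6, 8, 10).
    points : optional explicit (n, 2) point array overriding ``make_grid``
        (used for per-window recomputation; descriptors depend only on the
        luminance and the point, so restricting points restricts the output).
    """
    grid = grid or GridSpec()
    lum = np.asarray(lum, dtype=np.float64)
    if lum.ndim != 2 or lum.size == 0:
        raise ValueError(f"expected a nonempty 2-D luminance plane, got shape {lum.shape}")
    if points is None:
        points = make_grid(lum.shape[1], lum.shape[0], grid.spacing)
    points = np.asarray(points, dtype=np.int64).reshape(-1, 2)
    n_radii = len(grid.radii)
    descriptors = np.zeros((points.shape[0], n_radii, DESC_DIM))
    if points.shape[0] > 0:
        pad = _pad_for(grid.radii)
        mag, ang = _gradient_fields(lum, pad)
        for ri, radius in enumerate(grid.radii):
            desc, _ = _run_kernel_on_fields(mag, ang, points, radius, None, pad)
            descriptors[:, ri, :] = desc
    return DescriptorSet(points=points, descriptors=descriptors, grid=grid)
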