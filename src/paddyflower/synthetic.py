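"""Seeded synthetic paddy-canopy imagery with exact ground truth.

The generator emulates the statistical structure the detector exploits, not
photorealism:

* a green/brown background of randomly oriented elongated strokes (leaf
  blades seen from above);
* non-flowering panicles as dull, curvilinear arcs (quadratic Beziers);
* flowering panicles as the same arcs overlaid with dense 1-3 px bright,
  near-white speckles — the extruded-anther texture that makes flowering
  panicles visually distinct;
* a diurnal flowering schedule: images every 5 minutes from 08:00 to 16:00,
  with the number of flowering panicles drawn Poisson around a
  Gaussian-shaped daily rate whose peak time is configurable per day (a
  late peak emulates rain-delayed anthesis).

Every generator is a pure function of its spec and seed, and each image's
ground truth (flowering-region rectangles, hence the exact FPN) is recorded
by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from datetime import date, datetime, time, timedelta

import numpy as np

from .classifier import BACKGROUND, FLOWERING, PatchSample
from .image_io import Image

__all__ = [
    "CanopySpec",
    "GroundTruth",
    "PlacementError",
    "SamplingError",
    "render_canopy",
    "sample_patches",
    "simulate_series",
    "ACQUISITION_START",
    "ACQUISITION_END",
    "ACQUISITION_STEP_MIN",
]

ACQUISITION_START = time(8, 0)
ACQUISITION_END = time(16, 0)
ACQUISITION_STEP_MIN = 5

#: Gaussian sigma of the diurnal flowering-rate curve, in minutes. Rice
#: spikelet anthesis is concentrated within roughly +-1.5 h of the daily
#: peak, so the bulk of the curve spans ~3 h.
DEFAULT_WIDTH_MINUTES = 45.0


class PlacementError(RuntimeError):
    """A flowering panicle could not be placed inside the image bounds."""


class SamplingError(RuntimeError):
    """Patch sampling could not satisfy its overlap constraints."""


@dataclass(frozen=True)
class CanopySpec:
    """Parameters of one rendered canopy image.

    ``background_stroke_density`` is leaf strokes per pixel;
    ``anther_speckle_density`` is speckles per flowering panicle.
    """

    width: int = 1400
    height: int = 1120
    n_flowering: int = 8
    n_nonflowering_panicles: int = 25
    background_stroke_density: float = 0.012
    anther_speckle_density: float = 300.0
    illumination_gain: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be positive")
        if self.n_flowering < 0 or self.n_nonflowering_panicles < 0:
            raise ValueError("panicle counts must be >= 0")
        if self.background_stroke_density <= 0 or self.anther_speckle_density <= 0:
            raise ValueError("densities must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    """Flowering-panicle bounding rectangles (half-open) and their count."""

    flowering_regions: tuple[tuple[int, int, int, int], ...]
    fpn: int

    def __post_init__(self) -> None:
        if self.fpn != len(self.flowering_regions):
            raise ValueError("fpn must equal the number of flowering regions")


def _paint(canvas: np.ndarray, xs: np.ndarray, ys: np.ndarray, colors: np.ndarray) -> None:
    """Write colors at rounded integer coordinates, clipped to the canvas."""
    h, w = canvas.shape[:2]
    xi = np.clip(np.round(xs).astype(np.int64), 0, w - 1)
    yi = np.clip(np.round(ys).astype(np.int64), 0, h - 1)
    canvas[yi.ravel(), xi.ravel()] = colors.reshape(-1, 3)


def _paint_strokes(canvas: np.ndarray, rng: np.random.Generator, n: int) -> None:
    h, w = canvas.shape[:2]
    cx = rng.uniform(0, w, n)
    cy = rng.uniform(0, h, n)
    angle = rng.uniform(0, np.pi, n)
    length = rng.uniform(14, 36, n)
    is_green = rng.random(n) < 0.75
    colors = np.empty((n, 3))
    colors[:, 0] = np.where(is_green, rng.uniform(30, 85, n), rng.uniform(95, 150, n))
    colors[:, 1] = np.where(is_green, rng.uniform(85, 170, n), rng.uniform(65, 110, n))
    colors[:, 2] = np.where(is_green, rng.uniform(20, 65, n), rng.uniform(30, 60, n))
    n_samples = 26
    t = np.linspace(-0.5, 0.5, n_samples)
    dx = np.cos(angle)[:, None] * (length[:, None] * t[None, :])
    dy = np.sin(angle)[:, None] * (length[:, None] * t[None, :])
    # two parallel runs half a pixel apart give strokes ~2 px of body
    px = -np.sin(angle)[:, None] * 0.5
    py = np.cos(angle)[:, None] * 0.5
    col = np.repeat(colors[:, None, :], n_samples, axis=1)
    for off in (0.0, 1.0):
        _paint(canvas, cx[:, None] + dx + off * px, cy[:, None] + dy + off * py, col)


def _bezier_points(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)
    u = 1.0 - t
    return (u * u)[:, None] * p0 + (2 * u * t)[:, None] * p1 + (t * t)[:, None] * p2


def _arc_geometry(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random panicle arc (start, control, end) relative to its start point."""
    span = rng.uniform(70, 130)
    theta = rng.uniform(0, 2 * np.pi)
    end = np.array([span * math.cos(theta), span * math.sin(theta)])
    perp = np.array([-end[1], end[0]]) / max(span, 1e-9)
    ctrl = end / 2.0 + perp * rng.uniform(12, 34) * rng.choice([-1.0, 1.0])
    return np.zeros(2), ctrl, end


def _paint_arc(canvas: np.ndarray, rng: np.random.Generator, start: np.ndarray,
               ctrl: np.ndarray, end: np.ndarray, base_color: np.ndarray) -> np.ndarray:
    pts = _bezier_points(start, start + ctrl, start + end, 120)
    jitter = rng.normal(0.0, 6.0, size=(len(pts), 3))
    colors = np.clip(base_color[None, :] + jitter, 0, 255)
    for ox, oy in ((0, 0), (1, 0), (0, 1), (1, 1)):
        _paint(canvas, pts[:, 0] + ox, pts[:, 1] + oy, colors)
    return pts


def _speckle_offsets(size: int) -> np.ndarray:
    if size <= 1:
        return np.array([[0, 0]])
    if size == 2:
        return np.array([[0, 0], [1, 0], [0, 1], [1, 1]])
    return np.array([[0, 0], [1, 0], [-1, 0], [0, 1], [0, -1], [1, 1], [-1, -1]])


def render_canopy(spec: CanopySpec) -> tuple[Image, GroundTruth]:
    """Render one synthetic canopy image with its flowering ground truth."""
    rng = np.random.default_rng(spec.seed)
    w, h = spec.width, spec.height
    canvas = np.empty((h, w, 3), dtype=np.float64)
    canvas[..., 0] = 42.0
    canvas[..., 1] = 52.0
    canvas[..., 2] = 30.0
    canvas += rng.uniform(-10, 10, size=(h, w, 1))

    n_strokes = int(round(spec.background_stroke_density * w * h))
    if n_strokes > 0:
        _paint_strokes(canvas, rng, n_strokes)

    straw = np.array([150.0, 140.0, 88.0])
    for _ in range(spec.n_nonflowering_panicles):
        start = np.array([rng.uniform(0, w), rng.uniform(0, h)])
        _s0, ctrl, end = _arc_geometry(rng)
        _paint_arc(canvas, rng, start, ctrl, end, straw)

    margin = 8.0  # speckle jitter reach beyond the arc
    regions: list[tuple[int, int, int, int]] = []
    for _ in range(spec.n_flowering):
        placed = False
        for _attempt in range(100):
            start = np.array([rng.uniform(0, w), rng.uniform(0, h)])
            _s0, ctrl, end = _arc_geometry(rng)
            pts = _bezier_points(start, start + ctrl, start + end, 120)
            lo = pts.min(axis=0) - margin
            hi = pts.max(axis=0) + margin
            if lo[0] >= 0 and lo[1] >= 0 and hi[0] < w and hi[1] < h:
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place a flowering panicle inside {w}x{h} after 100 tries"
            )
        pts = _paint_arc(canvas, rng, start, ctrl, end, straw)
        n_sp = int(round(spec.anther_speckle_density))
        anchor = pts[rng.integers(0, len(pts), n_sp)]
        jitter = rng.normal(0.0, 3.0, size=(n_sp, 2))
        centers = anchor + jitter
        sizes = rng.integers(1, 4, n_sp)
        shade = rng.uniform(228, 255, n_sp)
        for i in range(n_sp):
            offs = _speckle_offsets(int(sizes[i]))
            color = np.array([shade[i], shade[i], shade[i] * rng.uniform(0.92, 1.0)])
            _paint(
                canvas,
                np.clip(centers[i, 0] + offs[:, 0], lo[0], hi[0]),
                np.clip(centers[i, 1] + offs[:, 1], lo[1], hi[1]),
                np.repeat(color[None, :], len(offs), axis=0),
            )
        x0, y0 = np.floor(lo).astype(int)
        x1, y1 = np.ceil(hi).astype(int) + 1
        regions.append((max(x0, 0), max(y0, 0), min(x1, w), min(y1, h)))

    canvas *= spec.illumination_gain
    pixels = np.clip(np.round(canvas), 0, 255).astype(np.uint8)
    img = Image.from_pixels(pixels, source_path=f"synthetic(seed={spec.seed})")
    gt = GroundTruth(flowering_regions=tuple(regions), fpn=len(regions))
    return img, gt


def _rect_area(r: tuple[int, int, int, int]) -> int:
    return max(r[2] - r[0], 0) * max(r[3] - r[1], 0)


def _intersection(a, b) -> int:
    return _rect_area((max(a[0], b[0]), max(a[1], b[1]), min(a[2], b[2]), min(a[3], b[3])))


def sample_patches(img: Image, gt: GroundTruth, n_pos: int, n_neg: int,
                   patch_px_range: tuple[int, int] = (60, 160),
                   seed: int = 0, max_tries: int = 200) -> list[PatchSample]:
    """Draw labeled training patches from a rendered canopy.

    Positive patches cover at least 30% of some flowering region's area;
    negative patches intersect no flowering region. Patch sides are drawn
    uniformly from ``patch_px_range`` (training patches need not share a
    size). Raises :class:`SamplingError` when the constraints cannot be met
    within ``max_tries`` draws per patch.
    """
    if n_pos > 0 and gt.fpn == 0:
        raise ValueError("cannot sample positive patches from an image with no flowering regions")
    rng = np.random.default_rng(seed)
    lo, hi = patch_px_range
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid patch size range {patch_px_range}")
    w, h = img.width, img.height
    samples: list[PatchSample] = []

    def crop(x0, y0, x1, y1):
        return Image(
            pixels=img.pixels[y0:y1, x0:x1],
            luminance=img.luminance[y0:y1, x0:x1],
            timestamp=img.timestamp,
            source_path=img.source_path,
        )

    for i in range(n_pos):
        for _try in range(max_tries):
            region = gt.flowering_regions[rng.integers(0, gt.fpn)]
            side = int(rng.integers(lo, hi + 1))
            rcx = (region[0] + region[2]) / 2 + rng.normal(0, side / 4)
            rcy = (region[1] + region[3]) / 2 + rng.normal(0, side / 4)
            x0 = int(np.clip(round(rcx - side / 2), 0, max(w - side, 0)))
            y0 = int(np.clip(round(rcy - side / 2), 0, max(h - side, 0)))
            rect = (x0, y0, min(x0 + side, w), min(y0 + side, h))
            best = max(_intersection(rect, r) / _rect_area(r) for r in gt.flowering_regions)
            if best >= 0.30:
                samples.append(
                    PatchSample(patch=crop(*rect), label=FLOWERING,
                                source=f"{img.source_path}+pos{i}@{rect}")
                )
                break
        else:
            raise SamplingError(
                f"failed to draw positive patch {i} with >=30% region overlap"
            )
    for i in range(n_neg):
        for _try in range(max_tries):
            side = int(rng.integers(lo, hi + 1))
            x0 = int(rng.integers(0, max(w - side, 0) + 1))
            y0 = int(rng.integers(0, max(h - side, 0) + 1))
            rect = (x0, y0, min(x0 + side, w), min(y0 + side, h))
            if all(_intersection(rect, r) == 0 for r in gt.flowering_regions):
                samples.append(
                    PatchSample(patch=crop(*rect), label=BACKGROUND,
                                source=f"{img.source_path}+neg{i}@{rect}")
                )
                break
        else:
            raise SamplingError(
                f"failed to draw negative patch {i} clear of all flowering regions"
            )
    return samples


def _day_timestamps(day: date) -> list[datetime]:
    start = datetime.combine(day, ACQUISITION_START)
    end = datetime.combine(day, ACQUISITION_END)
    out = []
    t = start
    while t <= end:
        out.append(t)
        t += timedelta(minutes=ACQUISITION_STEP_MIN)
    return out


def simulate_series(
    days: int,
    peak_time: dict[int, time] | time,
    amplitude: float,
    width_minutes: float = DEFAULT_WIDTH_MINUTES,
    spec: CanopySpec | None = None,
    seed: int = 0,
    start_date: date = date(2013, 8, 23),
) -> list[tuple[Image, datetime, GroundTruth]]:
    """Render a diurnal acquisition campaign with known flowering schedule.

    One image every 5 minutes from 08:00 to 16:00 (97 per day) for ``days``
    consecutive days. At each instant the number of flowering panicles is
    Poisson with rate ``amplitude * exp(-(t - peak)^2 / (2 * width^2))``;
    ``peak_time`` is either a single time of day or a {day index: time} map
    (day indices start at 0), letting individual days emulate rain-delayed
    afternoon peaks.
    """
    if days < 1:
        raise ValueError(f"days must be >= 1, got {days}")
    if width_minutes <= 0:
        raise ValueError("width_minutes must be > 0")
    spec = spec or CanopySpec()
    rng = np.random.default_rng(seed)
    out: list[tuple[Image, datetime, GroundTruth]] = []
    for d in range(days):
        day = start_date + timedelta(days=d)
        peak = peak_time.get(d) if isinstance(peak_time, dict) else peak_time
        if peak is None:
            raise ValueError(f"peak_time map lacks day index {d}")
        peak_min = peak.hour * 60 + peak.minute
        for ts in _day_timestamps(day):
            t_min = ts.hour * 60 + ts.minute
            rate = amplitude * math.exp(
                -((t_min - peak_min) ** 2) / (2.0 * width_minutes ** 2)
            )
            n_fl = int(rng.poisson(rate))
            img_seed = int(rng.integers(0, 2**31 - 1))
            frame_spec = replace(spec, n_flowering=n_fl, seed=img_seed)
            img, gt = render_canopy(frame_spec)
            img.timestamp = ts
            img.source_path = f"synthetic_{ts.strftime('%Y%m%d_%H%M')}"
            out.append((img, ts, gt))
    return out
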