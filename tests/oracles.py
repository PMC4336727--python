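"""Independent brute-force oracles used by the unit and acceptance tests.

These are deliberately naive re-derivations — flood fill by stack walking,
exhaustive nearest-neighbor search, a literal per-pixel SIFT transcription —
kept separate from the implementation paths they validate.
"""

import math

import numpy as np

TWO_PI = 2.0 * math.pi


def flood_fill_components(verdicts: np.ndarray, connectivity: int) -> list[set]:
    """Connected components of a boolean grid by explicit stack flood fill."""
    if connectivity == 4:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        neigh = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros_like(verdicts, dtype=bool)
    comps = []
    rows, cols = verdicts.shape
    for r in range(rows):
        for c in range(cols):
            if verdicts[r, c] and not seen[r, c]:
                comp = set()
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    comp.add((rr, cc))
                    for dr, dc in neigh:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < rows and 0 <= nc < cols and verdicts[nr, nc] \
                                and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
                comps.append(comp)
    return comps


def nearest_center(descriptor: np.ndarray, centers: np.ndarray) -> int:
    """Exhaustive nearest-neighbor with lowest-index tie-breaking."""
    best, best_d = 0, np.inf
    for i, c in enumerate(centers):
        d = float(np.sum((descriptor - c) ** 2))
        if d < best_d:
            best, best_d = i, d
    return best


def reference_sift(lum: np.ndarray, center: tuple, radius: int, theta: float) -> np.ndarray:
    """Literal per-pixel transcription of the descriptor conventions.

    Zero-padded luminance, central-difference gradients, nearest-pixel
    sampling of the rotated 4r x 4r square, hard binning into 16 patches x
    8 orientation bins, L2 normalize / clip 0.2 / renormalize.
    """
    lum = np.asarray(lum, dtype=np.float64)
    h, w = lum.shape

    def lum_at(yy, xx):
        if 0 <= yy < h and 0 <= xx < w:
            return lum[yy, xx]
        return 0.0

    def grad(yy, xx):
        gx = (lum_at(yy, xx + 1) - lum_at(yy, xx - 1)) / 2.0
        gy = (lum_at(yy + 1, xx) - lum_at(yy - 1, xx)) / 2.0
        return gx, gy

    cx, cy = center
    side = 4 * radius
    desc = np.zeros(128)
    c, s = math.cos(theta), math.sin(theta)
    for v in range(side):
        for u in range(side):
            ox = u - side / 2.0 + 0.5
            oy = v - side / 2.0 + 0.5
            dx = c * ox - s * oy
            dy = s * ox + c * oy
            xx = cx + int(round(dx))
            yy = cy + int(round(dy))
            gx, gy = grad(yy, xx)
            mag = math.hypot(gx, gy)
            if mag > 0.0:
                rel = math.atan2(gy, gx) - theta
                rel %= TWO_PI
                b = min(int(rel * 8 / TWO_PI), 7)
                patch = (v // radius) * 4 + (u // radius)
                desc[patch * 8 + b] += mag
    norm = np.linalg.norm(desc)
    if norm == 0:
        return desc
    desc = np.minimum(desc / norm, 0.2)
    return desc / np.linalg.norm(desc)


def reference_dominant_orientation(lum: np.ndarray, center: tuple, radius: int) -> float:
    lum = np.asarray(lum, dtype=np.float64)
    h, w = lum.shape

    def lum_at(yy, xx):
        if 0 <= yy < h and 0 <= xx < w:
            return lum[yy, xx]
        return 0.0

    cx, cy = center
    sigma = radius / 2.0
    hist = np.zeros(36)
    total = 0.0
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            if dx * dx + dy * dy > radius * radius:
                continue
            xx, yy = cx + dx, cy + dy
            gx = (lum_at(yy, xx + 1) - lum_at(yy, xx - 1)) / 2.0
            gy = (lum_at(yy + 1, xx) - lum_at(yy - 1, xx)) / 2.0
            mag = math.hypot(gx, gy)
            if mag > 0.0:
                ang = math.atan2(gy, gx) % TWO_PI
                b = min(int(ang * 36 / TWO_PI), 35)
                weight = math.exp(-(dx * dx + dy * dy) / (2 * sigma * sigma))
                hist[b] += weight * mag
                total += weight * mag
    if total == 0.0:
        return 0.0
    return (int(np.argmax(hist)) + 0.5) * TWO_PI / 36


def lloyd_kmeans(X: np.ndarray, init_centers: np.ndarray, max_iter: int = 300):
    """Plain-python Lloyd iteration used as the clustering oracle."""
    centers = init_centers.copy().astype(float)
    assign = None
    for _ in range(max_iter):
        new_assign = np.array([nearest_center(x, centers) for x in X])
        if assign is not None and np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(len(centers)):
            members = X[assign == j]
            if len(members):
                centers[j] = members.mean(axis=0)
    inertia = sum(float(np.sum((x - centers[a]) ** 2)) for x, a in zip(X, assign))
    return centers, assign, inertia
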