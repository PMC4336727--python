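"""Flowering-vs-background classification of BoVW histograms.

The classifier is the additive chi-square kernel SVM standard for
histogram data, trained in primal form: each L1-normalized visual-word
histogram is lifted by the closed-form homogeneous kernel map, whose inner
products approximate

    K(x, y) = sum_i 2 x_i y_i / (x_i + y_i),

and a linear soft-margin SVM (hinge loss) is fitted on the lifted vectors.
For the chi-square kernel the map's spectrum is kappa(lambda) =
sech(pi * lambda); each histogram bin ``x`` expands into ``2n + 1``
coordinates

    sqrt(x * L),
    sqrt(2 x L sech(pi j L)) * cos(j L log x),   j = 1..n
    sqrt(2 x L sech(pi j L)) * sin(j L log x),   j = 1..n

with x = 0 mapping to zeros. Defaults n = 2, L = 0.5 keep the kernel
approximation error below 1e-2 on normalized histograms while expanding a
600-bin histogram to only 3000 dimensions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.svm import LinearSVC

from .features import GridSpec, dense_multiscale_sift
from .image_io import Image
from .vocabulary import BoVWHistogram, Codebook, bovw_histogram

__all__ = [
    "PatchSample",
    "FlowerModel",
    "ConfusionCounts",
    "chi2_kernel",
    "kernel_map",
    "kernel_map_matrix",
    "suggested_period",
    "train_model",
    "predict",
    "evaluate_metrics",
    "save_model",
    "load_model",
]

FLOWERING = 1
BACKGROUND = -1

DEFAULT_MAP_ORDER = 2
DEFAULT_MAP_PERIOD = 0.5
DEFAULT_C = 1.0
DEFAULT_WINDOW_PX = 140


@dataclass
class PatchSample:
    """A labeled training patch: +1 contains flowering panicle parts, -1 not."""

    patch: Image
    label: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.label not in (FLOWERING, BACKGROUND):
            raise ValueError(f"label must be +1 or -1, got {self.label}")
        if self.patch.height < 1 or self.patch.width < 1:
            raise ValueError("patch must be nonempty")


@dataclass
class FlowerModel:
    """Fitted linear SVM over kernel-mapped BoVW histograms."""

    weights: np.ndarray
    bias: float
    map_order_n: int
    map_period_L: float
    C: float
    k: int
    window_px: int = DEFAULT_WINDOW_PX
    codebook_ref: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64).ravel()
        expected = (2 * self.map_order_n + 1) * self.k
        if self.weights.shape[0] != expected:
            raise ValueError(
                f"weight dimension {self.weights.shape[0]} != (2n+1)*k = {expected}"
            )
        if self.C <= 0:
            raise ValueError(f"C must be > 0, got {self.C}")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")


def chi2_kernel(h1: np.ndarray, h2: np.ndarray) -> float:
    """Additive chi-square histogram kernel sum_i 2 h1_i h2_i / (h1_i + h2_i)."""
    a = np.asarray(h1, dtype=np.float64).ravel()
    b = np.asarray(h2, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError(f"histogram lengths differ: {a.shape[0]} vs {b.shape[0]}")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("chi-square kernel requires nonnegative histograms")
    denom = a + b
    mask = denom > 0
    return float(np.sum(2.0 * a[mask] * b[mask] / denom[mask]))


def kernel_map_matrix(H: np.ndarray, n: int = DEFAULT_MAP_ORDER,
                      L: float = DEFAULT_MAP_PERIOD) -> np.ndarray:
    """Homogeneous chi-square kernel map applied row-wise to (m, k) histograms.

    Output is (m, (2n+1)*k); the 2n+1 coordinates of each bin are contiguous.
    """
    if n < 1:
        raise ValueError(f"map order n must be >= 1, got {n}")
    if L <= 0:
        raise ValueError(f"map period L must be > 0, got {L}")
    H = np.atleast_2d(np.asarray(H, dtype=np.float64))
    if np.any(H < 0):
        raise ValueError("kernel map requires nonnegative histograms")
    m, k = H.shape
    out = np.zeros((m, k, 2 * n + 1))
    pos = H > 0
    x = H[pos]
    logx = np.log(x)
    out[..., 0][pos] = np.sqrt(x * L)  # kappa(0) = sech(0) = 1
    for j in range(1, n + 1):
        kappa = 1.0 / np.cosh(np.pi * j * L)
        amp = np.sqrt(2.0 * x * L * kappa)
        out[..., 2 * j - 1][pos] = amp * np.cos(j * L * logx)
        out[..., 2 * j][pos] = amp * np.sin(j * L * logx)
    return out.reshape(m, k * (2 * n + 1))


def kernel_map(h: np.ndarray, n: int = DEFAULT_MAP_ORDER,
               L: float = DEFAULT_MAP_PERIOD) -> np.ndarray:
    """Kernel map of a single histogram; see :func:`kernel_map_matrix`."""
    h = np.asarray(h, dtype=np.float64).ravel()
    return kernel_map_matrix(h[None, :], n=n, L=L)[0]


def suggested_period(n: int) -> float:
    """Sampling period L best suited to a map of order ``n``.

    The map's inner product differs from the exact kernel, per histogram
    bin, by ``sqrt(x*y) * (p(r) - sech(r/2))`` where ``r = log(x/y)`` and

        p(r) = L * (1 + 2 * sum_j sech(pi j L) cos(j L r)),   j = 1..n,

    a rectangle-rule/truncation approximation of the kernel's spectral
    representation. Increasing the order only helps if the period shrinks
    with it: at fixed L the periodization bias dominates and more terms do
    not reduce the error. This picks L on a 0.005 grid minimizing the
    kernel-magnitude-weighted worst case ``|p(r) - sech(r/2)| * sech(r/2)``
    over log-ratios r in [0, 4] — closed-form, data-free, and yielding
    L = 0.5 at the default order n = 2.
    """
    if n < 1:
        raise ValueError(f"map order n must be >= 1, got {n}")
    r = np.linspace(0.0, 4.0, 1201)
    target = 1.0 / np.cosh(r / 2.0)
    j = np.arange(1, n + 1)[:, None]
    best_L, best_err = None, np.inf
    for L in np.arange(0.20, 0.9001, 0.005):
        prof = L * (1.0 + 2.0 * np.sum(
            (1.0 / np.cosh(np.pi * j * L)) * np.cos(j * L * r[None, :]), axis=0
        ))
        err = np.max(np.abs(prof - target) * target)
        if err < best_err:
            best_L, best_err = L, err
    return float(best_L)


def _patch_histogram(patch: Image, codebook: Codebook, grid: GridSpec) -> np.ndarray:
    dset = dense_multiscale_sift(patch.luminance, grid)
    return bovw_histogram(dset, codebook, normalize=True).counts


def train_model(samples: list[PatchSample], codebook: Codebook,
                params: dict | None = None, seed: int = 0,
                grid: GridSpec | None = None,
                window_px: int = DEFAULT_WINDOW_PX,
                codebook_ref: str = "") -> FlowerModel:
    """Fit the flowering-detection SVM from labeled patches.

    Each patch runs through dense multi-scale SIFT, L1-normalized BoVW
    encoding against ``codebook`` and the homogeneous kernel map; a linear
    hinge-loss SVM is then fitted on the mapped vectors. Deterministic for
    fixed inputs and seed.
    """
    params = dict(params or {})
    C = float(params.pop("C", DEFAULT_C))
    n = int(params.pop("n", DEFAULT_MAP_ORDER))
    L = float(params.pop("L", DEFAULT_MAP_PERIOD))
    if params:
        raise ValueError(f"unknown training parameters: {sorted(params)}")
    if not samples:
        raise ValueError("cannot train on an empty sample list")
    labels = np.array([s.label for s in samples])
    if len(set(labels.tolist())) < 2:
        raise ValueError("training requires both flowering and background samples")
    grid = grid or GridSpec()
    hists = np.stack([_patch_histogram(s.patch, codebook, grid) for s in samples])
    X = kernel_map_matrix(hists, n=n, L=L)
    svc = LinearSVC(
        C=C,
        loss="hinge",
        random_state=seed,
        max_iter=50000,
        tol=1e-6,
    ).fit(X, labels)
    return FlowerModel(
        weights=svc.coef_.ravel(),
        bias=float(svc.intercept_[0]),
        map_order_n=n,
        map_period_L=L,
        C=C,
        k=codebook.k,
        window_px=window_px,
        codebook_ref=codebook_ref,
        seed=seed,
    )


def predict(h: BoVWHistogram | np.ndarray, model: FlowerModel) -> tuple[int, float]:
    """Classify one histogram; returns (label, decision score).

    The label is +1 (flowering) iff the score is strictly positive; a score
    of exactly zero is classified as background.
    """
    counts = h.counts if isinstance(h, BoVWHistogram) else np.asarray(h, dtype=np.float64)
    counts = counts.ravel()
    if counts.shape[0] != model.k:
        raise ValueError(f"histogram length {counts.shape[0]} != model k {model.k}")
    phi = kernel_map(counts, n=model.map_order_n, L=model.map_period_L)
    score = float(phi @ model.weights + model.bias)
    return (FLOWERING if score > 0 else BACKGROUND), score


def evaluate_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Accuracy, TP rate and TN rate from confusion counts.

    accuracy = (TP+TN)/(TP+FP+TN+FN); tp_rate = TP/(TP+FN);
    tn_rate = TN/(FP+TN). A rate whose denominator is zero is reported as
    ``None`` (undefined), never as 0.
    """
    total = c.TP + c.FP + c.TN + c.FN
    if total == 0:
        raise ValueError("confusion counts are all zero")
    return {
        "accuracy": (c.TP + c.TN) / total,
        "tp_rate": c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else None,
        "tn_rate": c.TN / (c.FP + c.TN) if (c.FP + c.TN) > 0 else None,
    }


def save_model(model: FlowerModel, path: str | Path) -> None:
    payload = {
        "weights": model.weights.tolist(),
        "bias": model.bias,
        "map_order_n": model.map_order_n,
        "map_period_L": model.map_period_L,
        "C": model.C,
        "k": model.k,
        "window_px": model.window_px,
        "codebook_ref": model.codebook_ref,
        "seed": model.seed,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> FlowerModel:
    payload = json.loads(Path(path).read_text())
    return FlowerModel(
        weights=np.asarray(payload["weights"], dtype=np.float64),
        bias=float(payload["bias"]),
        map_order_n=int(payload["map_order_n"]),
        map_period_L=float(payload["map_period_L"]),
        C=float(payload["C"]),
        k=int(payload["k"]),
        window_px=int(payload["window_px"]),
        codebook_ref=str(payload.get("codebook_ref", "")),
        seed=int(payload.get("seed", 0)),
    )
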