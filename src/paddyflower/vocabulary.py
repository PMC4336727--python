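"""Visual-word vocabulary: k-means codebook training and BoVW encoding.

The vocabulary is a set of ``k`` cluster centers (default 600) in the
128-dimensional descriptor space, trained with Lloyd's algorithm restarted
several times from random data points as initial centers; the restart with
the lowest within-cluster sum of squares wins. Descriptor sets are encoded
as histograms of nearest-center assignments ("bag of visual words");
zero descriptors — flat, texture-free supports — carry no evidence and are
excluded from both training and encoding.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .features import DESC_DIM, DescriptorSet

__all__ = [
    "Codebook",
    "BoVWHistogram",
    "train_codebook",
    "assign_word",
    "assign_words",
    "bovw_histogram",
    "nonzero_descriptors",
    "save_codebook",
    "load_codebook",
]

DEFAULT_K = 600
DEFAULT_RESTARTS = 8
MAX_ITER = 300


@dataclass
class Codebook:
    """k visual words (cluster centers) plus training provenance."""

    centers: np.ndarray  # (k, 128) float64
    k: int
    inertia: float
    seed: int
    n_restarts: int
    restart_inertias: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64)
        if self.centers.shape != (self.k, DESC_DIM):
            raise ValueError(
                f"centers shape {self.centers.shape} inconsistent with k={self.k}"
            )
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("codebook centers must be finite")


@dataclass
class BoVWHistogram:
    """Visual-word occurrence histogram over a descriptor set."""

    counts: np.ndarray
    normalized: bool

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)


def nonzero_descriptors(dset: DescriptorSet) -> np.ndarray:
    """Flatten a DescriptorSet and drop all-zero (flat-support) rows."""
    flat = dset.flat()
    if flat.shape[0] == 0:
        return flat
    return flat[np.any(flat != 0.0, axis=1)]


def train_codebook(descriptors: np.ndarray, k: int = DEFAULT_K,
                   n_restarts: int = DEFAULT_RESTARTS, seed: int = 0) -> Codebook:
    """Train the visual vocabulary by restarted Lloyd's k-means.

    Each restart initializes centers as ``k`` distinct descriptors drawn
    uniformly at random (seeded); the restart with minimum inertia is kept.
    """
    X = np.asarray(descriptors, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != DESC_DIM:
        raise ValueError(f"descriptors must be (n, {DESC_DIM}), got {X.shape}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if X.shape[0] < k:
        raise ValueError(
            f"need at least k={k} descriptors to train the codebook, got {X.shape[0]}"
        )
    if n_restarts < 1:
        raise ValueError(f"n_restarts must be >= 1, got {n_restarts}")
    rng = np.random.default_rng(seed)
    best: KMeans | None = None
    inertias: list[float] = []
    for _ in range(n_restarts):
        init_idx = rng.choice(X.shape[0], size=k, replace=False)
        km = KMeans(
            n_clusters=k,
            init=X[init_idx],
            n_init=1,
            max_iter=MAX_ITER,
            tol=0.0,
            random_state=0,
        ).fit(X)
        inertias.append(float(km.inertia_))
        if best is None or km.inertia_ < best.inertia_:
            best = km
    assert best is not None
    return Codebook(
        centers=best.cluster_centers_.astype(np.float64),
        k=k,
        inertia=float(best.inertia_),
        seed=seed,
        n_restarts=n_restarts,
        restart_inertias=tuple(inertias),
    )


def assign_words(descriptors: np.ndarray, codebook: Codebook,
                 chunk: int = 8192) -> np.ndarray:
    """Nearest-center index for each descriptor row (ties -> lowest index)."""
    X = np.ascontiguousarray(descriptors, dtype=np.float32)
    if X.ndim != 2 or X.shape[1] != codebook.centers.shape[1]:
        raise ValueError(
            f"descriptor dimension {X.shape} does not match codebook "
            f"{codebook.centers.shape}"
        )
    C = np.ascontiguousarray(codebook.centers, dtype=np.float32)
    c2 = np.einsum("ij,ij->i", C, C)
    out = np.empty(X.shape[0], dtype=np.int64)
    for start in range(0, X.shape[0], chunk):
        block = X[start:start + chunk]
        d2 = c2[None, :] - 2.0 * (block @ C.T)
        out[start:start + chunk] = np.argmin(d2, axis=1)
    return out


def assign_word(descriptor: np.ndarray, codebook: Codebook) -> int:
    """Visual word (nearest-center index) of a single descriptor."""
    d = np.asarray(descriptor, dtype=np.float64).ravel()
    if d.shape[0] != codebook.centers.shape[1]:
        raise ValueError(
            f"descriptor length {d.shape[0]} does not match codebook dimension "
            f"{codebook.centers.shape[1]}"
        )
    diff = codebook.centers - d[None, :]
    return int(np.argmin(np.einsum("ij,ij->i", diff, diff)))


def bovw_histogram(dset: DescriptorSet, codebook: Codebook,
                   normalize: bool = True) -> BoVWHistogram:
    """Histogram of visual words over every point and scale of a set.

    Zero-vector descriptors are skipped; with ``normalize`` the counts are
    divided by their sum (L1), leaving an all-zero histogram for empty input.
    """
    descs = nonzero_descriptors(dset)
    counts = np.zeros(codebook.k)
    if descs.shape[0] > 0:
        words = assign_words(descs, codebook)
        np.add.at(counts, words, 1.0)
    if normalize:
        total = counts.sum()
        if total > 0:
            counts = counts / total
    return BoVWHistogram(counts=counts, normalized=normalize)


def save_codebook(codebook: Codebook, path: str | Path) -> None:
    """Persist as CSV: metadata comment lines + k rows of 128 columns."""
    header = (
        f"paddyflower codebook k={codebook.k} seed={codebook.seed} "
        f"n_restarts={codebook.n_restarts} inertia={codebook.inertia!r} "
        f"restart_inertias={','.join(repr(v) for v in codebook.restart_inertias)}"
    )
    np.savetxt(path, codebook.centers, delimiter=",", fmt="%.17g", header=header)


def load_codebook(path: str | Path) -> Codebook:
    with open(path) as fh:
        first = fh.readline()
    meta = {}
    for token in first.lstrip("# ").split():
        if "=" in token:
            key, val = token.split("=", 1)
            meta[key] = val
    centers = np.loadtxt(path, delimiter=",", ndmin=2)
    restarts = tuple(
        float(v) for v in meta.get("restart_inertias", "").split(",") if v
    )
    return Codebook(
        centers=centers,
        k=int(meta.get("k", centers.shape[0])),
        inertia=float(meta.get("inertia", "nan")),
        seed=int(meta.get("seed", 0)),
        n_restarts=int(meta.get("n_restarts", 1)),
        restart_inertias=restarts,
    )
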