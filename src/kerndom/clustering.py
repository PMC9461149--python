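"""Kernel k-means and spectral clustering of residues from a kernel matrix.

Both clusterers take the number of clusters m and are restarted from many
random initializations (100 by default), keeping the labelling with the
lowest within-cluster sum of squared feature-space distances. All randomness
flows from an explicit seed, so a run is exactly reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.cluster import KMeans

from .kernels import KernelMatrix

logger = logging.getLogger(__name__)

DEFAULT_RESTARTS = 100
MAX_ITER = 300


@dataclass
class ClusterLabels:
    """A residue labelling: entries in {1..m}, plus the clustering objective."""

    labels: np.ndarray
    m: int
    objective: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)


def _as_matrix(K: KernelMatrix | np.ndarray) -> np.ndarray:
    return K.K if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)


def _kkm_single(K: np.ndarray, m: int, rng: np.random.Generator,
                trace: list[float] | None = None):
    """One kernel k-means run from a random partition; returns (labels, obj)."""
    n = K.shape[0]
    diag = np.diag(K)
    labels = rng.integers(0, m, size=n)
    # guarantee every cluster starts non-empty
    labels[rng.choice(n, size=m, replace=False)] = np.arange(m)

    for _ in range(MAX_ITER):
        H = np.zeros((n, m))
        H[np.arange(n), labels] = 1.0
        sizes = H.sum(axis=0)
        Hn = H / sizes
        KH = K @ Hn                      # (i,c) -> mean_{j in c} K_ij
        s = np.einsum("ic,ic->c", Hn, K @ Hn)  # mean_{j,j' in c} K_jj'
        dist2 = diag[:, None] - 2.0 * KH + s[None, :]
        if trace is not None:
            trace.append(float(np.clip(dist2[np.arange(n), labels], 0, None).sum()))
        new_labels = np.argmin(dist2, axis=1)

        # empty-cluster repair: move the point farthest from its own centroid
        for c in range(m):
            if not np.any(new_labels == c):
                own = dist2[np.arange(n), new_labels].copy()
                counts = np.bincount(new_labels, minlength=m)
                own[counts[new_labels] <= 1] = -np.inf  # keep clusters alive
                new_labels[int(np.argmax(own))] = c

        if np.array_equal(new_labels, labels):
            break
        labels = new_labels

    H = np.zeros((n, m))
    H[np.arange(n), labels] = 1.0
    Hn = H / H.sum(axis=0)
    KH = K @ Hn
    s = np.einsum("ic,ic->c", Hn, K @ Hn)
    dist2 = diag[:, None] - 2.0 * KH + s[None, :]
    obj = float(np.clip(dist2[np.arange(n), labels], 0.0, None).sum())
    return labels, obj


def kernel_kmeans(
    K: KernelMatrix | np.ndarray,
    m: int,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
) -> ClusterLabels:
    """Kernel k-means: k-means in the kernel's feature space.

    Point-to-centroid distances are computed implicitly from the kernel
    (K_ii - 2 mean_{j in C} K_ij + mean_{j,j' in C} K_jj'). The best of
    ``restarts`` random initial partitions (lowest within-cluster
    sum-of-squares) is returned; ties keep the earliest restart.
    """
    Km = _as_matrix(K)
    n = Km.shape[0]
    if not (2 <= m <= n):
        raise ValueError(f"m={m} out of range [2, {n}]")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    best_labels, best_obj = None, np.inf
    for r in range(restarts):
        rng = np.random.default_rng(int(seed) + r)
        labels, obj = _kkm_single(Km, m, rng)
        if obj < best_obj - 1e-12:
            best_labels, best_obj = labels, obj
    return ClusterLabels(labels=best_labels + 1, m=m, objective=best_obj)


def spectral(
    K: KernelMatrix | np.ndarray,
    m: int,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
    normalized: bool = True,
) -> ClusterLabels:
    """Spectral clustering of the kernel matrix treated as a similarity.

    Ng-Jordan-Weiss variant: symmetric-normalized Laplacian, embedding by the
    m smallest-eigenvalue eigenvectors with row normalization, then standard
    k-means with ``restarts`` restarts. ``normalized=False`` uses the
    unnormalized Laplacian and skips row normalization.
    """
    S = _as_matrix(K).copy()
    n = S.shape[0]
    if not (2 <= m <= n):
        raise ValueError(f"m={m} out of range [2, {n}]")
    if np.any(S < 0):
        logger.warning("negative similarities clamped to 0 for spectral clustering")
        np.clip(S, 0.0, None, out=S)
    np.fill_diagonal(S, 0.0)
    deg = S.sum(axis=1)
    if np.all(deg == 0):
        raise ValueError("all-zero similarity matrix")

    if normalized:
        d = np.where(deg > 0, deg, 1.0)
        inv_sqrt = 1.0 / np.sqrt(d)
        L = np.eye(n) - inv_sqrt[:, None] * S * inv_sqrt[None, :]
    else:
        L = np.diag(deg) - S
    w, U = scipy.linalg.eigh((L + L.T) / 2.0)
    emb = U[:, np.argsort(w)[:m]]
    if normalized:
        norms = np.linalg.norm(emb, axis=1)
        emb = emb / np.where(norms > 0, norms, 1.0)[:, None]

    km = KMeans(
        n_clusters=m,
        n_init=restarts,
        max_iter=MAX_ITER,
        random_state=int(seed) % (2**31),
    ).fit(emb)
    return ClusterLabels(labels=km.labels_ + 1, m=m, objective=float(km.inertia_))
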