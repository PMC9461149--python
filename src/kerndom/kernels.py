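"""Diffusion kernels on the residue contact graph.

Four graph node kernels are supported, each a symmetric positive
semi-definite affinity between residues:

- LED: Laplacian exponential diffusion, K = exp(-beta L)
- MD:  Markov diffusion, K = Z(t) Z(t)^T with Z(t) = (1/t) sum_{tau<=t} P^tau,
       P = D^-1 A
- MED: Markov exponential diffusion, K = exp(-beta M) with
       M = (D - A - n* I) / n*, n* = max weighted degree + 1, which rebalances
       LED so central (high-degree) nodes are not favoured
- RL:  regularized Laplacian, K = (I + alpha L)^-1, summing walks of every
       length between two nodes

The bandwidth (beta, t or alpha) is tied to the structure's size through the
radius of gyration: bandwidth = eta * Rg^2, with per-(kernel, clusterer)
defaults in ETA_DEFAULTS. The kernel induces a feature-space metric
D_ij = sqrt(K_ii - 2 K_ij + K_jj) used by segment merging and the silhouette.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .contacts import ContactGraph, weighted_degree_max

KERNEL_KINDS = ("led", "md", "med", "rl")

#: Default bandwidth proportionality constants eta, keyed by
#: (kernel kind, clusterer) with clusterer in {"kernel-kmeans", "spectral"}.
ETA_DEFAULTS: dict[tuple[str, str], float] = {
    ("led", "kernel-kmeans"): 6e-3,
    ("led", "spectral"): 4e-3,
    ("md", "kernel-kmeans"): 2.5e-1,
    ("md", "spectral"): 8e-1,
    ("med", "kernel-kmeans"): 4e-1,
    ("med", "spectral"): 3.5e-1,
    ("rl", "kernel-kmeans"): 2.1e-2,
    ("rl", "spectral"): 2.2e-2,
}


@dataclass
class KernelMatrix:
    K: np.ndarray
    kind: str
    bandwidth: float

    @property
    def n(self) -> int:
        return self.K.shape[0]


@dataclass
class DistanceMatrix:
    D: np.ndarray

    @property
    def n(self) -> int:
        return self.D.shape[0]


@dataclass
class BandwidthRule:
    """bandwidth = eta * Rg^2; for the MD kernel rounded to an integer >= 1."""

    eta: float
    rg: float

    def __post_init__(self) -> None:
        if not (self.eta > 0):
            raise ValueError(f"eta must be positive, got {self.eta}")


def bandwidth(rule: BandwidthRule, kind: str = "led") -> float:
    """Realize the bandwidth for a kernel kind from eta and Rg."""
    if not (rule.rg > 0):
        raise ValueError(f"radius of gyration must be positive, got {rule.rg}")
    value = rule.eta * rule.rg**2
    if kind == "md":  # discrete diffusion time
        return float(max(1, round(value)))
    return float(value)


def default_bandwidth(kind: str, clusterer: str, rg: float, eta: float | None = None):
    """Bandwidth from the default (or user-supplied) eta for a configuration."""
    if eta is None:
        eta = ETA_DEFAULTS[(kind, clusterer)]
    return bandwidth(BandwidthRule(eta=eta, rg=rg), kind=kind)


def _sym_expm(M: np.ndarray) -> np.ndarray:
    """exp(M) for symmetric M via eigendecomposition (stable, exactly symmetric)."""
    w, U = scipy.linalg.eigh(M)
    E = (U * np.exp(w)) @ U.T
    return (E + E.T) / 2.0


def led_kernel(graph: ContactGraph, beta: float) -> KernelMatrix:
    """Laplacian exponential diffusion kernel K = exp(-beta L)."""
    if not np.isfinite(beta) or beta < 0:
        raise ValueError(f"beta must be finite and >= 0, got {beta}")
    K = _sym_expm(-beta * graph.laplacian)
    return KernelMatrix(K=K, kind="led", bandwidth=float(beta))


def md_kernel(graph: ContactGraph, t: int) -> KernelMatrix:
    """Markov diffusion kernel K = Z(t) Z(t)^T, Z(t) = (1/t) sum P^tau."""
    t = int(t)
    if t < 1:
        raise ValueError(f"t must be a positive integer, got {t}")
    deg = graph.degrees
    if np.any(deg <= 0):
        raise ValueError("isolated node: transition matrix P = D^-1 A undefined")
    P = graph.adjacency / deg[:, None]
    Z = np.zeros_like(P)
    Ppow = np.eye(graph.n_nodes)
    for _ in range(t):
        Ppow = Ppow @ P
        Z += Ppow
    Z /= t
    K = Z @ Z.T
    return KernelMatrix(K=(K + K.T) / 2.0, kind="md", bandwidth=float(t))


def med_kernel(graph: ContactGraph, beta: float) -> KernelMatrix:
    """Markov exponential diffusion kernel K = exp(-beta (D - A - n* I)/n*)."""
    if not np.isfinite(beta) or beta < 0:
        raise ValueError(f"beta must be finite and >= 0, got {beta}")
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    n_star = weighted_degree_max(graph) + 1.0
    M = (graph.laplacian - n_star * np.eye(graph.n_nodes)) / n_star
    K = _sym_expm(-beta * M)
    return KernelMatrix(K=K, kind="med", bandwidth=float(beta))


def rl_kernel(graph: ContactGraph, alpha: float) -> KernelMatrix:
    """Regularized Laplacian kernel K = (I + alpha L)^-1."""
    if not (alpha > 0) or not np.isfinite(alpha):
        raise ValueError(f"alpha must be positive and finite, got {alpha}")
    n = graph.n_nodes
    A = np.eye(n) + alpha * graph.laplacian
    c, low = scipy.linalg.cho_factor(A)
    K = scipy.linalg.cho_solve((c, low), np.eye(n))
    return KernelMatrix(K=(K + K.T) / 2.0, kind="rl", bandwidth=float(alpha))


def compute_kernel(graph: ContactGraph, kind: str, bw: float) -> KernelMatrix:
    """Dispatch on kernel kind with a realized bandwidth value."""
    if kind == "led":
        return led_kernel(graph, bw)
    if kind == "md":
        return md_kernel(graph, int(bw))
    if kind == "med":
        return med_kernel(graph, bw)
    if kind == "rl":
        return rl_kernel(graph, bw)
    raise ValueError(f"unknown kernel kind {kind!r}; expected one of {KERNEL_KINDS}")


def kernel_to_distance(kernel: KernelMatrix | np.ndarray) -> DistanceMatrix:
    """Feature-space metric D_ij = sqrt(K_ii - 2 K_ij + K_jj).

    Negative values from round-off are clamped to zero before the square
    root; the diagonal is exactly zero.
    """
    K = kernel.K if isinstance(kernel, KernelMatrix) else np.asarray(kernel)
    diag = np.diag(K)
    sq = diag[:, None] - 2.0 * K + diag[None, :]
    np.clip(sq, 0.0, None, out=sq)
    D = np.sqrt(sq)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D=(D + D.T) / 2.0)


def kpca_embed(kernel: KernelMatrix | np.ndarray, n_components: int) -> np.ndarray:
    """Kernel PCA coordinates from a double-centered kernel matrix.

    Eigenvectors of the centered kernel, scaled by sqrt of their (clamped
    non-negative) eigenvalues, ordered by decreasing eigenvalue. With
    ``n_components = n`` the pairwise Euclidean distances of the embedding
    reproduce :func:`kernel_to_distance`.
    """
    K = kernel.K if isinstance(kernel, KernelMatrix) else np.asarray(kernel)
    n = K.shape[0]
    if n_components < 1:
        raise ValueError(f"n_components must be >= 1, got {n_components}")
    if n_components > n:
        raise ValueError(f"n_components={n_components} exceeds n={n}")
    ones = np.full((n, n), 1.0 / n)
    Kc = K - ones @ K - K @ ones + ones @ K @ ones
    w, U = scipy.linalg.eigh((Kc + Kc.T) / 2.0)
    order = np.argsort(w)[::-1][:n_components]
    lam = np.clip(w[order], 0.0, None)
    return U[:, order] * np.sqrt(lam)
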