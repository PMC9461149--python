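"""Single/multi-domain classification of a protein chain.

A chain is summarized by a fixed, documented set of per-chain features in
three overlapping families — biological (size, compactness, hydrophobicity,
accessibility), network-based (edge totals, centrality statistics,
clustering coefficients of the contact graph) and clusterability
(alpha-carbon PCA spectrum, Hopkins statistic, dip statistic) — and
classified by a bagging ensemble of decision trees. Each of the 190
bootstrap samples (the size of the training set) is balanced by SMOTE
oversampling of the minority class before its tree is fitted; prediction is
a majority vote, with ties resolved toward 'multi' (the clustering stage
can still fall back to single-domain, making that the safer direction).

The feature set covers every family used by comparable structure
classifiers, but its exact membership is a configurable reconstruction, so
the model is retrainable rather than a fixed artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx
import scipy.stats
from scipy.spatial import cKDTree
from sklearn.tree import DecisionTreeClassifier

from .contacts import ContactGraph
from .dipstat import dip_statistic
from .structure import ProteinChain

LABELS = ("single", "multi")
DEFAULT_N_ESTIMATORS = 190

_CENTRALITY_STATS = ("mean", "var", "max", "skew")


def _stats(x: np.ndarray) -> dict[str, float]:
    x = np.asarray(x, dtype=float)
    sk = scipy.stats.skew(x) if x.std() > 0 else 0.0
    return {"mean": float(x.mean()), "var": float(x.var()),
            "max": float(x.max()), "skew": float(sk)}


def _weighted_var(x: np.ndarray, w: np.ndarray) -> float:
    w = np.asarray(w, dtype=float)
    if w.sum() <= 0:
        return float(np.var(x))
    mu = np.average(x, weights=w)
    return float(np.average((x - mu) ** 2, weights=w))


def feature_names() -> list[str]:
    """The documented feature order shared by extraction and the model."""
    names = [
        "n_residues", "radius_of_gyration",
        "hydro_mean", "hydro_var", "rsa_mean", "rsa_var",
        "hydro_var_rsa_weighted", "rsa_var_degree_weighted",
        "edge_weight_total", "edge_weight_per_residue",
    ]
    for cent in ("degree", "closeness", "betweenness"):
        for mode in ("w", "u"):
            for stat in _CENTRALITY_STATS:
                names.append(f"{cent}_{mode}_{stat}")
    names += [f"pca_var{i}" for i in (1, 2, 3)]
    names += [f"pca_evr{i}" for i in (1, 2, 3)]
    names += ["pca_ratio21", "pca_ratio31", "pca_ratio32"]
    names += [f"pca_wvar{i}" for i in (1, 2, 3)]
    names += ["hopkins_stat", "dip_stat",
              "clustering_global", "clustering_avg_local"]
    return names


FEATURE_ORDER: list[str] = feature_names()


def hopkins(points: np.ndarray, sample_fraction: float = 0.25, seed: int = 0) -> float:
    """Hopkins clusterability statistic in [0, 1].

    Compares nearest-neighbour distances of uniform pseudo-points in the
    data's bounding box against those of sampled real points; ~0.5 for
    spatially uniform data, near 1 for strongly clustered data. The box is
    taken in the data's own principal-axis frame (with a fixed sign
    convention), which makes the statistic rigid-motion invariant.
    """
    X = np.asarray(points, dtype=float)
    n, d = X.shape
    if n < 10:
        raise ValueError(f"Hopkins statistic needs >= 10 points, got {n}")
    centered = X - X.mean(axis=0)
    _, axes = np.linalg.eigh(centered.T @ centered)
    axes = axes[:, ::-1]
    proj = centered @ axes
    for j in range(d):  # intrinsic sign convention: positive skew
        if np.sum(proj[:, j] ** 3) < 0:
            proj[:, j] = -proj[:, j]
    X = proj
    lo, hi = X.min(axis=0), X.max(axis=0)
    if np.all(hi - lo == 0):
        raise ValueError("degenerate bounding box: all points identical")
    rng = np.random.default_rng(seed)
    m = max(1, int(round(sample_fraction * n)))
    tree = cKDTree(X)

    pseudo = rng.uniform(lo, hi, size=(m, d))
    u = tree.query(pseudo, k=1)[0]
    sample_idx = rng.choice(n, size=m, replace=False)
    w = tree.query(X[sample_idx], k=2)[0][:, 1]  # skip self-match

    num = np.sum(u)
    den = num + np.sum(w)
    if den == 0:
        raise ValueError("degenerate geometry: zero nearest-neighbour distances")
    return float(num / den)


def extract_features(
    chain: ProteinChain, graph: ContactGraph, seed: int = 0
) -> dict[str, float]:
    """Per-chain feature vector (see :func:`feature_names` for the order)."""
    if graph.n_nodes != chain.n:
        raise ValueError(
            f"graph has {graph.n_nodes} nodes but chain has {chain.n} residues"
        )
    fv: dict[str, float] = {}
    hydro = chain.hydrophobicities()
    rsa = chain.rsas()
    deg = graph.degrees

    fv["n_residues"] = float(chain.n)
    fv["radius_of_gyration"] = float(chain.rg)
    fv["hydro_mean"] = float(hydro.mean())
    fv["hydro_var"] = float(hydro.var())
    fv["rsa_mean"] = float(rsa.mean())
    fv["rsa_var"] = float(rsa.var())
    fv["hydro_var_rsa_weighted"] = _weighted_var(hydro, rsa)
    fv["rsa_var_degree_weighted"] = _weighted_var(rsa, deg)
    fv["edge_weight_total"] = graph.total_edge_weight
    fv["edge_weight_per_residue"] = graph.total_edge_weight / chain.n

    G = nx.from_numpy_array(graph.adjacency)
    for _, _, dat in G.edges(data=True):
        dat["invw"] = 1.0 / dat["weight"]
    cents = {
        ("degree", "w"): deg,
        ("degree", "u"): np.array([G.degree(i) for i in range(chain.n)], float),
        ("closeness", "w"): np.array(
            list(nx.closeness_centrality(G, distance="invw").values())
        ),
        ("closeness", "u"): np.array(list(nx.closeness_centrality(G).values())),
        ("betweenness", "w"): np.array(
            list(nx.betweenness_centrality(G, weight="invw").values())
        ),
        ("betweenness", "u"): np.array(list(nx.betweenness_centrality(G).values())),
    }
    for (cent, mode), values in cents.items():
        for stat, val in _stats(values).items():
            fv[f"{cent}_{mode}_{stat}"] = val

    ca = chain.ca_coords()
    centered = ca - ca.mean(axis=0)
    cov = centered.T @ centered / chain.n
    evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    evals = np.clip(evals, 0.0, None)
    total = evals.sum() or 1.0
    for i in range(3):
        fv[f"pca_var{i + 1}"] = float(evals[i])
    for i in range(3):
        fv[f"pca_evr{i + 1}"] = float(evals[i] / total)
    eps = 1e-12
    fv["pca_ratio21"] = float(evals[1] / (evals[0] + eps))
    fv["pca_ratio31"] = float(evals[2] / (evals[0] + eps))
    fv["pca_ratio32"] = float(evals[2] / (evals[1] + eps))
    w = rsa if rsa.sum() > 0 else np.ones(chain.n)
    mu_w = np.average(ca, axis=0, weights=w)
    cw = ca - mu_w
    cov_w = (cw * w[:, None]).T @ cw / w.sum()
    wevals = np.clip(np.sort(np.linalg.eigvalsh(cov_w))[::-1], 0.0, None)
    for i in range(3):
        fv[f"pca_wvar{i + 1}"] = float(wevals[i])

    # clusterability statistics need a minimum of points; tiny chains get
    # the unimodal/uniform neutral values
    fv["hopkins_stat"] = hopkins(ca, seed=seed) if chain.n >= 10 else 0.5
    # dip on the first principal axis: the least-favourable 1-D shadow
    first_pc = np.linalg.eigh(cov)[1][:, -1]
    fv["dip_stat"] = (
        dip_statistic(centered @ first_pc) if chain.n >= 4 else 1.0 / (2 * chain.n)
    )
    fv["clustering_global"] = float(nx.transitivity(G))
    fv["clustering_avg_local"] = float(nx.average_clustering(G))

    assert list(fv) == FEATURE_ORDER
    return fv


def feature_matrix(rows: list[dict[str, float]]) -> np.ndarray:
    return np.array([[fv[name] for name in FEATURE_ORDER] for fv in rows])


def smote_balance(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator, k: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Balance a two-class sample by SMOTE oversampling of the minority.

    Synthetic minority points are uniform interpolations between a minority
    point and one of its k nearest minority neighbours; the result has
    exactly equal class counts.
    """
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    minority = classes[np.argmin(counts)]
    deficit = int(abs(counts[0] - counts[1]))
    if deficit == 0:
        return X, y
    Xm = X[y == minority]
    if len(Xm) == 1:
        synth = np.repeat(Xm, deficit, axis=0)
    else:
        kk = min(k, len(Xm) - 1)
        nn = cKDTree(Xm).query(Xm, k=kk + 1)[1][:, 1:]
        base = rng.integers(0, len(Xm), size=deficit)
        nbr = nn[base, rng.integers(0, kk, size=deficit)]
        gamma = rng.uniform(0, 1, size=(deficit, 1))
        synth = Xm[base] + gamma * (Xm[nbr] - Xm[base])
    Xb = np.vstack([X, synth])
    yb = np.concatenate([y, np.full(deficit, minority, dtype=y.dtype)])
    return Xb, yb


@dataclass
class BaggingModel:
    """SMOTE-balanced bagging of decision trees for single/multi prediction."""

    estimators: list[DecisionTreeClassifier]
    feature_order: list[str]
    seed: int
    n_estimators: int = DEFAULT_N_ESTIMATORS
    classes: tuple[str, str] = LABELS

    def save(self, path) -> None:
        import joblib

        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "BaggingModel":
        import joblib

        model = joblib.load(path)
        if not isinstance(model, BaggingModel):
            raise TypeError(f"{path} does not contain a BaggingModel")
        return model


def train(
    X: np.ndarray,
    y: np.ndarray,
    n_estimators: int = DEFAULT_N_ESTIMATORS,
    seed: int = 0,
    feature_order: list[str] | None = None,
) -> BaggingModel:
    """Fit the bagging classifier.

    Each estimator sees a bootstrap of size equal to the training set,
    rebalanced by SMOTE, and fits an unpruned decision tree. Deterministic
    given the seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 examples of each class")
    n = len(y)
    ss = np.random.SeedSequence(seed)
    estimators = []
    for child in ss.spawn(n_estimators):
        rng = np.random.default_rng(child)
        while True:
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == 2:
                break
        Xb, yb = smote_balance(X[idx], y[idx], rng)
        tree = DecisionTreeClassifier(
            random_state=int(rng.integers(0, 2**31))
        ).fit(Xb, yb)
        estimators.append(tree)
    if feature_order is None:
        feature_order = (
            FEATURE_ORDER
            if X.shape[1] == len(FEATURE_ORDER)
            else [f"f{i}" for i in range(X.shape[1])]
        )
    return BaggingModel(
        estimators=estimators,
        feature_order=list(feature_order),
        seed=seed,
        n_estimators=n_estimators,
    )


def predict(model: BaggingModel, fv: dict[str, float] | np.ndarray):
    """Majority-vote prediction; returns (label, multi-vote fraction).

    A tie votes 'multi': the downstream clustering stage can still return a
    single domain, so over-calling multi is the recoverable error.
    """
    if isinstance(fv, dict):
        missing = [f for f in model.feature_order if f not in fv]
        if missing:
            raise ValueError(f"feature vector missing features: {missing}")
        x = np.array([[fv[name] for name in model.feature_order]])
    else:
        x = np.atleast_2d(np.asarray(fv, dtype=float))
        if x.shape[1] != len(model.feature_order):
            raise ValueError(
                f"expected {len(model.feature_order)} features, got {x.shape[1]}"
            )
    votes = np.array([est.predict(x)[0] for est in model.estimators])
    frac_multi = float(np.mean(votes == "multi"))
    label = "multi" if frac_multi >= 0.5 else "single"
    return label, frac_multi
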