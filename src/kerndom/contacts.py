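"""Residue contact graph.

Two residues are connected when at least one pair of their heavy atoms lies
within the contact cutoff (4 A by default, inclusive); the edge weight is the
number of such atom pairs. The weighted Laplacian L = D - A generates the
diffusion kernels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .structure import ProteinChain

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 4.0


@dataclass
class ContactGraph:
    """Weighted undirected residue graph with adjacency/degree/Laplacian views."""

    adjacency: np.ndarray  # symmetric, zero diagonal, non-negative counts

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def degree_matrix(self) -> np.ndarray:
        return np.diag(self.degrees)

    @property
    def laplacian(self) -> np.ndarray:
        return self.degree_matrix - self.adjacency

    @property
    def n_components(self) -> int:
        ncomp, _ = connected_components(self.adjacency > 0, directed=False)
        return int(ncomp)

    @property
    def total_edge_weight(self) -> float:
        return float(self.adjacency.sum()) / 2.0

    def write_edge_list(self, path) -> None:
        """Export as 'node1 node2 weight' lines (1-based node indices)."""
        with open(path, "w") as fh:
            ii, jj = np.nonzero(np.triu(self.adjacency))
            for i, j in zip(ii, jj):
                fh.write(f"{i + 1} {j + 1} {int(self.adjacency[i, j])}\n")


def build_contact_graph(
    chain: ProteinChain, cutoff: float = DEFAULT_CUTOFF
) -> ContactGraph:
    """Count atomic contacts (distance <= cutoff) between residue pairs.

    Unordered atom pairs are counted once; contacts within a residue are
    ignored. A disconnected graph is allowed but logged as a warning, since
    domain assignment across components is ill-posed.
    """
    n = chain.n
    if n < 2:
        raise ValueError("need at least 2 residues to build a contact graph")
    coords = []
    owner = []
    for idx, res in enumerate(chain.residues):
        for atom in res.atoms:
            coords.append(atom.coord)
            owner.append(idx)
    coords = np.asarray(coords)
    owner = np.asarray(owner)

    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    adjacency = np.zeros((n, n), dtype=float)
    if len(pairs):
        ri = owner[pairs[:, 0]]
        rj = owner[pairs[:, 1]]
        keep = ri != rj
        np.add.at(adjacency, (ri[keep], rj[keep]), 1.0)
        np.add.at(adjacency, (rj[keep], ri[keep]), 1.0)

    graph = ContactGraph(adjacency=adjacency)
    ncomp = graph.n_components
    if ncomp > 1:
        logger.warning("contact graph is disconnected (%d components)", ncomp)
    return graph


def weighted_degree_max(graph: ContactGraph) -> float:
    """Maximum weighted degree over the nodes (0 for an empty graph)."""
    if graph.n_nodes == 0:
        return 0.0
    return float(graph.degrees.max(initial=0.0))
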