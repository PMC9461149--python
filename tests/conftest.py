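"""Shared fixtures: synthetic chains, random graphs, tiny hand-built objects."""

from __future__ import annotations

import numpy as np
import pytest

from kerndom.contacts import ContactGraph, build_contact_graph
from kerndom.structure import Atom, ProteinChain, Residue
from kerndom.synth import FixtureSpec, make_chain


def toy_chain(ca_positions, aa="ALA", extra_atoms=(), ss=None, hydro=None, rsa=None):
    """Hand-build a chain from CA coordinates (one residue per coordinate)."""
    residues = []
    for i, ca in enumerate(np.asarray(ca_positions, dtype=float)):
        atoms = [Atom(name="CA", element="C", coord=ca)]
        for off in extra_atoms:
            atoms.append(Atom(name="CB", element="C", coord=ca + np.asarray(off)))
        residues.append(
            Residue(
                seq_index=i + 1,
                pdb_number=str(i + 1),
                aa_code=aa if isinstance(aa, str) else aa[i],
                atoms=atoms,
                ca_coord=ca,
                ss="-" if ss is None else ss[i],
                rsa=0.0 if rsa is None else rsa[i],
                hydrophobicity=0.0 if hydro is None else hydro[i],
            )
        )
    return ProteinChain(chain_id="A", residues=residues)


def random_weighted_graph(n: int, rng: np.random.Generator, p: float = 0.5,
                          connected: bool = True) -> ContactGraph:
    """Random integer-weighted graph; optionally forced connected via a path."""
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                A[i, j] = A[j, i] = float(rng.integers(1, 6))
    if connected:
        for i in range(n - 1):
            if A[i, i + 1] == 0:
                A[i, i + 1] = A[i + 1, i] = 1.0
    return ContactGraph(adjacency=A)


@pytest.fixture(scope="session")
def two_blob():
    """Standard two-domain fixture: 2 x 60 residues, 25 A gap."""
    chain, planted = make_chain(FixtureSpec(seed=42))
    return chain, planted


@pytest.fixture(scope="session")
def two_blob_graph(two_blob):
    chain, _ = two_blob
    return build_contact_graph(chain)
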