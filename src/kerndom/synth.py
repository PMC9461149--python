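"""Synthetic protein-like chains with planted domain structure.

The generator emulates exactly what the assignment method consumes —
residues with heavy-atom coordinates, secondary-structure labels, relative
accessibility and amino-acid identity (hence hydrophobicity) — and nothing
else about real protein physics. Each planted domain is a compact blob of
residues on a jittered cubic grid; blobs are separated by an empty gap much
wider than the contact cutoff, so the planted partition is the unambiguous
ground truth. An optional linker walks residues across the gap. At least
30% of each blob's residues are guaranteed hydrophobic (Kyte-Doolittle
index > 2) so the silhouette criterion is always computable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import KYTE_DOOLITTLE, MAX_ACCESSIBILITY, THREE_TO_ONE
from .structure import Atom, ProteinChain, Residue

HYDROPHOBIC_AA = ("ILE", "VAL", "LEU", "PHE", "CYS")  # KD > 2
OTHER_AA = ("ALA", "GLY", "SER", "THR", "ASP", "LYS", "GLN", "MET")

PDB_MAX_ATOMS = 99_999


@dataclass
class FixtureSpec:
    """Parameters of one synthetic chain.

    inter_domain_gap is the empty space (A) between blob surfaces;
    intra_packing the grid spacing (A) between neighbouring residues inside
    a blob; noise_sd the coordinate jitter (A). helix_runs marks 1-based
    inclusive residue ranges as ss 'H'.
    """

    n_domains: int = 2
    residues_per_domain: list[int] = field(default_factory=lambda: [60, 60])
    inter_domain_gap: float = 25.0
    intra_packing: float = 3.8  # the real CA-CA step along a backbone
    helix_runs: list[tuple[int, int]] | None = None
    seed: int = 0
    noise_sd: float = 0.4
    linker_length: int = 0
    hydrophobic_fraction: float = 0.45

    def __post_init__(self) -> None:
        if self.n_domains < 1 or len(self.residues_per_domain) != self.n_domains:
            raise ValueError("residues_per_domain must list one size per domain")
        if min(self.residues_per_domain) < 1:
            raise ValueError("domain sizes must be positive")
        if self.inter_domain_gap <= self.intra_packing:
            raise ValueError(
                "infeasible geometry: inter_domain_gap must exceed intra_packing"
            )


def _blob_offsets(size: int, spacing: float) -> np.ndarray:
    """Centered jig of `size` grid points, ordered for a smooth chain walk."""
    side = int(np.ceil(size ** (1 / 3)))
    pts = []
    for ix in range(side):
        for iy in range(side):
            # serpentine ordering keeps sequence neighbours spatially close
            zs = range(side) if (ix + iy) % 2 == 0 else range(side - 1, -1, -1)
            for iz in zs:
                pts.append((ix, iy, iz))
    pts = np.array(pts[:size], dtype=float) * spacing
    return pts - pts.mean(axis=0)


def _sample_aa(rng: np.random.Generator, n: int, frac_hydrophobic: float) -> list[str]:
    aa = [
        str(rng.choice(HYDROPHOBIC_AA))
        if rng.random() < frac_hydrophobic
        else str(rng.choice(OTHER_AA))
        for _ in range(n)
    ]
    # guarantee >= 30% hydrophobic so the silhouette is always computable
    hydro = [i for i, a in enumerate(aa) if KYTE_DOOLITTLE[a] > 2]
    need = int(np.ceil(0.3 * n)) - len(hydro)
    if need > 0:
        others = [i for i in range(n) if i not in hydro]
        for i in rng.choice(others, size=need, replace=False):
            aa[i] = "ILE"
    return aa


def make_chain(spec: FixtureSpec) -> tuple[ProteinChain, np.ndarray]:
    """Generate a chain and its planted per-residue domain labels (1-based).

    Linker residues (if any) are labelled with the blob whose centroid is
    nearer, so a perfect assignment can reach ARI = 1 against the plant.
    """
    rng = np.random.default_rng(spec.seed)
    blob_offsets = [
        _blob_offsets(size, spec.intra_packing) for size in spec.residues_per_domain
    ]
    extents = [off[:, 0].max() - off[:, 0].min() for off in blob_offsets]
    centers = []
    x = 0.0
    for d in range(spec.n_domains):
        if d > 0:
            x += extents[d - 1] / 2 + spec.inter_domain_gap + extents[d] / 2
        centers.append(np.array([x, 0.0, 0.0]))

    ca_positions: list[np.ndarray] = []
    labels: list[int] = []
    for d in range(spec.n_domains):
        pts = centers[d] + blob_offsets[d]
        pts = pts + rng.normal(0.0, spec.noise_sd, size=pts.shape)
        ca_positions.extend(pts)
        labels.extend([d + 1] * len(pts))
        if spec.linker_length > 0 and d < spec.n_domains - 1:
            start = pts[-1]
            end = centers[d + 1] + blob_offsets[d + 1][0]
            for k in range(1, spec.linker_length + 1):
                frac = k / (spec.linker_length + 1)
                pos = start + frac * (end - start)
                pos = pos + rng.normal(0.0, spec.noise_sd, size=3)
                ca_positions.append(pos)
                d_here = np.linalg.norm(pos - centers[d])
                d_next = np.linalg.norm(pos - centers[d + 1])
                labels.append(d + 1 if d_here <= d_next else d + 2)

    n = len(ca_positions)
    aa_codes: list[str] = []
    pos = 0
    for d, size in enumerate(spec.residues_per_domain):
        aa_codes.extend(_sample_aa(rng, size, spec.hydrophobic_fraction))
        pos += size
        if spec.linker_length > 0 and d < spec.n_domains - 1:
            aa_codes.extend(_sample_aa(rng, spec.linker_length, spec.hydrophobic_fraction))

    helix_mask = np.zeros(n, dtype=bool)
    for b, e in spec.helix_runs or []:
        helix_mask[b - 1 : e] = True

    residues = []
    side_names = ("CB", "CG", "OXT")
    for i, (ca, aa) in enumerate(zip(ca_positions, aa_codes)):
        atoms = [Atom(name="CA", element="C", coord=ca)]
        # backbone-like carbonyl midway to the next residue guarantees the
        # sequence-neighbour contact (as a peptide bond would), unless the
        # next residue is across an inter-domain gap
        if i + 1 < n:
            step = ca_positions[i + 1] - ca
            if np.linalg.norm(step) <= 2.0 * spec.intra_packing:
                atoms.append(Atom(name="C", element="C", coord=ca + 0.5 * step))
        for name in side_names[: int(rng.integers(1, 4))]:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            atoms.append(
                Atom(
                    name=name,
                    element=name[0],
                    coord=ca + direction * rng.uniform(1.2, 1.8),
                )
            )
        residues.append(
            Residue(
                seq_index=i + 1,
                pdb_number=str(i + 1),
                aa_code=aa,
                atoms=atoms,
                ca_coord=ca,
                ss="H" if helix_mask[i] else "-",
                rsa=float(rng.uniform(0.0, 1.0)),
                hydrophobicity=KYTE_DOOLITTLE[aa],
            )
        )
    chain = ProteinChain(chain_id="A", residues=residues)
    from .structure import radius_of_gyration

    radius_of_gyration(chain)
    return chain, np.array(labels, dtype=int)


def write_pdb(chain: ProteinChain, path: str | Path) -> None:
    """Write standard ATOM records (single chain, single model)."""
    n_atoms = sum(len(r.atoms) for r in chain.residues)
    if n_atoms > PDB_MAX_ATOMS:
        raise ValueError(f"{n_atoms} atoms exceed the PDB format limit {PDB_MAX_ATOMS}")
    lines = []
    serial = 0
    for res in chain.residues:
        for atom in res.atoms:
            serial += 1
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name}{'':1s}{res.aa_code:>3s} "
                f"{chain.chain_id}{int(res.pdb_number):4d}    "
                f"{atom.coord[0]:8.3f}{atom.coord[1]:8.3f}{atom.coord[2]:8.3f}"
                f"{atom.occupancy:6.2f}{0.0:6.2f}          {atom.element:>2s}"
            )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_dssp(chain: ProteinChain, path: str | Path) -> None:
    """Write a minimal classic-format DSSP file for the chain.

    Synthetic: carries the chain's ss and an absolute accessibility
    reconstructed as rsa times the Miller maximum, in the fixed-column
    layout the DSSP reader consumes.
    """
    lines = [
        "==== Secondary Structure Definition (synthetic) ====",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC",
    ]
    for i, res in enumerate(chain.residues):
        acc = res.rsa * MAX_ACCESSIBILITY[res.aa_code]
        ss = res.ss if res.ss != "-" else " "
        line = (
            f"{i + 1:5d}{int(res.pdb_number):5d} {chain.chain_id} "
            f"{THREE_TO_ONE[res.aa_code]}  {ss}"
        )
        line = line.ljust(34) + f"{acc:4.0f}"
        lines.append(line)
    Path(path).write_text("\n".join(lines) + "\n")


def make_feature_dataset(
    n_single: int, n_multi: int, seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature table from generated single- and two-blob chains.

    Single-domain chains are one blob of 40-60 residues; multi-domain
    chains two blobs of 25-35 residues each. Features are extracted with
    :func:`kerndom.classify.extract_features` on the real contact graph.
    """
    if min(n_single, n_multi) < 10:
        raise ValueError("need at least 10 chains per class")
    from .classify import FEATURE_ORDER, extract_features
    from .contacts import build_contact_graph

    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for label, count in (("single", n_single), ("multi", n_multi)):
        for _ in range(count):
            if label == "single":
                sizes = [int(rng.integers(40, 61))]
            else:
                sizes = [int(rng.integers(25, 36)) for _ in range(2)]
            spec = FixtureSpec(
                n_domains=len(sizes),
                residues_per_domain=sizes,
                inter_domain_gap=float(rng.uniform(18.0, 30.0)),
                seed=int(rng.integers(0, 2**31)),
            )
            chain, _ = make_chain(spec)
            graph = build_contact_graph(chain)
            rows.append(extract_features(chain, graph, seed=int(rng.integers(0, 2**31))))
            labels.append(label)
    table = pd.DataFrame(rows, columns=FEATURE_ORDER)
    return table, np.array(labels)
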