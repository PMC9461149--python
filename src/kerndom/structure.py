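"""Protein chain model: parsing, per-residue annotation, chain descriptors.

A parsed chain is an ordered list of residues, each carrying its heavy atoms,
alpha-carbon coordinate, secondary-structure class, relative solvent
accessibility and Kyte-Doolittle hydrophobicity. Everything downstream
(contact graph, kernels, clustering) consumes this object only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import KYTE_DOOLITTLE, MAX_ACCESSIBILITY, standardize_resname

logger = logging.getLogger(__name__)

SS_CLASSES = frozenset("HGIEBTS-")


class StructureError(ValueError):
    """Raised for unusable structure input (missing chain, too few residues)."""


@dataclass
class Atom:
    """A heavy atom: label, element, coordinate (Angstrom), occupancy, altloc."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coord must be a finite 3-vector")


@dataclass
class Residue:
    """One amino-acid residue with its atoms and biological annotations.

    ``seq_index`` is the 1-based position among the retained residues of the
    chain; ``pdb_number`` is the author residue number plus insertion code
    (used to map DSSP records onto the chain).
    """

    seq_index: int
    pdb_number: str
    aa_code: str
    atoms: list[Atom]
    ca_coord: np.ndarray
    ss: str = "-"
    rsa: float = 0.0
    hydrophobicity: float = 0.0

    def __post_init__(self) -> None:
        self.ca_coord = np.asarray(self.ca_coord, dtype=float)


@dataclass
class ProteinChain:
    chain_id: str
    residues: list[Residue]
    rg: float = field(default=0.0)

    @property
    def n(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca_coord for r in self.residues])

    def all_atom_coords(self) -> np.ndarray:
        return np.concatenate([[a.coord for a in r.atoms] for r in self.residues])

    def hydrophobicities(self) -> np.ndarray:
        return np.array([r.hydrophobicity for r in self.residues])

    def rsas(self) -> np.ndarray:
        return np.array([r.rsa for r in self.residues])

    def ss_string(self) -> str:
        return "".join(r.ss for r in self.residues)


def _is_hydrogen(element: str, name: str) -> bool:
    el = element.strip().upper()
    if el in ("H", "D"):
        return True
    if not el:  # fall back on the atom-name convention
        stripped = name.strip().lstrip("0123456789")
        return stripped[:1].upper() in ("H", "D")
    return False


def parse_chain(structure_file: str | Path, chain_id: str) -> ProteinChain:
    """Parse one chain of a PDB (or mmCIF) file into a :class:`ProteinChain`.

    Only the first model is read. Heteroatoms, waters and hydrogens are
    excluded; for alternate locations only the highest-occupancy conformer is
    kept; residues without an alpha-carbon are dropped with a warning.
    """
    path = Path(structure_file)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")

    from Bio.PDB import MMCIFParser, PDBParser

    if path.suffix.lower() in (".cif", ".mmcif"):
        parser = MMCIFParser(QUIET=True)
    else:
        parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("chain", str(path))

    model = next(structure.get_models())  # model 1 only
    if chain_id not in [c.id for c in model]:
        raise StructureError(f"chain not found: {chain_id!r} in {path.name}")
    bio_chain = model[chain_id]

    residues: list[Residue] = []
    for res in bio_chain:
        het, resseq, icode = res.id
        if het.strip():  # heteroatom or water
            continue
        aa = standardize_resname(res.get_resname())
        if aa is None:
            logger.warning("dropping unknown residue %s %s", res.get_resname(), resseq)
            continue
        atoms: list[Atom] = []
        ca = None
        for atom in res:  # DisorderedAtom yields its highest-occupancy child
            if _is_hydrogen(atom.element or "", atom.get_name()):
                continue
            a = Atom(
                name=atom.get_name(),
                element=(atom.element or "").strip(),
                coord=atom.get_coord(),
                occupancy=atom.get_occupancy() or 1.0,
                altloc=atom.get_altloc().strip(),
            )
            atoms.append(a)
            if atom.get_name() == "CA":
                ca = a.coord
        if ca is None:
            logger.warning("dropping residue %s%s: no alpha-carbon", resseq, icode.strip())
            continue
        pdb_number = f"{resseq}{icode.strip()}"
        residues.append(
            Residue(
                seq_index=len(residues) + 1,
                pdb_number=pdb_number,
                aa_code=aa,
                atoms=atoms,
                ca_coord=ca,
            )
        )

    if len(residues) < 2:
        raise StructureError(
            f"chain {chain_id!r} has {len(residues)} usable residues (need >= 2)"
        )
    chain = ProteinChain(chain_id=chain_id, residues=residues)
    chain.rg = radius_of_gyration(chain)
    return chain


def parse_dssp(dssp_file: str | Path) -> dict[tuple[str, str], tuple[str, float]]:
    """Read a classic-format DSSP file.

    Returns a map from (chain id, author residue number + insertion code) to
    (secondary-structure class, absolute accessibility in A^2).
    """
    records: dict[tuple[str, str], tuple[str, float]] = {}
    in_data = False
    for line in Path(dssp_file).read_text().splitlines():
        if not in_data:
            if line.startswith("  #  RESIDUE"):
                in_data = True
            continue
        if len(line) < 38 or line[13] == "!":  # chain break record
            continue
        resnum = line[5:10].strip()
        icode = line[10].strip()
        chain = line[11].strip()
        ss = line[16].strip() or "-"
        try:
            acc = float(line[34:38])
        except ValueError as exc:
            raise ValueError(f"unmappable DSSP record: {line!r}") from exc
        records[(chain, f"{resnum}{icode}")] = (ss, acc)
    if not records:
        raise ValueError(f"no residue records found in DSSP file {dssp_file}")
    return records


def annotate(chain: ProteinChain, dssp_file: str | Path | None = None) -> ProteinChain:
    """Attach secondary structure, relative accessibility and hydrophobicity.

    Hydrophobicity always comes from the Kyte-Doolittle table. If
    ``dssp_file`` is given, ss and rsa (= accessibility / Miller maximum for
    the amino acid) are read from it, matching residues by author number;
    residues absent from the DSSP record get ss '-' and rsa 0 with a warning.
    Without a DSSP file, any ss/rsa already present on the residues is kept.
    """
    dssp = parse_dssp(dssp_file) if dssp_file is not None else None
    for res in chain.residues:
        res.hydrophobicity = KYTE_DOOLITTLE[res.aa_code]
        if dssp is None:
            continue
        rec = dssp.get((chain.chain_id, res.pdb_number))
        if rec is None:
            logger.warning(
                "residue %s not in DSSP record; ss='-', rsa=0", res.pdb_number
            )
            res.ss, res.rsa = "-", 0.0
        else:
            ss, acc = rec
            res.ss = ss if ss in SS_CLASSES else "-"
            res.rsa = acc / MAX_ACCESSIBILITY[res.aa_code]
    return chain


def radius_of_gyration(chain: ProteinChain) -> float:
    """Root-mean-square distance of all retained atoms to their centroid."""
    coords = chain.all_atom_coords()
    if coords.size == 0:
        raise StructureError("chain has no atoms")
    centroid = coords.mean(axis=0)
    rg = float(np.sqrt(np.mean(np.sum((coords - centroid) ** 2, axis=1))))
    chain.rg = rg
    return rg


def hydrophobic_mask(chain: ProteinChain, threshold: float = 2.0) -> np.ndarray:
    """Boolean mask of residues with Kyte-Doolittle index strictly > threshold."""
    return chain.hydrophobicities() > threshold
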