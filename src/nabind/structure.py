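"""Per-residue binding labels from protein-nucleic-acid complex structures.

A protein residue is labeled binding iff some heavy atom of the residue lies
within (r_vdw(a) + r_vdw(b) + 0.5) angstroms of some nucleic-acid atom — i.e.
the minimal gap d(a, b) - r_vdw(a) - r_vdw(b) over all atom pairs is strictly
below the 0.5 A tolerance.  Distances are over heavy atoms only (crystal
structures rarely resolve hydrogens).  The van der Waals radii are Bondi-type
values shipped with the package and overridable.

PDB and mmCIF files are parsed with gemmi; waters and non-polymer heteroatoms
are excluded, modified residues map to 'X' in the sequence but remain eligible
for labeling, and only the highest-occupancy alternate conformer of each atom
is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .seqio import LabelTrack

# Bondi-type van der Waals radii (angstroms), heavy atoms common in
# protein/nucleic-acid structures.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90, "B": 1.92, "SI": 2.10,
}

#: distance tolerance added to the vdW-radius sum (angstroms)
CONTACT_TOLERANCE = 0.5

_PROTEIN_RESIDUES = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
# common modified residues kept as protein, mapped to 'X'
_MODIFIED_PROTEIN = {"MSE", "SEC", "PYL", "SEP", "TPO", "PTR", "CSO", "HYP", "MLY"}
_NUCLEIC_RESIDUES = {"A", "C", "G", "U", "T", "DA", "DC", "DG", "DT", "DU", "DI", "I", "PSU"}
_WATER = {"HOH", "WAT", "DOD"}


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class AtomRecord:
    chain_id: str
    residue_index: int  # author numbering from the source file
    residue_name: str
    atom_name: str
    element: str
    coords: tuple[float, float, float]
    molecule_class: str  # "protein" | "nucleic"

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.coords)):
            raise StructureError(
                f"non-finite coordinates for atom {self.atom_name} in "
                f"{self.chain_id}/{self.residue_name}{self.residue_index}"
            )


@dataclass
class ParsedComplex:
    """Atoms of one model, partitioned into protein and nucleic-acid chains."""

    atoms: list[AtomRecord]

    @property
    def protein_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.molecule_class == "protein"]

    @property
    def nucleic_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.molecule_class == "nucleic"]

    def protein_chains(self) -> dict[str, list[tuple[int, str, list[AtomRecord]]]]:
        """Per-chain residue lists [(residue_index, one_letter, atoms)] in file order."""
        chains: dict[str, dict[int, tuple[str, list[AtomRecord]]]] = {}
        for a in self.protein_atoms:
            res = chains.setdefault(a.chain_id, {}).setdefault(
                a.residue_index,
                (_PROTEIN_RESIDUES.get(a.residue_name, "X"), []),
            )
            res[1].append(a)
        return {
            cid: [(idx, *residues[idx]) for idx in residues]
            for cid, residues in chains.items()
        }

    def chain_sequence(self, chain_id: str) -> str:
        return "".join(one for _, one, _ in self.protein_chains()[chain_id])


def _classify(residue_name: str) -> str | None:
    name = residue_name.strip().upper()
    if name in _WATER:
        return None
    if name in _PROTEIN_RESIDUES or name in _MODIFIED_PROTEIN:
        return "protein"
    if name in _NUCLEIC_RESIDUES:
        return "nucleic"
    return None  # ions / ligands / unknown heteroatoms are excluded


def read_structure(path: str | Path) -> ParsedComplex:
    """Parse a PDB or mmCIF file into classified atom records."""
    import gemmi

    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"{path}: cannot parse structure: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: structure contains no models")
    st.setup_entities()

    atoms: list[AtomRecord] = []
    model = st[0]
    for chain in model:
        for residue in chain:
            cls = _classify(residue.name)
            if cls is None:
                continue
            best: dict[str, "gemmi.Atom"] = {}
            for atom in residue:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in best.values():
                element = atom.element.name.upper()
                if element == "H" or element == "D":
                    continue
                atoms.append(
                    AtomRecord(
                        chain_id=chain.name,
                        residue_index=residue.seqid.num,
                        residue_name=residue.name,
                        atom_name=atom.name,
                        element=element,
                        coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                        molecule_class=cls,
                    )
                )
    if not atoms:
        raise StructureError(f"{path}: no protein or nucleic-acid atoms found")
    return ParsedComplex(atoms)


def label_binding_sites(
    complex_: ParsedComplex | Sequence[AtomRecord],
    radii: Mapping[str, float] | None = None,
    tolerance: float = CONTACT_TOLERANCE,
) -> dict[str, LabelTrack]:
    """Label each protein chain's residues by the vdW-contact rule.

    Residue i of a chain gets label 1 iff
    min over (protein atom a of residue i, nucleic atom b) of
    [d(a, b) - r_vdw(a) - r_vdw(b)] < tolerance (strict).
    """
    if not isinstance(complex_, ParsedComplex):
        complex_ = ParsedComplex(list(complex_))
    radii = dict(VDW_RADII if radii is None else radii)
    for r in radii.values():
        if r <= 0:
            raise StructureError("van der Waals radii must be positive")

    nuc = complex_.nucleic_atoms
    if not nuc:
        raise StructureError("structure contains no nucleic-acid chain")
    chains = complex_.protein_chains()
    if not chains:
        raise StructureError("structure contains no protein chain")

    def radius(atom: AtomRecord) -> float:
        try:
            return radii[atom.element]
        except KeyError:
            raise StructureError(
                f"unknown element {atom.element!r} (atom {atom.atom_name} in "
                f"{atom.chain_id}/{atom.residue_name}{atom.residue_index})"
            ) from None

    nuc_xyz = np.array([a.coords for a in nuc])
    nuc_r = np.array([radius(a) for a in nuc])
    tree = cKDTree(nuc_xyz)
    max_reach = float(nuc_r.max()) + max(radii.values()) + tolerance

    tracks: dict[str, LabelTrack] = {}
    for chain_id, residues in chains.items():
        labels = []
        for _, _, atoms in residues:
            bound = 0
            for a in atoms:
                r_a = radius(a)
                for j in tree.query_ball_point(a.coords, r=max_reach):
                    d = float(np.linalg.norm(np.asarray(a.coords) - nuc_xyz[j]))
                    if d - (r_a + nuc_r[j]) < tolerance:
                        bound = 1
                        break
                if bound:
                    break
            labels.append(bound)
        tracks[chain_id] = LabelTrack(chain_id, tuple(labels))
    return tracks


def label_structure_file(
    path: str | Path,
    radii: Mapping[str, float] | None = None,
    tolerance: float = CONTACT_TOLERANCE,
) -> tuple[dict[str, str], dict[str, LabelTrack]]:
    """Parse a complex and return (chain sequences, chain label tracks)."""
    complex_ = read_structure(path)
    tracks = label_binding_sites(complex_, radii, tolerance)
    seqs = {cid: complex_.chain_sequence(cid) for cid in tracks}
    return seqs, tracks
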