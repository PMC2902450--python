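"""Structure I/O, dihedral extraction and side-chain construction.

Side chains are parameterized entirely by their chi dihedrals: bond lengths
and bond angles are held at ideal values (Engh–Huber-type numbers shipped in
the topology table below), so a residue's heavy-atom side chain is rebuilt
from (backbone frame, chi vector) by sequential internal-to-Cartesian (NeRF)
placement.  Aromatic/guanidinium ring atoms past the last rotatable bond use
fixed dihedrals; rings are built atom-by-atom, which reproduces chi angles
exactly and ideal bonds along the construction tree.

PDB reading/writing goes through Biopython's Bio.PDB; heavy atoms only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .circular import wrap_angle
from .model import CHI_COUNTS, ResidueAngles

# ---------------------------------------------------------------------------
# Basic geometry
# ---------------------------------------------------------------------------

def compute_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle of four points, IUPAC convention, in [-pi, pi).

    cis (eclipsed) = 0; the sign follows the right-hand rule about p2->p3.
    Invariant under rigid-body motion of all four points.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-10:
        raise ValueError("dihedral undefined: coincident central points")
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < 1e-10 or np.linalg.norm(w) < 1e-10:
        raise ValueError("dihedral undefined: colinear points")
    angle = np.arctan2(np.dot(np.cross(b1, v), w), np.dot(v, w))
    return float(wrap_angle(angle))


def place_atom(a, b, c, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Place atom X bonded to c with |cX| = bond, angle(b,c,X) = angle and
    dihedral(a,b,c,X) = dihedral (radians). Standard NeRF construction."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(angle),
                  bond * np.sin(angle) * np.cos(dihedral),
                  bond * np.sin(angle) * np.sin(dihedral)])
    return c + d[0] * bc + d[1] * m + d[2] * n


# ---------------------------------------------------------------------------
# Structure containers
# ---------------------------------------------------------------------------

@dataclass
class AtomRecord:
    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")


BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class Residue:
    name: str
    chain_id: str
    resseq: int
    icode: str = " "
    atoms: dict = field(default_factory=dict)   # name -> AtomRecord, insertion order

    @property
    def key(self):
        return (self.chain_id, self.resseq, self.icode)

    def coord(self, name: str) -> np.ndarray:
        return self.atoms[name].coord

    @property
    def backbone_complete(self) -> bool:
        return all(a in self.atoms for a in ("N", "CA", "C"))

    def side_chain_atom_names(self):
        return [n for n in self.atoms if n not in BACKBONE_ATOMS and n != "OXT"]


@dataclass
class StructureModel:
    residues: list = field(default_factory=list)
    flagged: list = field(default_factory=list)   # (residue key, reason)

    def residue_by_key(self, key) -> Optional[Residue]:
        for r in self.residues:
            if r.key == key:
                return r
        return None


CHAIN_BREAK_CA_CA = 4.5  # Angstrom


def chain_breaks(structure: StructureModel) -> list:
    """Indices i where the CA(i)-CA(i+1) distance exceeds the break threshold."""
    breaks = []
    for i in range(len(structure.residues) - 1):
        a, b = structure.residues[i], structure.residues[i + 1]
        if "CA" in a.atoms and "CA" in b.atoms:
            if np.linalg.norm(a.coord("CA") - b.coord("CA")) > CHAIN_BREAK_CA_CA:
                breaks.append(i)
    return breaks


# ---------------------------------------------------------------------------
# PDB I/O (Bio.PDB behind the module surface)
# ---------------------------------------------------------------------------

_ELEMENT_FROM_NAME = {"N": "N", "O": "O", "S": "S"}


def _element_of(atom_name: str) -> str:
    stripped = atom_name.strip()
    for prefix in ("CL", "BR"):   # not expected in standard residues; safety
        if stripped.startswith(prefix):
            return prefix.capitalize()
    return _ELEMENT_FROM_NAME.get(stripped[0], "C") if stripped else "C"


def read_pdb(path, backbone_only: bool = False, drop_hetero: bool = True) -> StructureModel:
    """Read the first model/first chain ordering of a PDB file.

    Altloc policy: highest occupancy wins.  Hydrogens are always dropped;
    residues with incomplete backbones are flagged, unknown residue names are
    flagged but kept.
    """
    from Bio.PDB import PDBParser
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bio_structure = parser.get_structure("s", str(path))
    structure = StructureModel()
    bio_model = next(iter(bio_structure))
    for chain in bio_model:
        for res in chain:
            het, resseq, icode = res.id
            if het.strip() and drop_hetero:
                continue
            residue = Residue(name=res.get_resname().upper(), chain_id=chain.id,
                              resseq=resseq, icode=icode)
            for atom in res:
                if atom.is_disordered():
                    atom = max(atom, key=lambda a: a.get_occupancy() or 0.0)
                name = atom.get_name()
                element = (atom.element or _element_of(name)).upper().capitalize()
                if element == "H" or name.startswith("H") or name[:1].isdigit():
                    continue
                if backbone_only and name not in BACKBONE_ATOMS and name != "OXT":
                    continue
                residue.atoms[name] = AtomRecord(
                    name=name, element=element, coord=atom.get_coord(),
                    occupancy=atom.get_occupancy() or 1.0,
                    bfactor=atom.get_bfactor() or 0.0)
            if residue.name not in CHI_COUNTS and residue.name not in ("ALA", "GLY"):
                structure.flagged.append((residue.key, f"unknown residue {residue.name}"))
            if not residue.backbone_complete:
                structure.flagged.append((residue.key, "incomplete backbone"))
            structure.residues.append(residue)
    for i in chain_breaks(structure):
        structure.flagged.append((structure.residues[i].key, "chain break after residue"))
    return structure


def write_pdb(structure: StructureModel, path) -> None:
    """Write a StructureModel as a single-model PDB file via Bio.PDB."""
    from Bio.PDB import PDBIO
    from Bio.PDB.Atom import Atom as BioAtom
    from Bio.PDB.Chain import Chain as BioChain
    from Bio.PDB.Model import Model as BioModel
    from Bio.PDB.Residue import Residue as BioResidue
    from Bio.PDB.Structure import Structure as BioStructure

    s = BioStructure("s")
    m = BioModel(0)
    s.add(m)
    chains = {}
    serial = 1
    for res in structure.residues:
        if res.chain_id not in chains:
            chains[res.chain_id] = BioChain(res.chain_id)
            m.add(chains[res.chain_id])
        bres = BioResidue((" ", res.resseq, res.icode), res.name, "")
        for atom in res.atoms.values():
            bres.add(BioAtom(atom.name, np.asarray(atom.coord, dtype=np.float64),
                             atom.bfactor, atom.occupancy, " ",
                             atom.name.center(4) if len(atom.name) < 4 else atom.name,
                             serial, element=atom.element.upper()))
            serial += 1
        chains[res.chain_id].add(bres)
    io = PDBIO()
    io.set_structure(s)
    io.save(str(path))


# ---------------------------------------------------------------------------
# Side-chain topology: ideal internal coordinates
#
# Each side-chain atom is defined by three reference atoms (a, b, c), an
# ideal bond length c-X (Angstrom), an ideal bond angle b-c-X (degrees), and
# a dihedral a-b-c-X that is either a fixed value (degrees) or ("chi", k,
# offset_deg) meaning chi_k + offset.  References always precede dependents.
# ---------------------------------------------------------------------------

def _chi(k, offset=0.0):
    return ("chi", k, offset)


#: CB placement shared by all side chains: refs (N, C, CA); the improper
#: dihedral value fixes L-chirality at CA.
_CB = ("CB", ("N", "C", "CA"), 1.530, 110.5, 122.6)

SIDE_CHAIN_TOPOLOGY = {
    "SER": [_CB, ("OG", ("N", "CA", "CB"), 1.417, 110.8, _chi(1))],
    "CYS": [_CB, ("SG", ("N", "CA", "CB"), 1.808, 114.4, _chi(1))],
    "THR": [_CB, ("OG1", ("N", "CA", "CB"), 1.433, 109.6, _chi(1)),
            ("CG2", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, -120.0))],
    "VAL": [_CB, ("CG1", ("N", "CA", "CB"), 1.521, 110.5, _chi(1)),
            ("CG2", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, 122.0))],
    "ILE": [_CB, ("CG1", ("N", "CA", "CB"), 1.530, 110.4, _chi(1)),
            ("CG2", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, -122.0)),
            ("CD1", ("CA", "CB", "CG1"), 1.513, 113.8, _chi(2))],
    "LEU": [_CB, ("CG", ("N", "CA", "CB"), 1.530, 116.3, _chi(1)),
            ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, _chi(2)),
            ("CD2", ("CA", "CB", "CG"), 1.521, 110.7, _chi(2, 122.0))],
    "ASP": [_CB, ("CG", ("N", "CA", "CB"), 1.516, 112.6, _chi(1)),
            ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, _chi(2)),
            ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, _chi(2, 180.0))],
    "ASN": [_CB, ("CG", ("N", "CA", "CB"), 1.516, 112.6, _chi(1)),
            ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, _chi(2)),
            ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, _chi(2, 180.0))],
    "GLU": [_CB, ("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
            ("CD", ("CA", "CB", "CG"), 1.516, 112.6, _chi(2)),
            ("OE1", ("CB", "CG", "CD"), 1.249, 118.4, _chi(3)),
            ("OE2", ("CB", "CG", "CD"), 1.249, 118.4, _chi(3, 180.0))],
    "GLN": [_CB, ("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
            ("CD", ("CA", "CB", "CG"), 1.516, 112.6, _chi(2)),
            ("OE1", ("CB", "CG", "CD"), 1.231, 120.8, _chi(3)),
            ("NE2", ("CB", "CG", "CD"), 1.328, 116.4, _chi(3, 180.0))],
    "MET": [_CB, ("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
            ("SD", ("CA", "CB", "CG"), 1.803, 112.7, _chi(2)),
            ("CE", ("CB", "CG", "SD"), 1.791, 100.9, _chi(3))],
    "LYS": [_CB, ("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
            ("CD", ("CA", "CB", "CG"), 1.520, 111.3, _chi(2)),
            ("CE", ("CB", "CG", "CD"), 1.520, 111.3, _chi(3)),
            ("NZ", ("CG", "CD", "CE"), 1.489, 111.9, _chi(4))],
    "ARG": [_CB, ("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
            ("CD", ("CA", "CB", "CG"), 1.520, 111.3, _chi(2)),
            ("NE", ("CB", "CG", "CD"), 1.461, 112.0, _chi(3)),
            ("CZ", ("CG", "CD", "NE"), 1.329, 124.2, _chi(4)),
            ("NH1", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
            ("NH2", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0)],
    "HIS": [_CB, ("CG", ("N", "CA", "CB"), 1.497, 113.8, _chi(1)),
            ("ND1", ("CA", "CB", "CG"), 1.371, 122.7, _chi(2)),
            ("CD2", ("CA", "CB", "CG"), 1.356, 131.1, _chi(2, 180.0)),
            ("CE1", ("CB", "CG", "ND1"), 1.319, 109.3, 180.0),
            ("NE2", ("CB", "CG", "CD2"), 1.374, 107.2, 180.0)],
    "PHE": [_CB, ("CG", ("N", "CA", "CB"), 1.502, 113.8, _chi(1)),
            ("CD1", ("CA", "CB", "CG"), 1.384, 120.8, _chi(2)),
            ("CD2", ("CA", "CB", "CG"), 1.384, 120.8, _chi(2, 180.0)),
            ("CE1", ("CB", "CG", "CD1"), 1.382, 120.8, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.382, 120.8, 180.0),
            ("CZ", ("CG", "CD1", "CE1"), 1.382, 120.0, 0.0)],
    "TYR": [_CB, ("CG", ("N", "CA", "CB"), 1.512, 113.9, _chi(1)),
            ("CD1", ("CA", "CB", "CG"), 1.389, 120.8, _chi(2)),
            ("CD2", ("CA", "CB", "CG"), 1.389, 120.8, _chi(2, 180.0)),
            ("CE1", ("CB", "CG", "CD1"), 1.382, 121.2, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.382, 121.2, 180.0),
            ("CZ", ("CG", "CD1", "CE1"), 1.378, 119.6, 0.0),
            ("OH", ("CD1", "CE1", "CZ"), 1.376, 119.9, 180.0)],
    "TRP": [_CB, ("CG", ("N", "CA", "CB"), 1.498, 113.6, _chi(1)),
            ("CD1", ("CA", "CB", "CG"), 1.365, 126.9, _chi(2)),
            ("CD2", ("CA", "CB", "CG"), 1.433, 126.7, _chi(2, 180.0)),
            ("NE1", ("CB", "CG", "CD1"), 1.374, 110.2, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.409, 107.2, 180.0),
            ("CE3", ("CB", "CG", "CD2"), 1.398, 133.9, 0.0),
            ("CZ2", ("CG", "CD2", "CE2"), 1.394, 122.4, 180.0),
            ("CZ3", ("CG", "CD2", "CE3"), 1.392, 118.6, 180.0),
            ("CH2", ("CD2", "CE2", "CZ2"), 1.368, 117.5, 0.0)],
    "PRO": [_CB, ("CG", ("N", "CA", "CB"), 1.492, 104.5, _chi(1)),
            ("CD", ("CA", "CB", "CG"), 1.503, 106.1, _chi(2))],
}

#: Canonical atom quadruples defining each chi dihedral.
CHI_ATOMS = {}
for _aa, _atoms in SIDE_CHAIN_TOPOLOGY.items():
    quads = []
    by_name = {a[0]: a for a in _atoms}
    for k in range(1, CHI_COUNTS[_aa] + 1):
        for name, refs, _, _, dih in _atoms:
            if isinstance(dih, tuple) and dih[1] == k and dih[2] == 0.0:
                quads.append(refs + (name,))
                break
    CHI_ATOMS[_aa] = quads


def build_side_chain(residue_backbone: dict, amino_acid: str, chi) -> dict:
    """Construct side-chain heavy atoms from backbone N/CA/C and a chi vector.

    Returns an ordered dict name -> AtomRecord.  Extracting chi from the
    built atoms reproduces the input exactly (up to numerical precision).
    """
    aa = amino_acid.upper()
    if aa not in SIDE_CHAIN_TOPOLOGY:
        raise KeyError(f"no side-chain topology for {amino_acid!r}")
    chi = np.asarray(chi, dtype=float)
    if len(chi) != CHI_COUNTS[aa]:
        raise ValueError(f"{aa}: expected {CHI_COUNTS[aa]} chi angles, got {len(chi)}")
    coords = {name: np.asarray(residue_backbone[name], dtype=float)
              for name in ("N", "CA", "C")}
    out = {}
    for name, refs, bond, angle, dih in SIDE_CHAIN_TOPOLOGY[aa]:
        if isinstance(dih, tuple):
            _, k, offset = dih
            dihedral = chi[k - 1] + np.radians(offset)
        else:
            dihedral = np.radians(dih)
        pos = place_atom(coords[refs[0]], coords[refs[1]], coords[refs[2]],
                         bond, np.radians(angle), dihedral)
        coords[name] = pos
        out[name] = AtomRecord(name=name, element=_element_of(name), coord=pos)
    return out


def apply_side_chain(residue: Residue, chi) -> None:
    """Replace a residue's side-chain atoms with ones rebuilt at ``chi``."""
    for name in list(residue.atoms):
        if name not in BACKBONE_ATOMS and name != "OXT":
            del residue.atoms[name]
    residue.atoms.update(build_side_chain(
        {n: residue.coord(n) for n in ("N", "CA", "C")}, residue.name, chi))


def extract_chi(residue: Residue) -> Optional[tuple]:
    """Chi angles of a residue from its atoms; None if atoms are missing."""
    aa = residue.name
    if aa not in CHI_ATOMS:
        return ()
    chi = []
    for quad in CHI_ATOMS[aa]:
        if not all(n in residue.atoms for n in quad):
            return None
        chi.append(compute_dihedral(*(residue.coord(n) for n in quad)))
    return tuple(chi)


def extract_residue_angles(structure: StructureModel, skip_flagged: bool = True):
    """Extract (phi, psi, chi) records for all side-chain-bearing residues.

    First/last residues get missing phi/psi respectively; residues with
    missing side-chain atoms are excluded and reported in the second return
    value.
    """
    records, excluded = [], []
    residues = structure.residues
    for i, res in enumerate(residues):
        if res.name in ("ALA", "GLY") or res.name not in CHI_COUNTS:
            continue
        if not res.backbone_complete:
            excluded.append((res.key, "incomplete backbone"))
            continue
        phi = psi = None
        if i > 0 and residues[i - 1].backbone_complete and \
                residues[i - 1].chain_id == res.chain_id:
            phi = compute_dihedral(residues[i - 1].coord("C"), res.coord("N"),
                                   res.coord("CA"), res.coord("C"))
        if i + 1 < len(residues) and "N" in residues[i + 1].atoms and \
                residues[i + 1].chain_id == res.chain_id:
            psi = compute_dihedral(res.coord("N"), res.coord("CA"),
                                   res.coord("C"), residues[i + 1].coord("N"))
        chi = extract_chi(res)
        if chi is None:
            excluded.append((res.key, "missing side-chain atoms"))
            continue
        records.append((res.key, ResidueAngles(amino_acid=res.name, phi=phi,
                                               psi=psi, chi=chi)))
    return records, excluded


# ---------------------------------------------------------------------------
# Backbone construction for synthetic fixtures
# ---------------------------------------------------------------------------

_BB = {"N_CA": 1.458, "CA_C": 1.525, "C_N": 1.329, "C_O": 1.231,
       "N_CA_C": 111.2, "CA_C_N": 116.2, "C_N_CA": 121.7, "CA_C_O": 120.8}


def build_backbone(sequence, phi_psi, chain_id: str = "A") -> StructureModel:
    """Ideal-geometry backbone (N, CA, C, O) from a sequence of residue names
    and per-residue (phi, psi) in radians.  omega is fixed trans (180 deg)."""
    if len(sequence) != len(phi_psi):
        raise ValueError("sequence and phi_psi lengths differ")
    structure = StructureModel()
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_BB["N_CA"], 0.0, 0.0])
    theta = np.radians(_BB["N_CA_C"])
    c = ca + _BB["CA_C"] * np.array([np.cos(np.pi - theta), np.sin(np.pi - theta), 0.0])
    prev = None
    for i, (name, (phi, psi)) in enumerate(zip(sequence, phi_psi)):
        res = Residue(name=name.upper(), chain_id=chain_id, resseq=i + 1)
        if i > 0:
            n = place_atom(prev["N"], prev["CA"], prev["C"],
                           _BB["C_N"], np.radians(_BB["CA_C_N"]), prev["psi"])
            ca = place_atom(prev["CA"], prev["C"], n,
                            _BB["N_CA"], np.radians(_BB["C_N_CA"]), np.pi)  # omega
            c = place_atom(prev["C"], n, ca, _BB["CA_C"],
                           np.radians(_BB["N_CA_C"]), phi)
        for atom_name, pos in (("N", n), ("CA", ca), ("C", c)):
            res.atoms[atom_name] = AtomRecord(name=atom_name,
                                              element=_element_of(atom_name), coord=pos)
        o = place_atom(res.coord("N"), res.coord("CA"), res.coord("C"),
                       _BB["C_O"], np.radians(_BB["CA_C_O"]), psi + np.pi)
        res.atoms["O"] = AtomRecord(name="O", element="O", coord=o)
        structure.residues.append(res)
        prev = {"N": res.coord("N"), "CA": res.coord("CA"), "C": res.coord("C"),
                "psi": psi}
    return structure
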