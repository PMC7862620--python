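"""Molecular data model, file I/O, parameterization and rotatable-bond detection.

The data model is deliberately small: atoms carry coordinates, charges and
van der Waals parameters; bonds carry order/ring/rotatability flags.  Two
parameterization backends are provided: ``"mmff"`` delegates MMFF94S atom
typing, bond-charge-increment partial charges and vdW well parameters to
RDKit, while ``"builtin"`` uses a minimal element table (C, H, N, O, S, P,
halogens) so that synthetic fixtures can be parameterized without a force
field.  The tool never adds hydrogens: structures are expected with explicit
hydrogens already present.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Bond",
    "ParameterizedMolecule",
    "ComplexStructure",
    "BindingAffinity",
    "StructureFormatError",
    "ParameterizationError",
    "read_structure",
    "write_sdf",
    "write_pdb",
    "assign_parameters",
    "detect_rotatable_bonds",
    "affinity_to_energy",
    "BONDI_RADII",
    "GAS_CONSTANT_KCAL",
]

#: Bondi-style element van der Waals radii (Angstrom); feed d_vdW sums.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}

#: Pauling electronegativities for the builtin bond-charge-increment scheme.
_ELECTRONEG = {
    "H": 2.20, "C": 2.55, "N": 3.04, "O": 3.44, "S": 2.58, "P": 2.19,
    "F": 3.98, "Cl": 3.16, "Br": 2.96, "I": 2.66,
}

#: Builtin homonuclear vdW parameters: element -> (well depth kcal/mol,
#: minimum-energy separation R*_ii Angstrom).  Only used by the builtin
#: backend; MMFF parameters take over when the RDKit backend is active.
_BUILTIN_VDW = {
    "H": (0.030, 3.00), "C": (0.070, 3.80), "N": (0.110, 3.60),
    "O": (0.120, 3.40), "S": (0.250, 4.00), "P": (0.200, 4.10),
    "F": (0.080, 3.30), "Cl": (0.260, 3.90), "Br": (0.320, 4.10),
    "I": (0.400, 4.40),
}

#: Charge transferred per unit electronegativity difference and bond order.
_BCI_SCALE = 0.1

_BOND_ORDER_VALUE = {"single": 1.0, "aromatic": 1.5, "double": 2.0, "triple": 3.0}

GAS_CONSTANT_KCAL = 1.987204259e-3  # kcal / (mol K)


class StructureFormatError(ValueError):
    """Raised when a structure file cannot be parsed or lacks required data."""


class ParameterizationError(ValueError):
    """Raised when an atom falls outside the parameter table coverage."""


@dataclass
class Atom:
    index: int
    element: str
    coords: np.ndarray
    formal_charge: int = 0
    partial_charge: float = math.nan
    vdw_well_depth: float = math.nan
    vdw_rmin: float = math.nan
    contact_radius: float = math.nan
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.index}: coords must be a finite 3-vector")
        self.is_hydrogen = self.element == "H"


@dataclass
class Bond:
    atom_i: int
    atom_j: int
    order: Literal["single", "double", "triple", "aromatic"] = "single"
    in_ring: bool = False
    rotatable: bool = False

    def __post_init__(self) -> None:
        if self.atom_i == self.atom_j:
            raise ValueError("bond endpoints must differ")
        if self.rotatable and (self.order != "single" or self.in_ring):
            raise ValueError("rotatable bonds must be acyclic single bonds")


class ParameterizedMolecule:
    """Atoms + bonds with (possibly pending) force-field parameters."""

    def __init__(self, atoms: Sequence[Atom], bonds: Sequence[Bond],
                 net_charge: Optional[int] = None, name: str = ""):
        self.atoms = list(atoms)
        self.bonds = list(bonds)
        self.name = name
        n = len(self.atoms)
        for b in self.bonds:
            if not (0 <= b.atom_i < n and 0 <= b.atom_j < n):
                raise ValueError("bond references an unknown atom index")
        if net_charge is None:
            net_charge = int(sum(a.formal_charge for a in self.atoms))
        self.net_charge = net_charge
        self._rdmol = None  # original RDKit mol when read through RDKit

    # -- convenience array views ------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    @property
    def contact_radii(self) -> np.ndarray:
        return np.array([a.contact_radius for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list:
        return [a.element for a in self.atoms]

    @property
    def hydrogen_mask(self) -> np.ndarray:
        return np.array([a.is_hydrogen for a in self.atoms], dtype=bool)

    @property
    def is_parameterized(self) -> bool:
        return all(math.isfinite(a.partial_charge) and math.isfinite(a.vdw_rmin)
                   for a in self.atoms)

    def neighbors(self, idx: int) -> list:
        out = []
        for b in self.bonds:
            if b.atom_i == idx:
                out.append(b.atom_j)
            elif b.atom_j == idx:
                out.append(b.atom_i)
        return out

    def bonded_pairs(self) -> set:
        return {frozenset((b.atom_i, b.atom_j)) for b in self.bonds}

    def validate_charges(self, tol: float = 1e-3) -> None:
        total = float(np.nansum(self.charges))
        if abs(total - self.net_charge) > tol:
            raise ParameterizationError(
                f"partial charges sum to {total:.4f}, expected {self.net_charge}")


@dataclass
class ComplexStructure:
    """Receptor + ligand in one coordinate frame.

    Atom indexing is global: receptor atoms occupy ``[0, n_receptor)`` and
    ligand atoms ``[n_receptor, n_receptor + n_ligand)``.
    """

    receptor: ParameterizedMolecule
    ligand: ParameterizedMolecule

    @property
    def n_receptor(self) -> int:
        return self.receptor.n_atoms

    @property
    def n_ligand(self) -> int:
        return self.ligand.n_atoms

    def global_side(self, indices: Iterable[int]) -> str:
        """Classify global atom indices; raise if they span both molecules."""
        idx = list(indices)
        nr = self.n_receptor
        sides = {"receptor" if i < nr else "ligand" for i in idx}
        if len(sides) != 1:
            raise ValueError("atom subset references atoms of both molecules")
        return sides.pop()


@dataclass
class BindingAffinity:
    value: float  # molar
    kind: Literal["Kd", "Ki", "IC50"] = "Kd"
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError("affinity value must be positive")


# ---------------------------------------------------------------------------
# File I/O (RDKit-backed)
# ---------------------------------------------------------------------------

def _rdkit():
    from rdkit import Chem  # deferred: keeps import cheap for metric-only use
    return Chem


def _from_rdkit(mol, name: str = "") -> ParameterizedMolecule:
    Chem = _rdkit()
    if mol.GetNumConformers() == 0:
        raise StructureFormatError("structure has no 3D coordinates")
    conf = mol.GetConformer()
    if not conf.Is3D() and all(abs(conf.GetAtomPosition(i).z) < 1e-9
                               for i in range(mol.GetNumAtoms())):
        # allow genuinely planar 3D molecules; reject 2D depictions only when
        # flagged 2D by the file
        if mol.GetNumAtoms() > 1 and not conf.Is3D():
            raise StructureFormatError("structure carries 2D coordinates only")
    atoms = []
    for a in mol.GetAtoms():
        pos = conf.GetAtomPosition(a.GetIdx())
        el = a.GetSymbol()
        atoms.append(Atom(index=a.GetIdx(), element=el,
                          coords=(pos.x, pos.y, pos.z),
                          formal_charge=a.GetFormalCharge(),
                          contact_radius=BONDI_RADII.get(el, 1.7)))
    order_map = {Chem.BondType.SINGLE: "single", Chem.BondType.DOUBLE: "double",
                 Chem.BondType.TRIPLE: "triple", Chem.BondType.AROMATIC: "aromatic"}
    bonds = []
    for b in mol.GetBonds():
        bonds.append(Bond(atom_i=b.GetBeginAtomIdx(), atom_j=b.GetEndAtomIdx(),
                          order=order_map.get(b.GetBondType(), "single"),
                          in_ring=b.IsInRing()))
    pm = ParameterizedMolecule(atoms, bonds, name=name)
    pm._rdmol = mol
    return pm


def read_structure(path: str, fmt: Optional[str] = None,
                   strict_hydrogens: bool = False) -> ParameterizedMolecule:
    """Read a PDB / SDF (V2000) / MOL2 structure with explicit hydrogens.

    Charges and vdW parameters are left unassigned (NaN); call
    :func:`assign_parameters` afterwards.
    """
    Chem = _rdkit()
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = os.path.splitext(path)[1].lstrip(".").lower()
    fmt = fmt.lower()
    if fmt in ("sdf", "sd", "mol"):
        mol = Chem.MolFromMolFile(path, sanitize=False, removeHs=False)
    elif fmt == "mol2":
        mol = Chem.MolFromMol2File(path, sanitize=False, removeHs=False)
    elif fmt == "pdb":
        mol = Chem.MolFromPDBFile(path, sanitize=False, removeHs=False)
    else:
        raise StructureFormatError(f"unsupported format: {fmt}")
    if mol is None or mol.GetNumAtoms() == 0:
        raise StructureFormatError(f"could not parse {path} as {fmt}")
    pm = _from_rdkit(mol, name=os.path.basename(path))
    if not any(a.is_hydrogen for a in pm.atoms):
        msg = f"{path}: no explicit hydrogens found"
        if strict_hydrogens:
            raise StructureFormatError(msg)
        warnings.warn(msg)
    return pm


def _to_rdkit(molecule: ParameterizedMolecule):
    from rdkit import Chem
    from rdkit.Geometry import Point3D
    order_map = {"single": Chem.BondType.SINGLE, "double": Chem.BondType.DOUBLE,
                 "triple": Chem.BondType.TRIPLE, "aromatic": Chem.BondType.AROMATIC}
    rw = Chem.RWMol()
    for a in molecule.atoms:
        ra = Chem.Atom(a.element)
        ra.SetFormalCharge(int(a.formal_charge))
        ra.SetNoImplicit(True)
        rw.AddAtom(ra)
    for b in molecule.bonds:
        rw.AddBond(b.atom_i, b.atom_j, order_map[b.order])
    conf = Chem.Conformer(molecule.n_atoms)
    for i, a in enumerate(molecule.atoms):
        conf.SetAtomPosition(i, Point3D(*map(float, a.coords)))
    conf.Set3D(True)
    mol = rw.GetMol()
    mol.AddConformer(conf)
    return mol


def write_sdf(molecule: ParameterizedMolecule, path: str) -> None:
    from rdkit import Chem
    mol = molecule._rdmol if molecule._rdmol is not None else _to_rdkit(molecule)
    block = Chem.MolToMolBlock(mol, kekulize=False)
    with open(path, "w") as fh:
        fh.write(block)
        fh.write("$$$$\n")


def write_pdb(molecule: ParameterizedMolecule, path: str) -> None:
    from rdkit import Chem
    mol = molecule._rdmol if molecule._rdmol is not None else _to_rdkit(molecule)
    with open(path, "w") as fh:
        fh.write(Chem.MolToPDBBlock(mol))


# ---------------------------------------------------------------------------
# Parameter assignment
# ---------------------------------------------------------------------------

def _assign_builtin(molecule: ParameterizedMolecule) -> None:
    for a in molecule.atoms:
        if a.element not in _ELECTRONEG:
            raise ParameterizationError(
                f"atom {a.index} ({a.element}) outside builtin parameter coverage")
    q = np.array([float(a.formal_charge) for a in molecule.atoms])
    for b in molecule.bonds:
        ei = molecule.atoms[b.atom_i].element
        ej = molecule.atoms[b.atom_j].element
        # charge flows toward the more electronegative end; antisymmetric by
        # construction so the molecular net charge is conserved exactly
        w = _BCI_SCALE * _BOND_ORDER_VALUE[b.order] * (_ELECTRONEG[ej] - _ELECTRONEG[ei])
        q[b.atom_i] += w
        q[b.atom_j] -= w
    for a, qi in zip(molecule.atoms, q):
        a.partial_charge = float(qi)
        eps, rmin = _BUILTIN_VDW[a.element]
        a.vdw_well_depth = eps
        a.vdw_rmin = rmin
        if not math.isfinite(a.contact_radius):
            a.contact_radius = BONDI_RADII[a.element]


def _assign_mmff(molecule: ParameterizedMolecule) -> None:
    from rdkit import Chem
    from rdkit.Chem import AllChem
    mol = molecule._rdmol if molecule._rdmol is not None else _to_rdkit(molecule)
    mol = Chem.Mol(mol)
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - depends on input chemistry
        raise ParameterizationError(f"sanitization failed: {exc}") from exc
    props = AllChem.MMFFGetMoleculeProperties(mol, mmffVariant="MMFF94s")
    if props is None:
        raise ParameterizationError(
            "MMFF94S typing failed (atom outside parameter coverage)")
    for i, a in enumerate(molecule.atoms):
        a.partial_charge = float(props.GetMMFFPartialCharge(i))
        rstar_ii, eps_ii = props.GetMMFFVdWParams(i, i)[2], props.GetMMFFVdWParams(i, i)[3]
        a.vdw_rmin = float(rstar_ii)
        a.vdw_well_depth = float(eps_ii)
        if not math.isfinite(a.contact_radius):
            a.contact_radius = BONDI_RADII.get(a.element, 1.7)


def assign_parameters(molecule: ParameterizedMolecule,
                      backend: str = "auto") -> ParameterizedMolecule:
    """Assign partial charges and vdW parameters in place (and return it).

    backend ``"mmff"`` uses RDKit MMFF94S (bond-charge-increment charges,
    force-field well parameters); ``"builtin"`` uses the minimal element
    table; ``"auto"`` tries MMFF first and falls back to builtin.
    """
    if backend == "builtin":
        _assign_builtin(molecule)
    elif backend == "mmff":
        _assign_mmff(molecule)
    elif backend == "auto":
        try:
            _assign_mmff(molecule)
        except ParameterizationError:
            _assign_builtin(molecule)
    else:
        raise ValueError(f"unknown backend: {backend}")
    molecule.validate_charges()
    return molecule


# ---------------------------------------------------------------------------
# Rotatable bonds
# ---------------------------------------------------------------------------

def _is_amide_cn(molecule: ParameterizedMolecule, b: Bond) -> bool:
    ei = molecule.atoms[b.atom_i].element
    ej = molecule.atoms[b.atom_j].element
    pair = {ei, ej}
    if pair != {"C", "N"}:
        return False
    c_idx = b.atom_i if ei == "C" else b.atom_j
    for other in molecule.bonds:
        if other is b or c_idx not in (other.atom_i, other.atom_j):
            continue
        o_idx = other.atom_j if other.atom_i == c_idx else other.atom_i
        if molecule.atoms[o_idx].element == "O" and other.order == "double":
            return True
    return False


def detect_rotatable_bonds(molecule: ParameterizedMolecule,
                           amide_exclusion: bool = True) -> list:
    """Flag and return rotatable bonds.

    Rule: acyclic single bond between two heavy atoms, each end bonded to at
    least one additional heavy atom; amide C-N bonds excluded by default.
    """
    heavy_degree = {}
    for b in molecule.bonds:
        for i, j in ((b.atom_i, b.atom_j), (b.atom_j, b.atom_i)):
            if not molecule.atoms[j].is_hydrogen:
                heavy_degree[i] = heavy_degree.get(i, 0) + 1
    rotatable = []
    for b in molecule.bonds:
        b.rotatable = False
        if b.order != "single" or b.in_ring:
            continue
        ai, aj = molecule.atoms[b.atom_i], molecule.atoms[b.atom_j]
        if ai.is_hydrogen or aj.is_hydrogen:
            continue
        # each end needs a heavy neighbor besides the bond partner
        if heavy_degree.get(b.atom_i, 0) < 2 or heavy_degree.get(b.atom_j, 0) < 2:
            continue
        if amide_exclusion and _is_amide_cn(molecule, b):
            continue
        b.rotatable = True
        rotatable.append(b)
    return rotatable


# ---------------------------------------------------------------------------
# Affinity conversion
# ---------------------------------------------------------------------------

def affinity_to_energy(affinity: BindingAffinity) -> float:
    """Convert a binding constant (molar) to kcal/mol: RT ln(value).

    Kd, Ki and IC50 are treated identically; temperature is taken from the
    affinity record (default 298.15 K).
    """
    if not affinity.value > 0:
        raise ValueError("affinity value must be positive")
    return GAS_CONSTANT_KCAL * affinity.temperature * math.log(affinity.value)
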