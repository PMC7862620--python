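"""Synthetic test-data generation.

Three families of artifacts, all bit-reproducible from (spec, seed):

* toy receptor-ligand complexes with simple, analyzable geometry (probe
  atoms at requested distances, carbon rotor chains partially enclosed in
  occluding shells, slabs for one-sided burial);
* feature tables drawn from a known linear model plus Gaussian noise, for
  parameter-recovery tests;
* screening score tables with Gaussian active/inactive score distributions.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .metrics import ScreeningTable
from .models import LinearCoefficients
from .structure import (Atom, Bond, ComplexStructure, ParameterizedMolecule,
                        assign_parameters, detect_rotatable_bonds)

__all__ = ["ToyComplexSpec", "make_toy_complex", "make_feature_table",
           "make_screening_scores", "chain_molecule", "shell_atoms",
           "slab_molecule", "FIXTURE_CATALOG"]

CHAIN_SPACING = 1.5      # A between chain carbons
SHELL_CLEARANCE = 2.2    # A from the outermost buried atom to the shell;
                         # must stay below the probe-blocking reach
                         # (r_atom + r_shell + 2 * probe ~ 6.2 A for carbons)
                         # so central atoms of a buried chain are occluded too
SHELL_OPENING = 4.6      # shell atoms closer than this to an unburied
                         # ligand atom are removed (carves the pocket mouth)


@dataclass
class ToyComplexSpec:
    pocket_shape: str = "none"            # none | shell | slab
    pocket_atom_count: int = 250
    ligand_template: str = "rigid_probe"  # rigid_probe | n_rotor_chain(k) | charged_pair
    pair_distances: Sequence[float] = (4.0,)
    charge_overrides: Dict[Tuple[str, int], float] = field(default_factory=dict)
    bury_first_n: Optional[int] = None    # leading ligand atoms enclosed by the shell
    shell_opening: float = SHELL_OPENING  # pocket-mouth carving radius, A
    slab_gap: float = 3.0                 # A from ligand plane to the slab
    extra_receptor_atoms: Sequence[dict] = ()  # {element, coords, q} appended
    seed: int = 0

    def __post_init__(self):
        if any(d <= 0 for d in self.pair_distances):
            raise ValueError("pair distances must be positive")


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float) + 0.5
    z = 1.0 - 2.0 * i / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack((rho * np.cos(theta), rho * np.sin(theta), z))


def chain_molecule(n_heavy: int, element: str = "C",
                   spacing: float = CHAIN_SPACING, name: str = "chain",
                   zigzag: bool = True) -> ParameterizedMolecule:
    """Linear heavy-atom chain along x (slight zigzag in y); single bonds."""
    atoms = []
    for i in range(n_heavy):
        y = 0.4 * (i % 2) if zigzag else 0.0
        atoms.append(Atom(index=i, element=element,
                          coords=(i * spacing, y, 0.0)))
    bonds = [Bond(atom_i=i, atom_j=i + 1) for i in range(n_heavy - 1)]
    return ParameterizedMolecule(atoms, bonds, name=name)


def shell_atoms(center: np.ndarray, radius: float, count: int,
                element: str = "C") -> List[Atom]:
    pts = center + radius * _fibonacci_sphere(count)
    return [Atom(index=i, element=element, coords=p)
            for i, p in enumerate(pts)]


def slab_molecule(extent: float, spacing: float, z: float,
                  element: str = "C", name: str = "slab") -> ParameterizedMolecule:
    """Square grid of atoms in the plane at height z (one-sided occluder)."""
    xs = np.arange(-extent, extent + 1e-9, spacing)
    atoms = []
    k = 0
    for x in xs:
        for y in xs:
            atoms.append(Atom(index=k, element=element, coords=(x, y, z)))
            k += 1
    return ParameterizedMolecule(atoms, [], name=name)


def _parse_template(template: str):
    if template in ("rigid_probe", "charged_pair"):
        return template, 0
    m = re.fullmatch(r"n_rotor_chain\((\d+)\)", template)
    if m:
        return "n_rotor_chain", int(m.group(1))
    raise ValueError(f"unknown ligand template: {template!r}")


def _build_ligand(spec: ToyComplexSpec) -> ParameterizedMolecule:
    kind, k = _parse_template(spec.ligand_template)
    if kind == "rigid_probe":
        return ParameterizedMolecule(
            [Atom(index=0, element="C", coords=(0.0, 0.0, 0.0))], [],
            name="rigid_probe")
    if kind == "charged_pair":
        atoms = [Atom(index=0, element="C", coords=(0.0, 0.0, 0.0)),
                 Atom(index=1, element="O", coords=(1.3, 0.0, 0.0))]
        return ParameterizedMolecule(atoms, [Bond(atom_i=0, atom_j=1)],
                                     name="charged_pair")
    # k rotatable bonds need a chain of k + 3 heavy atoms
    return chain_molecule(k + 3, name=f"rotor_chain_{k}")


def _build_receptor(spec: ToyComplexSpec,
                    ligand: ParameterizedMolecule) -> ParameterizedMolecule:
    lig_xyz = ligand.coords
    if spec.pocket_shape == "none":
        # one probe atom per requested distance, each along its own direction
        # from ligand atom 0 so the realized nearest distance is exact
        dirs = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0],
                         [-1.0, 0, 0], [0, -1.0, 0], [0, 0, -1.0]])
        atoms = []
        for i, d in enumerate(spec.pair_distances):
            atoms.append(Atom(index=i, element="C",
                              coords=lig_xyz[0] + d * dirs[i % len(dirs)]))
        return ParameterizedMolecule(atoms, [], name="probe_pocket")
    if spec.pocket_shape == "shell":
        n_bury = spec.bury_first_n
        if n_bury is None:
            n_bury = ligand.n_atoms
        buried = lig_xyz[:n_bury]
        exposed = lig_xyz[n_bury:]
        center = buried.mean(axis=0)
        radius = float(np.max(np.linalg.norm(buried - center, axis=1))) + SHELL_CLEARANCE
        atoms = shell_atoms(center, radius, spec.pocket_atom_count)
        if len(exposed):
            keep = [a for a in atoms
                    if np.min(np.linalg.norm(exposed - a.coords, axis=1))
                    > spec.shell_opening]
            atoms = keep
        if not atoms:
            raise ValueError("infeasible shell geometry: no pocket atoms left")
        for i, a in enumerate(atoms):
            a.index = i
        return ParameterizedMolecule(atoms, [], name="shell_pocket")
    if spec.pocket_shape == "slab":
        extent = max(6.0, float(np.abs(lig_xyz[:, :2]).max()) + 4.0)
        z = float(lig_xyz[:, 2].min()) - spec.slab_gap
        return slab_molecule(extent, 1.8, z, name="slab_pocket")
    raise ValueError(f"unknown pocket shape: {spec.pocket_shape!r}")


def make_toy_complex(spec: ToyComplexSpec):
    """Build a deterministic toy complex; returns (complex, annotations).

    Annotations record the analytically intended quantities (requested pair
    distances, realized nearest intermolecular distance, rotatable-bond
    count, which atoms the pocket encloses) for oracle-style assertions.
    """
    ligand = _build_ligand(spec)
    receptor = _build_receptor(spec, ligand)
    assign_parameters(ligand, backend="builtin")
    assign_parameters(receptor, backend="builtin")
    if spec.extra_receptor_atoms:
        from .structure import BONDI_RADII, _BUILTIN_VDW
        atoms = list(receptor.atoms)
        for extra in spec.extra_receptor_atoms:
            el = extra["element"]
            eps, rmin = _BUILTIN_VDW[el]
            atoms.append(Atom(index=len(atoms), element=el,
                              coords=extra["coords"],
                              partial_charge=float(extra.get("q", 0.0)),
                              vdw_well_depth=eps, vdw_rmin=rmin,
                              contact_radius=BONDI_RADII[el]))
        receptor = ParameterizedMolecule(atoms, receptor.bonds,
                                         net_charge=receptor.net_charge,
                                         name=receptor.name)
    for (side, idx), q in spec.charge_overrides.items():
        mol = ligand if side == "ligand" else receptor
        mol.atoms[idx].partial_charge = float(q)
    rot = detect_rotatable_bonds(ligand)
    cplx = ComplexStructure(receptor=receptor, ligand=ligand)
    from scipy.spatial.distance import cdist
    dmin = float(cdist(receptor.coords, ligand.coords).min())
    annotations = {
        "requested_distances": list(spec.pair_distances),
        "realized_min_distance": dmin,
        "n_rotatable_bonds": len(rot),
        "rotatable_bonds": [(b.atom_i, b.atom_j) for b in rot],
        "buried_ligand_atoms": (list(range(spec.bury_first_n))
                                if spec.pocket_shape == "shell"
                                and spec.bury_first_n is not None
                                else None),
        "seed": spec.seed,
    }
    return cplx, annotations


def make_feature_table(n: int, coefficients: LinearCoefficients,
                       noise_sigma: float = 0.0,
                       feature_ranges: Optional[Dict[str, Tuple[float, float]]] = None,
                       seed: int = 0) -> pd.DataFrame:
    """Uniform features in stated ranges; targets = linear model + N(0, sigma)."""
    if n < 10:
        raise ValueError("need n >= 10")
    rng = np.random.default_rng(seed)
    feature_ranges = feature_ranges or {}
    data = {}
    for term in coefficients.term_set:
        lo, hi = feature_ranges.get(term, (0.0, 10.0))
        data[term] = rng.uniform(lo, hi, size=n)
    df = pd.DataFrame(data)
    y = np.full(n, coefficients.intercept)
    for term in coefficients.term_set:
        y = y + coefficients.weights[term] * df[term].to_numpy()
    if noise_sigma > 0:
        y = y + rng.normal(0.0, noise_sigma, size=n)
    df.insert(0, "complex_id", [f"cx{i:05d}" for i in range(n)])
    df["dG_exp"] = y
    return df


#: Named toy-complex catalog covering every descriptor-term branch; each
#: entry maps to (spec, expected values).  Expected entries are either exact
#: integers (counts) or (value, abs_tol) pairs.  Verified against the
#: descriptor engine by the test suite.
FIXTURE_CATALOG: Dict[str, dict] = {
    "probe_contact_4A": {
        "spec": ToyComplexSpec(pair_distances=(4.0,)),
        "expect": {"min_distance": (4.0, 1e-6)}},
    "probe_separated_25A": {
        "spec": ToyComplexSpec(pair_distances=(25.0,)),
        "expect": {"E_np_solv": (-0.82, 0.02), "E_lipo": (0.0, 0.0),
                   "E_entropy": 0, "E_coul": (0.0, 1e-12)}},
    "lipo_first_branch": {  # d = d_vdW + 0.3 (C-C Bondi sum 3.4)
        "spec": ToyComplexSpec(pair_distances=(3.7,)),
        "expect": {"E_lipo": (1.0, 1e-9)}},
    "lipo_linear_mid": {    # d = d_vdW + 2.0 -> 1 - 1.5/3
        "spec": ToyComplexSpec(pair_distances=(5.4,)),
        "expect": {"E_lipo": (0.5, 1e-9)}},
    "lipo_zero_branch": {   # d = d_vdW + 4.0
        "spec": ToyComplexSpec(pair_distances=(7.4,)),
        "expect": {"E_lipo": (0.0, 0.0)}},
    "chain_free_3rotors": {
        "spec": ToyComplexSpec(ligand_template="n_rotor_chain(3)",
                               pair_distances=(25.0,)),
        "expect": {"E_entropy": 0, "n_rotatable": 3}},
    "chain_shell_frozen_all": {
        "spec": ToyComplexSpec(pocket_shape="shell",
                               ligand_template="n_rotor_chain(3)"),
        "expect": {"E_entropy": 3}},
    "chain_shell_frozen_two": {
        "spec": ToyComplexSpec(pocket_shape="shell",
                               ligand_template="n_rotor_chain(3)",
                               bury_first_n=5, shell_opening=6.0),
        "expect": {"E_entropy": 2}},
    "chain_slab_unfrozen": {  # ~40% burial per side, below the 50% rule
        "spec": ToyComplexSpec(pocket_shape="slab",
                               ligand_template="n_rotor_chain(3)",
                               slab_gap=4.0),
        "expect": {"E_entropy": 0}},
    "chain_slab_frozen_all": {  # ~56% burial per side
        "spec": ToyComplexSpec(pocket_shape="slab",
                               ligand_template="n_rotor_chain(3)",
                               slab_gap=2.5),
        "expect": {"E_entropy": 3}},
    "polar_buried_unpartnered": {
        "spec": ToyComplexSpec(pocket_shape="shell",
                               ligand_template="charged_pair",
                               charge_overrides={("ligand", 1): -0.9}),
        "expect": {"E_polar_solv": 1}},
    "polar_exposed": {
        "spec": ToyComplexSpec(ligand_template="charged_pair",
                               pair_distances=(25.0,),
                               charge_overrides={("ligand", 1): -0.9}),
        "expect": {"E_polar_solv": 0}},
    "polar_buried_partnered": {
        "spec": ToyComplexSpec(pocket_shape="shell",
                               ligand_template="charged_pair",
                               charge_overrides={("ligand", 1): -0.9},
                               extra_receptor_atoms=(
                                   {"element": "N", "coords": (1.3, 0.0, 3.0),
                                    "q": 0.9},)),
        "expect": {"E_polar_solv": 0}},
}


def make_screening_scores(n_active: int, n_inactive: int,
                          separation: float, seed: int = 0) -> ScreeningTable:
    """Actives score ~ N(-separation, 1), inactives ~ N(0, 1); lower = better."""
    if n_active < 1 or n_inactive < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    scores = np.concatenate([rng.normal(-separation, 1.0, n_active),
                             rng.normal(0.0, 1.0, n_inactive)])
    labels = np.concatenate([np.ones(n_active, bool), np.zeros(n_inactive, bool)])
    ids = [f"act{i}" for i in range(n_active)] + \
          [f"dec{i}" for i in range(n_inactive)]
    return ScreeningTable(ids=ids, scores=scores, labels=labels)
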