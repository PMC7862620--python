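import numpy as np
import pytest

from plscore.structure import (Atom, Bond, ComplexStructure,
                               ParameterizedMolecule, assign_parameters)


def probe_atom(coords, element="C", q=0.0, eps=0.1, rmin=3.5, radius=1.7):
    a = Atom(index=0, element=element, coords=coords, partial_charge=q,
             contact_radius=radius)
    a.vdw_well_depth = eps
    a.vdw_rmin = rmin
    return a


def single_atom_molecule(coords, **kw):
    return ParameterizedMolecule([probe_atom(coords, **kw)], [])


def pair_complex(distance, q1=0.0, q2=0.0, eps1=0.1, eps2=0.1,
                 rmin1=3.5, rmin2=3.5, radius1=1.7, radius2=1.7):
    """One receptor atom and one ligand atom at the given separation."""
    rec = single_atom_molecule((0.0, 0.0, 0.0), q=q1, eps=eps1, rmin=rmin1,
                               radius=radius1)
    lig = single_atom_molecule((distance, 0.0, 0.0), q=q2, eps=eps2,
                               rmin=rmin2, radius=radius2)
    return ComplexStructure(receptor=rec, ligand=lig)


def random_complex(n_rec=10, n_lig=8, seed=0, spread=4.0, charged=True):
    """Random small parameterized complex for brute-force oracle checks."""
    rng = np.random.default_rng(seed)
    elements = ["C", "N", "O", "S"]

    def build(n, offset):
        atoms = []
        for i in range(n):
            el = elements[rng.integers(len(elements))]
            a = Atom(index=i, element=el,
                     coords=offset + rng.uniform(-spread, spread, 3))
            atoms.append(a)
        mol = ParameterizedMolecule(atoms, [])
        assign_parameters(mol, backend="builtin")
        if charged:
            for a in mol.atoms:
                a.partial_charge = float(rng.uniform(-0.8, 0.8))
        return mol

    rec = build(n_rec, np.zeros(3))
    lig = build(n_lig, np.array([6.0, 0.0, 0.0]))
    return ComplexStructure(receptor=rec, ligand=lig)


@pytest.fixture
def rd_molecule():
    """Factory: SMILES -> 3D-embedded ParameterizedMolecule via RDKit."""
    from rdkit import Chem
    from rdkit.Chem import AllChem
    from plscore.structure import _from_rdkit

    def build(smiles, seed=7):
        mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
        assert AllChem.EmbedMolecule(mol, randomSeed=seed) == 0
        return _from_rdkit(mol)

    return build
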