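"""Solvent-accessible surface areas via Shrake-Rupley sphere quadrature.

A fixed golden-spiral lattice of test points is placed on each atom's
solvent-expanded sphere (radius + probe); points falling inside any other
expanded sphere are inaccessible.  The lattice is deterministic, so areas are
bit-reproducible for identical inputs.  This is a stand-in for molecular
surface programs: downstream terms consume SAS only through a linear map and
thresholded ratios, so the algorithm substitution is tolerable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
from scipy.spatial import cKDTree

from .structure import ComplexStructure, ParameterizedMolecule

__all__ = ["SasResult", "solvent_accessible_areas", "delta_sas",
           "DEFAULT_PROBE", "DEFAULT_N_POINTS"]

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960

#: free-side areas below this (Angstrom^2) are treated as fully buried
DEGENERATE_FREE_SAS = 0.5


@dataclass
class SasResult:
    per_atom_area: np.ndarray  # Angstrom^2, input atom order
    total_area: float
    probe_radius: float
    n_sphere_points: int


def _golden_spiral(n: int) -> np.ndarray:
    """n deterministic, nearly uniform unit-sphere points."""
    i = np.arange(n, dtype=float) + 0.5
    z = 1.0 - 2.0 * i / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack((rho * np.cos(theta), rho * np.sin(theta), z))


def _gather(molecules, include_hydrogens: bool):
    coords, radii, keep = [], [], []
    for mol in molecules:
        c = mol.coords
        r = mol.contact_radii
        h = mol.hydrogen_mask
        coords.append(c)
        radii.append(r)
        keep.append(~h if not include_hydrogens else np.ones(len(c), dtype=bool))
    return np.vstack(coords), np.concatenate(radii), np.concatenate(keep)


def solvent_accessible_areas(
    molecules: Union[ParameterizedMolecule, Sequence[ParameterizedMolecule]],
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    include_hydrogens: bool = True,
) -> SasResult:
    """Per-atom SAS of one or more molecules treated as one rigid assembly.

    Excluded atoms (hydrogens in heavy-only mode) get zero area and do not
    occlude.  Areas are in Angstrom^2, ordered as the concatenated input
    atoms.
    """
    if isinstance(molecules, ParameterizedMolecule):
        molecules = [molecules]
    if n_points < 96:
        raise ValueError("n_points must be >= 96")
    coords, radii, keep = _gather(molecules, include_hydrogens)
    if not np.all(radii[keep] > 0):
        raise ValueError("all atoms need a positive contact_radius")
    n = len(coords)
    areas = np.zeros(n)
    if n == 0:
        return SasResult(areas, 0.0, probe, n_points)

    act_idx = np.flatnonzero(keep)
    if len(act_idx) == 0:
        return SasResult(areas, 0.0, probe, n_points)
    act_coords = coords[act_idx]
    act_ext = radii[act_idx] + probe

    if len(act_idx) > 1:
        d = np.linalg.norm(act_coords[:, None, :] - act_coords[None, :, :], axis=-1)
        iu = np.triu_indices(len(act_idx), k=1)
        if np.any(d[iu] < 1e-9):
            warnings.warn("two atoms share identical coordinates; "
                          "areas remain defined")

    unit = _golden_spiral(n_points)
    tree = cKDTree(act_coords)
    max_ext = act_ext.max()
    for k, ai in enumerate(act_idx):
        ext = act_ext[k]
        # neighbors whose expanded sphere can reach this atom's test sphere
        nb = tree.query_ball_point(act_coords[k], ext + max_ext)
        nb = [j for j in nb if j != k]
        pts = act_coords[k] + ext * unit
        if nb:
            nb_c = act_coords[nb]
            nb_e = act_ext[nb]
            d2 = np.sum((pts[:, None, :] - nb_c[None, :, :]) ** 2, axis=-1)
            buried = np.any(d2 < (nb_e[None, :] ** 2) - 1e-12, axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[ai] = frac * 4.0 * np.pi * ext * ext
    return SasResult(areas, float(areas.sum()), probe, n_points)


def delta_sas(
    cplx: ComplexStructure,
    atom_subset: Iterable[int],
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    include_hydrogens: bool = True,
    free_result: SasResult = None,
    bound_result: SasResult = None,
):
    """SAS change of a global-index atom subset upon binding.

    Returns ``(free, bound, fraction_lost)``; ``fraction_lost`` is
    ``(free - bound) / free``, defined as 1 when the free-state area is
    degenerate (< 0.5 A^2, i.e. the side is already buried pre-binding).
    Precomputed :class:`SasResult` objects can be passed to amortize the
    quadrature over many subsets.
    """
    subset = np.asarray(list(atom_subset), dtype=int)
    if subset.size == 0:
        raise ValueError("atom subset must be non-empty")
    side = cplx.global_side(subset)  # raises if subset spans both molecules
    nr = cplx.n_receptor
    if free_result is None:
        parent = cplx.receptor if side == "receptor" else cplx.ligand
        free_result = solvent_accessible_areas(
            parent, probe=probe, n_points=n_points,
            include_hydrogens=include_hydrogens)
    if bound_result is None:
        bound_result = solvent_accessible_areas(
            [cplx.receptor, cplx.ligand], probe=probe, n_points=n_points,
            include_hydrogens=include_hydrogens)
    local = subset if side == "receptor" else subset - nr
    free = float(free_result.per_atom_area[local].sum())
    bound = float(bound_result.per_atom_area[subset].sum())
    if free < DEGENERATE_FREE_SAS:
        fraction_lost = 1.0
    else:
        fraction_lost = (free - bound) / free
    return free, bound, fraction_lost
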