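"""Physics-based intermolecular interaction terms and the descriptor vector.

Six terms are computed on a parameterized receptor-ligand complex:

* ``E_coul`` — Coulomb energy with a buffered distance and a constant or
  sigmoidal distance-dependent dielectric (Hingerty or Ramstein-Lavery).
* ``E_vdW`` — buffered 14-7 van der Waals energy with a configurable
  buffering constant (0.07 original, 0.67 softened).
* ``E_lipo`` — piecewise-linear lipophilic contact count (carbon-carbon or
  partial-charge-window atom selection).
* ``E_polar_solv`` — number of charged atoms buried upon binding with no
  charged interaction partner in the complex.
* ``E_np_solv`` — surface-area loss mapped to energy, G_np(S) = 0.0092 S + 0.82.
* ``E_entropy`` — number of ligand rotatable bonds frozen by binding (both
  bond sides lose >= 50% of their accessible surface).

The default configuration matches the selected basic function: Ramstein
dielectric tending to 4 plus the softened vdW potential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Literal, Optional

import numpy as np
from scipy.spatial.distance import cdist

from .structure import ComplexStructure, detect_rotatable_bonds
from .surface import solvent_accessible_areas, delta_sas, DEGENERATE_FREE_SAS

__all__ = [
    "DielectricModel", "TermConfig", "DescriptorVector",
    "dielectric_constant", "coulomb_term", "vdw_term", "lipophilic_term",
    "polar_solvation_term", "nonpolar_solvation_term", "one_solv_term",
    "torsional_entropy_term", "compute_descriptors", "g_np",
    "COULOMB_CONSTANT", "TERM_NAMES", "TERM_NAMES_ONESOLV",
]

COULOMB_CONSTANT = 332.0716  # kcal A / (mol e^2)

TERM_NAMES = ["E_coul", "E_vdW", "E_lipo", "E_entropy", "E_polar_solv", "E_np_solv"]
TERM_NAMES_ONESOLV = ["E_coul", "E_vdW", "E_lipo", "E_entropy", "oneSolv"]


@dataclass
class DielectricModel:
    kind: Literal["constant", "hingerty", "ramstein"] = "ramstein"
    D: float = 78.0
    D_i: float = 4.0
    s: float = 0.16
    constant_value: float = 1.0

    def __post_init__(self):
        if not (self.D >= self.D_i >= 1.0):
            raise ValueError("require D >= D_i >= 1")
        if self.s <= 0:
            raise ValueError("require s > 0")


@dataclass
class TermConfig:
    coulomb_constant: float = COULOMB_CONSTANT
    delta_elec: float = 0.05          # A, electrostatic buffering constant
    delta_vdw: float = 0.67           # 0.07 original / 0.67 softened
    gamma_vdw: float = 0.12
    lipo_variant: Literal["carbons", "charge_window"] = "charge_window"
    lipo_charge_window: tuple = (-0.4, 0.4)
    polar_charge_threshold: float = 0.8
    polar_contact_pad: float = 1.0    # A beyond the vdW radii sum
    polar_burial_threshold: float = 0.1  # bound SAS <= 10% of free SAS
    np_slope: float = 0.0092          # kcal/(mol A^2)
    np_intercept: float = 0.82        # kcal/mol
    entropy_burial_fraction: float = 0.5
    entropy_sides_include_hydrogens: bool = True
    polar_partner_opposite_sign_only: bool = False
    include_hydrogens_in_sas: bool = True
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    cutoff: Optional[float] = None    # optional nonbonded cutoff (non-canonical)
    amide_exclusion: bool = True

    def __post_init__(self):
        lo, hi = self.lipo_charge_window
        if not math.isclose(-lo, hi):
            raise ValueError("lipophilic charge window must be symmetric")
        for v in (self.delta_elec, self.gamma_vdw, self.polar_charge_threshold,
                  self.polar_contact_pad, self.np_slope):
            if v <= 0:
                raise ValueError("thresholds must be positive")


@dataclass
class DescriptorVector:
    E_coul: float
    E_vdW: float
    E_lipo: float
    E_entropy: int
    E_polar_solv: Optional[int] = None
    E_np_solv: Optional[float] = None
    oneSolv: Optional[float] = None

    def as_dict(self) -> dict:
        d = {"E_coul": self.E_coul, "E_vdW": self.E_vdW,
             "E_lipo": self.E_lipo, "E_entropy": self.E_entropy}
        if self.oneSolv is not None:
            d["oneSolv"] = self.oneSolv
        else:
            d["E_polar_solv"] = self.E_polar_solv
            d["E_np_solv"] = self.E_np_solv
        return d


# ---------------------------------------------------------------------------
# Dielectric functions
# ---------------------------------------------------------------------------

def dielectric_constant(r, model: DielectricModel):
    """Distance-dependent dielectric epsilon(r); r in Angstrom, scalar or array."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be >= 0")
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    if model.kind == "constant":
        eps = np.full_like(r, model.constant_value)
    elif model.kind == "hingerty":
        x = r / 2.5
        with np.errstate(over="ignore"):
            em1 = np.expm1(x)
            eps = np.where(
                x < 1e-8,
                1.0,  # analytic limit: x^2 e^x/(e^x-1)^2 -> 1
                78.0 - 77.0 * np.square(x) * np.exp(x) / np.square(np.where(em1 == 0, 1, em1)),
            )
        eps = np.where(np.isfinite(eps), eps, 78.0)  # overflow at huge r
    elif model.kind == "ramstein":
        rs = r * model.s
        eps = model.D - ((model.D - model.D_i) / 2.0) * (rs * rs + 2.0 * rs + 2.0) * np.exp(-rs)
    else:
        raise ValueError(f"unknown dielectric kind: {model.kind}")
    return float(eps[0]) if scalar else eps


# ---------------------------------------------------------------------------
# Pairwise geometry helpers
# ---------------------------------------------------------------------------

def _check_parameterized(cplx: ComplexStructure) -> None:
    for mol, label in ((cplx.receptor, "receptor"), (cplx.ligand, "ligand")):
        if not mol.is_parameterized:
            raise ValueError(f"{label} is not parameterized; "
                             "call assign_parameters first")


def _pair_distances(cplx: ComplexStructure) -> np.ndarray:
    return cdist(cplx.receptor.coords, cplx.ligand.coords)


# ---------------------------------------------------------------------------
# Terms
# ---------------------------------------------------------------------------

def coulomb_term(cplx: ComplexStructure, model: DielectricModel = None,
                 cfg: TermConfig = None) -> float:
    """Sum over intermolecular pairs of k q_i q_j / (eps(R) (R + delta_elec))."""
    model = model or DielectricModel()
    cfg = cfg or TermConfig()
    _check_parameterized(cplx)
    R = _pair_distances(cplx)
    qq = np.outer(cplx.receptor.charges, cplx.ligand.charges)
    eps = dielectric_constant(R.ravel(), model).reshape(R.shape)
    e = cfg.coulomb_constant * qq / (eps * (R + cfg.delta_elec))
    if cfg.cutoff is not None:
        e = np.where(R <= cfg.cutoff, e, 0.0)
    return float(e.sum())


def _pair_vdw_params(cplx: ComplexStructure):
    """Combine per-atom homonuclear well parameters into pair parameters.

    eps_ij = sqrt(eps_ii eps_jj); R*_ij = (R*_ii + R*_jj)/2.
    """
    er = np.array([a.vdw_well_depth for a in cplx.receptor.atoms])
    el = np.array([a.vdw_well_depth for a in cplx.ligand.atoms])
    rr = np.array([a.vdw_rmin for a in cplx.receptor.atoms])
    rl = np.array([a.vdw_rmin for a in cplx.ligand.atoms])
    if np.any(~np.isfinite(er)) or np.any(~np.isfinite(el)):
        raise ValueError("missing vdW pair parameters")
    eps_ij = np.sqrt(np.outer(er, el))
    rstar_ij = 0.5 * (rr[:, None] + rl[None, :])
    return eps_ij, rstar_ij


def buf_14_7(R, eps_ij, rstar_ij, delta: float, gamma: float = 0.12):
    """Buffered 14-7 pair energy (vectorized)."""
    R = np.asarray(R, dtype=float)
    t1 = ((1.0 + delta) * rstar_ij / (R + delta * rstar_ij)) ** 7
    t2 = (1.0 + gamma) * rstar_ij ** 7 / (R ** 7 + gamma * rstar_ij ** 7) - 2.0
    return eps_ij * t1 * t2


def vdw_term(cplx: ComplexStructure, cfg: TermConfig = None) -> float:
    cfg = cfg or TermConfig()
    _check_parameterized(cplx)
    R = _pair_distances(cplx)
    eps_ij, rstar_ij = _pair_vdw_params(cplx)
    e = buf_14_7(R, eps_ij, rstar_ij, cfg.delta_vdw, cfg.gamma_vdw)
    if cfg.cutoff is not None:
        e = np.where(R <= cfg.cutoff, e, 0.0)
    return float(e.sum())


def lipo_pair_contribution(d, d_vdw):
    """Piecewise-linear contact weight: 1 inside d_vdW+0.5, linear to 0 at
    d_vdW+3.5 (continuous at both breakpoints)."""
    d = np.asarray(d, dtype=float)
    x = d - d_vdw
    return np.clip(np.where(x <= 0.5, 1.0, 1.0 - (x - 0.5) / 3.0), 0.0, 1.0)


def lipophilic_term(cplx: ComplexStructure, cfg: TermConfig = None) -> float:
    cfg = cfg or TermConfig()
    _check_parameterized(cplx)
    if cfg.lipo_variant == "carbons":
        mr = np.array([a.element == "C" for a in cplx.receptor.atoms])
        ml = np.array([a.element == "C" for a in cplx.ligand.atoms])
    elif cfg.lipo_variant == "charge_window":
        lo, hi = cfg.lipo_charge_window
        mr = np.array([(not a.is_hydrogen) and lo < a.partial_charge < hi
                       for a in cplx.receptor.atoms])
        ml = np.array([(not a.is_hydrogen) and lo < a.partial_charge < hi
                       for a in cplx.ligand.atoms])
    else:
        raise ValueError(f"unknown lipophilic variant: {cfg.lipo_variant}")
    if not mr.any() or not ml.any():
        return 0.0
    cr = cplx.receptor.coords[mr]
    cl = cplx.ligand.coords[ml]
    d = cdist(cr, cl)
    d_vdw = (cplx.receptor.contact_radii[mr][:, None]
             + cplx.ligand.contact_radii[ml][None, :])
    return float(lipo_pair_contribution(d, d_vdw).sum())


def _charged_mask(mol, threshold: float) -> np.ndarray:
    return np.array([(not a.is_hydrogen) and a.element != "C"
                     and abs(a.partial_charge) > threshold for a in mol.atoms])


def polar_solvation_term(cplx: ComplexStructure, cfg: TermConfig = None) -> int:
    """Count charged atoms buried upon binding without a charged partner.

    A charged atom is non-hydrogen, non-carbon with |q| > 0.8 e.  Burial:
    bound-state SAS <= 10% of free-state SAS (or free-state already
    degenerate).  Two charged atoms interact when their distance is within
    the sum of their vdW radii + 1.0 A; covalently bonded neighbors are not
    counted as partners.
    """
    cfg = cfg or TermConfig()
    _check_parameterized(cplx)
    mols = [cplx.receptor, cplx.ligand]
    masks = [_charged_mask(m, cfg.polar_charge_threshold) for m in mols]
    if not any(m.any() for m in masks):
        return 0

    sas_kw = dict(probe=cfg.probe_radius, n_points=cfg.n_sphere_points,
                  include_hydrogens=cfg.include_hydrogens_in_sas)
    bound = solvent_accessible_areas(mols, **sas_kw)
    free = [solvent_accessible_areas(m, **sas_kw) for m in mols]
    offsets = [0, cplx.n_receptor]

    # global catalog of charged atoms for the partner test
    charged = []  # (global_idx, mol_idx, local_idx, coords, q, radius)
    for mi, (mol, mask) in enumerate(zip(mols, masks)):
        for li in np.flatnonzero(mask):
            a = mol.atoms[li]
            charged.append((offsets[mi] + li, mi, int(li), a.coords,
                            a.partial_charge, a.contact_radius))

    bonded = [m.bonded_pairs() for m in mols]
    count = 0
    for gi, mi, li, xyz, q, rad in charged:
        f = free[mi].per_atom_area[li]
        b = bound.per_atom_area[gi]
        buried = f < DEGENERATE_FREE_SAS or b <= cfg.polar_burial_threshold * f
        if not buried:
            continue
        has_partner = False
        for gj, mj, lj, xyz2, q2, rad2 in charged:
            if gj == gi:
                continue
            if mi == mj and frozenset((li, lj)) in bonded[mi]:
                continue
            if cfg.polar_partner_opposite_sign_only and q * q2 >= 0:
                continue
            if np.linalg.norm(xyz - xyz2) <= rad + rad2 + cfg.polar_contact_pad:
                has_partner = True
                break
        if not has_partner:
            count += 1
    return count


def g_np(sas: float, cfg: TermConfig = None) -> float:
    """Nonpolar surface free energy map, kcal/mol."""
    cfg = cfg or TermConfig()
    return cfg.np_slope * sas + cfg.np_intercept


def _sas_delta_energy(cplx: ComplexStructure, cfg: TermConfig,
                      include_hydrogens: bool, heavy_only: bool) -> float:
    kw = dict(probe=cfg.probe_radius, n_points=cfg.n_sphere_points,
              include_hydrogens=include_hydrogens and not heavy_only)
    s_complex = solvent_accessible_areas([cplx.receptor, cplx.ligand], **kw).total_area
    s_rec = solvent_accessible_areas(cplx.receptor, **kw).total_area
    s_lig = solvent_accessible_areas(cplx.ligand, **kw).total_area
    return g_np(s_complex, cfg) - (g_np(s_rec, cfg) + g_np(s_lig, cfg))


def nonpolar_solvation_term(cplx: ComplexStructure, cfg: TermConfig = None) -> float:
    """G_np(complex SAS) - G_np(free receptor SAS) - G_np(free ligand SAS)."""
    cfg = cfg or TermConfig()
    return _sas_delta_energy(cplx, cfg, cfg.include_hydrogens_in_sas,
                             heavy_only=False)


def one_solv_term(cplx: ComplexStructure, cfg: TermConfig = None) -> float:
    """Merged solvation term: same map as the nonpolar term but the SAS is
    restricted to all heavy atoms (polar and nonpolar)."""
    cfg = cfg or TermConfig()
    return _sas_delta_energy(cplx, cfg, True, heavy_only=True)


def torsional_entropy_term(cplx: ComplexStructure, cfg: TermConfig = None) -> int:
    """Count ligand rotatable bonds frozen by binding.

    For bond (i, j) the two sides are {i} + neighbors(i) \\ {j} and
    {j} + neighbors(j) \\ {i} (hydrogens included by default); a bond is
    frozen iff both sides lose >= 50% of their free-state SAS.
    """
    cfg = cfg or TermConfig()
    lig = cplx.ligand
    rot = [b for b in lig.bonds if b.rotatable]
    if not rot:
        rot = detect_rotatable_bonds(lig, amide_exclusion=cfg.amide_exclusion)
    if not rot:
        return 0
    kw = dict(probe=cfg.probe_radius, n_points=cfg.n_sphere_points,
              include_hydrogens=cfg.include_hydrogens_in_sas)
    free_lig = solvent_accessible_areas(lig, **kw)
    bound = solvent_accessible_areas([cplx.receptor, lig], **kw)
    nr = cplx.n_receptor

    def side_atoms(root: int, exclude: int) -> list:
        side = [root]
        for nb in lig.neighbors(root):
            if nb == exclude:
                continue
            if not cfg.entropy_sides_include_hydrogens and lig.atoms[nb].is_hydrogen:
                continue
            side.append(nb)
        return [nr + k for k in side]

    frozen = 0
    for b in rot:
        both = True
        for root, other in ((b.atom_i, b.atom_j), (b.atom_j, b.atom_i)):
            _, _, frac = delta_sas(cplx, side_atoms(root, other),
                                   free_result=free_lig, bound_result=bound)
            if frac < cfg.entropy_burial_fraction:
                both = False
                break
        if both:
            frozen += 1
    return frozen


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def compute_descriptors(cplx: ComplexStructure,
                        cfg: TermConfig = None,
                        model: DielectricModel = None,
                        solvation: Literal["two_terms", "one_solv"] = "two_terms",
                        ) -> DescriptorVector:
    """All terms on one parameterized complex; deterministic given config."""
    cfg = cfg or TermConfig()
    model = model or DielectricModel()
    if cplx.ligand.n_atoms == 0 or cplx.receptor.n_atoms == 0:
        raise ValueError("complex must contain a non-empty receptor and ligand")
    _check_parameterized(cplx)
    vec = DescriptorVector(
        E_coul=coulomb_term(cplx, model, cfg),
        E_vdW=vdw_term(cplx, cfg),
        E_lipo=lipophilic_term(cplx, cfg),
        E_entropy=torsional_entropy_term(cplx, cfg),
    )
    if solvation == "one_solv":
        vec.oneSolv = one_solv_term(cplx, cfg)
    elif solvation == "two_terms":
        vec.E_polar_solv = polar_solvation_term(cplx, cfg)
        vec.E_np_solv = nonpolar_solvation_term(cplx, cfg)
    else:
        raise ValueError(f"unknown solvation mode: {solvation}")
    return vec
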