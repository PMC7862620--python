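import math

import numpy as np
import pytest

from plscore.descriptors import (DielectricModel, TermConfig,
                                 buf_14_7, compute_descriptors, coulomb_term,
                                 dielectric_constant, g_np,
                                 lipo_pair_contribution, lipophilic_term,
                                 nonpolar_solvation_term, one_solv_term,
                                 polar_solvation_term, torsional_entropy_term,
                                 vdw_term, COULOMB_CONSTANT)
from plscore.fixtures import FIXTURE_CATALOG, ToyComplexSpec, make_toy_complex
from plscore.structure import ComplexStructure

from conftest import pair_complex, random_complex

CONST_EPS1 = DielectricModel(kind="constant", constant_value=1.0, D_i=1.0)


# ---------------------------------------------------------------------------
# Dielectric functions
# ---------------------------------------------------------------------------

class TestDielectric:
    def test_ramstein_zero_distance_limit(self):
        for di in (1.0, 4.0):
            m = DielectricModel(kind="ramstein", D_i=di)
            assert dielectric_constant(0.0, m) == pytest.approx(di)

    def test_ramstein_rs_equals_one(self):
        m = DielectricModel(kind="ramstein", D_i=4.0)
        # r s = 1 at r = 6.25: 78 - 37 * 5 / e
        expected = 78.0 - 37.0 * 5.0 / math.e
        assert dielectric_constant(6.25, m) == pytest.approx(expected, abs=1e-9)

    def test_hingerty_limits(self):
        h = DielectricModel(kind="hingerty", D_i=1.0)
        assert dielectric_constant(1e-10, h) == pytest.approx(1.0, abs=1e-6)
        assert dielectric_constant(100.0, h) == pytest.approx(78.0, abs=1e-6)

    def test_ramstein_long_range(self):
        # (rs)^2 e^{-rs} decays but is ~1e-3 at r = 100 with s = 0.16
        m = DielectricModel(kind="ramstein", D_i=4.0)
        assert dielectric_constant(100.0, m) == pytest.approx(78.0, abs=2e-3)
        assert dielectric_constant(300.0, m) == pytest.approx(78.0, abs=1e-6)

    @pytest.mark.parametrize("kind,di", [("hingerty", 1.0), ("ramstein", 1.0),
                                         ("ramstein", 4.0)])
    def test_monotone_and_bounded(self, kind, di):
        m = DielectricModel(kind=kind, D_i=di)
        r = np.linspace(0.0, 50.0, 2001)
        eps = dielectric_constant(r, m)
        lower = di if kind == "ramstein" else 1.0
        assert np.all(np.diff(eps) >= -1e-9)
        assert np.all(eps >= lower - 1e-9)
        assert np.all(eps <= 78.0 + 1e-9)

    def test_negative_r_rejected(self):
        with pytest.raises(ValueError):
            dielectric_constant(-1.0, DielectricModel())

    def test_invalid_model(self):
        with pytest.raises(ValueError):
            DielectricModel(D=2.0, D_i=4.0)


# ---------------------------------------------------------------------------
# Coulomb
# ---------------------------------------------------------------------------

class TestCoulomb:
    def test_unit_charges_buffered_to_one(self):
        # R + delta_elec = 1.0 exactly
        cplx = pair_complex(0.95, q1=1.0, q2=1.0)
        e = coulomb_term(cplx, CONST_EPS1, TermConfig())
        assert e == pytest.approx(COULOMB_CONSTANT, abs=1e-9)

    def test_zero_charge_pair(self):
        cplx = pair_complex(2.0, q1=0.0, q2=1.0)
        assert coulomb_term(cplx, CONST_EPS1) == 0.0

    @pytest.mark.parametrize("kind", ["constant", "hingerty", "ramstein"])
    def test_brute_force_oracle(self, kind):
        cplx = random_complex(n_rec=10, n_lig=8, seed=11)
        model = DielectricModel(kind=kind, D_i=4.0 if kind == "ramstein" else 1.0)
        cfg = TermConfig()
        expected = 0.0
        for ar in cplx.receptor.atoms:
            for al in cplx.ligand.atoms:
                r = float(np.linalg.norm(ar.coords - al.coords))
                eps = dielectric_constant(r, model)
                expected += (cfg.coulomb_constant * ar.partial_charge
                             * al.partial_charge / (eps * (r + cfg.delta_elec)))
        assert coulomb_term(cplx, model, cfg) == pytest.approx(expected, abs=1e-9)

    def test_unparameterized_rejected(self):
        cplx = pair_complex(2.0)
        cplx.ligand.atoms[0].partial_charge = math.nan
        with pytest.raises(ValueError):
            coulomb_term(cplx, CONST_EPS1)


# ---------------------------------------------------------------------------
# Buffered 14-7 van der Waals
# ---------------------------------------------------------------------------

class TestVdw:
    @pytest.mark.parametrize("delta", [0.07, 0.67])
    def test_minimum_at_rstar(self, delta):
        cplx = pair_complex(3.5, eps1=0.2, eps2=0.05, rmin1=3.5, rmin2=3.5)
        eps_ij = math.sqrt(0.2 * 0.05)
        cfg = TermConfig(delta_vdw=delta)
        assert vdw_term(cplx, cfg) == pytest.approx(-eps_ij, abs=1e-12)

    @pytest.mark.parametrize("delta", [0.07, 0.67])
    def test_grid_search_minimum(self, delta):
        # E(R*) = -eps exactly (both bracketed factors reduce to 1 and -1),
        # but for delta != gamma the true minimum sits slightly off R* and is
        # marginally deeper, so the grid check carries a tolerance.
        assert buf_14_7(3.7, 0.13, 3.7, delta) == pytest.approx(-0.13, abs=1e-15)
        r = np.linspace(1.0, 10.0, 20001)
        e = buf_14_7(r, 0.13, 3.7, delta)
        i = int(np.argmin(e))
        assert abs(r[i] - 3.7) / 3.7 < 0.04
        assert -0.13 * 1.05 < e[i] <= -0.13

    def test_long_range_decay(self):
        cplx = pair_complex(50.0, eps1=0.1, eps2=0.1)
        assert abs(vdw_term(cplx)) < 1e-6 * 0.1

    def test_softened_less_repulsive_short_range(self):
        r = np.linspace(1.5, 3.4, 200)  # inside R* = 3.5
        e_orig = buf_14_7(r, 0.1, 3.5, 0.07)
        e_soft = buf_14_7(r, 0.1, 3.5, 0.67)
        repulsive = e_orig > 0
        assert repulsive.any()
        assert np.all(e_soft[repulsive] < e_orig[repulsive])

    def test_brute_force_oracle(self):
        cplx = random_complex(n_rec=12, n_lig=9, seed=13)
        cfg = TermConfig()
        expected = 0.0
        for ar in cplx.receptor.atoms:
            for al in cplx.ligand.atoms:
                r = float(np.linalg.norm(ar.coords - al.coords))
                eps_ij = math.sqrt(ar.vdw_well_depth * al.vdw_well_depth)
                rstar = 0.5 * (ar.vdw_rmin + al.vdw_rmin)
                t1 = ((1 + cfg.delta_vdw) * rstar / (r + cfg.delta_vdw * rstar)) ** 7
                t2 = (1 + cfg.gamma_vdw) * rstar ** 7 / (r ** 7 + cfg.gamma_vdw * rstar ** 7) - 2
                expected += eps_ij * t1 * t2
        assert vdw_term(cplx, cfg) == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# Lipophilic contacts
# ---------------------------------------------------------------------------

class TestLipophilic:
    def test_first_branch(self):
        assert lipo_pair_contribution(3.7, 3.4) == pytest.approx(1.0)

    def test_linear_branch_midpoint(self):
        assert lipo_pair_contribution(5.4, 3.4) == pytest.approx(0.5)

    def test_zero_branch(self):
        assert lipo_pair_contribution(7.4, 3.4) == 0.0

    def test_continuity_at_breakpoints(self):
        for bp in (0.5, 3.5):
            lo = lipo_pair_contribution(3.4 + bp - 1e-9, 3.4)
            hi = lipo_pair_contribution(3.4 + bp + 1e-9, 3.4)
            assert lo == pytest.approx(hi, abs=1e-6)

    def test_non_increasing(self):
        d = np.linspace(0.0, 10.0, 1000)
        c = lipo_pair_contribution(d, 3.4)
        assert np.all(np.diff(c) <= 1e-12)

    def test_hydrogens_never_eligible(self):
        cplx = pair_complex(3.0)
        cplx.ligand.atoms[0].element = "H"
        cplx.ligand.atoms[0].is_hydrogen = True
        for variant in ("carbons", "charge_window"):
            assert lipophilic_term(cplx, TermConfig(lipo_variant=variant)) == 0.0

    def test_charge_window_excludes_charged(self):
        cplx = pair_complex(3.0, q1=0.0, q2=0.6)
        cfg = TermConfig(lipo_variant="charge_window")
        assert lipophilic_term(cplx, cfg) == 0.0
        # same geometry with both atoms carbon is eligible under "carbons"
        assert lipophilic_term(cplx, TermConfig(lipo_variant="carbons")) > 0.0

    def test_brute_force_oracle(self):
        cplx = random_complex(n_rec=14, n_lig=10, seed=17)
        cfg = TermConfig(lipo_variant="charge_window")
        lo, hi = cfg.lipo_charge_window
        expected = 0.0
        for ar in cplx.receptor.atoms:
            for al in cplx.ligand.atoms:
                if ar.is_hydrogen or al.is_hydrogen:
                    continue
                if not (lo < ar.partial_charge < hi and lo < al.partial_charge < hi):
                    continue
                d = float(np.linalg.norm(ar.coords - al.coords))
                dv = ar.contact_radius + al.contact_radius
                if d <= dv + 0.5:
                    expected += 1.0
                elif d <= dv + 3.5:
                    expected += 1.0 - (d - dv - 0.5) / 3.0
        assert lipophilic_term(cplx, cfg) == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# Solvation terms
# ---------------------------------------------------------------------------

class TestPolarSolvation:
    def test_no_charged_atoms(self):
        cplx = random_complex(seed=19)  # charges capped at |0.8|
        assert polar_solvation_term(cplx) == 0

    def test_buried_unpartnered_counts(self):
        cplx, _ = make_toy_complex(
            FIXTURE_CATALOG["polar_buried_unpartnered"]["spec"])
        assert polar_solvation_term(cplx) == 1

    def test_partner_suppresses_count(self):
        cplx, _ = make_toy_complex(
            FIXTURE_CATALOG["polar_buried_partnered"]["spec"])
        assert polar_solvation_term(cplx) == 0

    def test_exposed_not_counted(self):
        cplx, _ = make_toy_complex(FIXTURE_CATALOG["polar_exposed"]["spec"])
        assert polar_solvation_term(cplx) == 0


class TestNonpolarSolvation:
    def test_gnp_at_zero(self):
        assert g_np(0.0) == pytest.approx(0.82)

    def test_gnp_linear(self):
        assert g_np(100.0) == pytest.approx(0.0092 * 100 + 0.82)

    def test_separated_constant_offset(self):
        cplx = pair_complex(25.0)
        assert nonpolar_solvation_term(cplx) == pytest.approx(-0.82, abs=0.01)

    def test_hundred_square_angstrom_burial(self):
        # bracket the separation at which exactly 100 A^2 of total SAS is
        # lost, then evaluate the term there: 0.0092 * (-100) - 0.82
        from plscore.surface import solvent_accessible_areas

        def lost(d):
            cplx = pair_complex(d, radius1=2.2, radius2=2.2)
            s_c = solvent_accessible_areas([cplx.receptor, cplx.ligand]).total_area
            s_f = (solvent_accessible_areas(cplx.receptor).total_area
                   + solvent_accessible_areas(cplx.ligand).total_area)
            return s_f - s_c

        lo, hi = 0.5, 7.0
        assert lost(lo) > 100.0 > lost(hi)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if lost(mid) > 100.0:
                lo = mid
            else:
                hi = mid
        cplx = pair_complex(0.5 * (lo + hi), radius1=2.2, radius2=2.2)
        assert nonpolar_solvation_term(cplx) == pytest.approx(
            0.0092 * -100.0 - 0.82, abs=0.02)


class TestOneSolv:
    def test_equals_nonpolar_on_hydrogen_free_fixture(self):
        cplx = random_complex(seed=23)  # heavy atoms only by construction
        assert one_solv_term(cplx) == pytest.approx(
            nonpolar_solvation_term(cplx), abs=1e-12)

    def test_separated_constant_offset(self):
        cplx = pair_complex(25.0)
        assert one_solv_term(cplx) == pytest.approx(-0.82, abs=0.01)

    def test_monotone_in_burial(self):
        values = [one_solv_term(pair_complex(d)) for d in (6.0, 4.0, 3.0, 2.0)]
        assert all(b < a for a, b in zip(values, values[1:]))

    def test_ignores_hydrogens(self):
        cplx = pair_complex(3.0)
        ref = one_solv_term(cplx)
        cplx.ligand.atoms[0].element = "H"
        cplx.ligand.atoms[0].is_hydrogen = True
        # all-H ligand: only the receptor sphere remains on both sides
        assert one_solv_term(cplx) == pytest.approx(-0.82, abs=1e-9)
        assert ref != pytest.approx(-0.82, abs=0.1)


# ---------------------------------------------------------------------------
# Torsional entropy
# ---------------------------------------------------------------------------

class TestEntropy:
    def test_rigid_ligand_zero(self):
        cplx, _ = make_toy_complex(ToyComplexSpec(pair_distances=(4.0,)))
        assert torsional_entropy_term(cplx) == 0

    def test_both_sides_buried_frozen(self):
        cplx, ann = make_toy_complex(
            FIXTURE_CATALOG["chain_shell_frozen_all"]["spec"])
        assert torsional_entropy_term(cplx) == ann["n_rotatable_bonds"] == 3

    def test_partial_burial_two_frozen(self):
        cplx, _ = make_toy_complex(
            FIXTURE_CATALOG["chain_shell_frozen_two"]["spec"])
        assert torsional_entropy_term(cplx) == 2

    def test_below_threshold_not_frozen(self):
        cplx, _ = make_toy_complex(
            FIXTURE_CATALOG["chain_slab_unfrozen"]["spec"])
        assert torsional_entropy_term(cplx) == 0

    def test_separated_ligand_zero(self):
        cplx, _ = make_toy_complex(
            ToyComplexSpec(ligand_template="n_rotor_chain(3)",
                           pair_distances=(25.0,)))
        assert torsional_entropy_term(cplx) == 0

    def test_bounded_by_rotor_count(self):
        for name in ("chain_shell_frozen_all", "chain_shell_frozen_two",
                     "chain_slab_frozen_all"):
            cplx, ann = make_toy_complex(FIXTURE_CATALOG[name]["spec"])
            assert 0 <= torsional_entropy_term(cplx) <= ann["n_rotatable_bonds"]


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

class TestComputeDescriptors:
    def test_empty_ligand_rejected(self):
        cplx = random_complex(seed=29)
        from plscore.structure import ParameterizedMolecule
        empty = ComplexStructure(receptor=cplx.receptor,
                                 ligand=ParameterizedMolecule([], []))
        with pytest.raises(ValueError):
            compute_descriptors(empty)

    def test_composition_matches_individual_terms(self):
        cplx = random_complex(n_rec=10, n_lig=6, seed=31)
        cfg = TermConfig()
        model = DielectricModel()
        vec = compute_descriptors(cplx, cfg, model)
        assert vec.E_coul == coulomb_term(cplx, model, cfg)
        assert vec.E_vdW == vdw_term(cplx, cfg)
        assert vec.E_lipo == lipophilic_term(cplx, cfg)
        assert vec.E_entropy == torsional_entropy_term(cplx, cfg)
        assert vec.E_polar_solv == polar_solvation_term(cplx, cfg)
        assert vec.E_np_solv == nonpolar_solvation_term(cplx, cfg)

    def test_deterministic(self):
        cplx = random_complex(seed=37)
        v1 = compute_descriptors(cplx)
        v2 = compute_descriptors(cplx)
        assert v1 == v2

    def test_one_solv_mode(self):
        cplx = random_complex(seed=41)
        vec = compute_descriptors(cplx, solvation="one_solv")
        assert vec.oneSolv is not None
        assert vec.E_polar_solv is None
        assert "oneSolv" in vec.as_dict()
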