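import numpy as np
import pytest

from pepbind.energetics import (
    COULOMB_CONSTANT,
    EnergyBreakdown,
    PartitionError,
    PBSettings,
    SingularityError,
    binding_energy,
    coulomb_energy,
    lj_energy,
    lj_matrix,
    nonpolar_solvation,
    per_residue_decomposition,
    sasa_areas,
)
from pepbind.energetics.pb import debye_kappa2, reaction_field_energy
from pepbind.ensemble import Ensemble
from pepbind.forcefield import ParamTable, assign_parameters
from pepbind.structures import Atom, Residue, Structure
from pepbind.synthetic import EnsembleSpec, make_ensemble, make_toy_complex

BORN_RADIUS = 2.0


def born_energy(q=1.0, a=BORN_RADIUS, eps=80.0):
    return -0.5 * COULOMB_CONSTANT * (1.0 - 1.0 / eps) * q * q / a


def zero_charge_table():
    """Neutral one-element table: isolates LJ + SASA terms."""
    return ParamTable({
        "version": 0,
        "lj_by_element": {"C": {"rmin_half": 1.908, "epsilon": 0.086}},
        "solv_radius_by_element": {"C": 1.70},
        "fallback_charges": {"C": 0.0},
        "formal_charges": {"ALA": 0},
        "backbone_charges": {},
        "sidechain_charges": {"ALA": {}},
    })


class TestCoulomb:
    def test_hand_arithmetic(self):
        # k*q1*q2/r with k = 332.0637 and r chosen to give exactly 100
        e = coulomb_energy(
            np.array([[0.0, 0.0, 0.0]]), np.array([1.0]),
            np.array([[3.320637, 0.0, 0.0]]), np.array([1.0]), eps=1.0,
        )
        assert e == pytest.approx(100.0, abs=1e-10)

    def test_empty_set(self):
        e = coulomb_energy(np.zeros((0, 3)), np.array([]),
                           np.array([[1.0, 0, 0]]), np.array([1.0]))
        assert e == 0.0

    def test_eps_scaling(self):
        a = (np.array([[0.0, 0, 0]]), np.array([1.0]))
        b = (np.array([[3.0, 0, 0]]), np.array([-1.0]))
        assert coulomb_energy(*a, *b, eps=2.0) == pytest.approx(
            coulomb_energy(*a, *b, eps=1.0) / 2.0
        )

    def test_coincident_atoms_raise(self):
        with pytest.raises(SingularityError):
            coulomb_energy(np.zeros((1, 3)), np.array([1.0]),
                           np.zeros((1, 3)), np.array([1.0]))


class TestLennardJones:
    def test_minimum_identity(self):
        e1, e2 = 0.086, 0.21
        rh1, rh2 = 1.9, 1.7
        e = lj_energy(np.array([[0.0, 0, 0]]), [rh1], [e1],
                      np.array([[rh1 + rh2, 0, 0]]), [rh2], [e2])
        assert e == pytest.approx(-np.sqrt(e1 * e2), abs=1e-12)

    def test_zero_crossing(self):
        rmin = 3.6
        r0 = rmin / 2.0 ** (1.0 / 6.0)
        e = lj_energy(np.array([[0.0, 0, 0]]), [1.8], [0.1],
                      np.array([[r0, 0, 0]]), [1.8], [0.1])
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_matches_pair_enumeration(self):
        rng = np.random.default_rng(0)
        xa = rng.normal(size=(3, 3)) * 3.0
        xb = rng.normal(size=(2, 3)) * 3.0 + 8.0
        rha, rea = np.array([1.9, 1.7, 1.8]), np.array([0.086, 0.21, 0.17])
        rhb, reb = np.array([1.66, 2.0]), np.array([0.21, 0.25])
        total = lj_energy(xa, rha, rea, xb, rhb, reb)
        brute = 0.0
        for i in range(3):
            for j in range(2):
                r = np.linalg.norm(xa[i] - xb[j])
                rmin = rha[i] + rhb[j]
                epsij = np.sqrt(rea[i] * reb[j])
                brute += epsij * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
        assert total == pytest.approx(brute, abs=1e-10)


class TestSasa:
    def test_single_atom_closed_form(self):
        res = sasa_areas(np.zeros((1, 3)), np.array([1.7]), probe=1.4, n_points=240)
        assert res.total == pytest.approx(4 * np.pi * 3.1**2, rel=0.01)

    def test_no_occlusion_when_far(self):
        radii = np.array([1.7, 1.5])
        sep = radii.sum() + 2 * 1.4 + 0.5
        res = sasa_areas(np.array([[0.0, 0, 0], [sep, 0, 0]]), radii)
        isolated = sum(
            sasa_areas(np.zeros((1, 3)), np.array([r])).total for r in radii
        )
        assert res.total == pytest.approx(isolated, rel=1e-9)

    def test_fully_buried_atom(self):
        centers = [np.zeros(3)]
        radii = [1.7]
        for axis in range(3):
            for sign in (-1, 1):
                c = np.zeros(3)
                c[axis] = sign * 2.2
                centers.append(c)
                radii.append(2.4)
        res = sasa_areas(np.array(centers), np.array(radii))
        assert res.per_atom[0] == 0.0

    def test_monotone_under_approach(self):
        radii = np.array([1.7, 1.7])
        totals = [
            sasa_areas(np.array([[0.0, 0, 0], [d, 0, 0]]), radii).total
            for d in (6.0, 5.0, 4.0, 3.0, 2.0)
        ]
        assert all(a >= b for a, b in zip(totals, totals[1:]))

    def test_min_points_enforced(self):
        with pytest.raises(ValueError):
            sasa_areas(np.zeros((1, 3)), np.array([1.7]), n_points=50)


class TestNonpolar:
    def test_intercept(self):
        assert nonpolar_solvation(0.0) == pytest.approx(0.92)

    def test_arithmetic(self):
        assert nonpolar_solvation(1000.0) == pytest.approx(6.34)

    def test_linearity(self):
        s = 734.2
        g = nonpolar_solvation
        assert g(2 * s) - g(s) == pytest.approx(0.00542 * s, abs=1e-12)


class TestPoissonBoltzmann:
    def test_born_sphere_convergence(self):
        errs = []
        for h in (0.5, 0.25):
            e, _ = reaction_field_energy(
                np.zeros((1, 3)), np.array([1.0]), np.array([BORN_RADIUS]),
                eps_in=1.0, eps_out=80.0, ionic_strength=0.0,
                spacing=h, margin=8.0,
            )
            errs.append(abs(e - born_energy()) / abs(born_energy()))
        assert errs[1] < 0.05
        assert errs[1] < errs[0]  # at least linear order in spacing

    def test_zero_charges(self):
        e, per_atom = reaction_field_energy(
            np.zeros((2, 3)) + np.array([[0.0, 0, 0], [4.0, 0, 0]]),
            np.zeros(2), np.array([1.7, 1.7]),
            eps_in=1.0, eps_out=80.0, ionic_strength=0.0, spacing=0.5, margin=6.0,
        )
        assert e == 0.0 and np.all(per_atom == 0.0)

    def test_no_dielectric_contrast(self):
        e, _ = reaction_field_energy(
            np.zeros((1, 3)), np.array([1.0]), np.array([2.0]),
            eps_in=1.0, eps_out=1.0, ionic_strength=0.0, spacing=0.5, margin=6.0,
        )
        assert e == pytest.approx(0.0, abs=1e-6)

    def test_salt_strengthens_screening(self):
        kw = dict(eps_in=1.0, eps_out=80.0, spacing=0.5, margin=8.0)
        coords = np.zeros((1, 3))
        q, r = np.array([1.0]), np.array([2.0])
        e_nosalt, _ = reaction_field_energy(coords, q, r, ionic_strength=0.0, **kw)
        e_salt, _ = reaction_field_energy(coords, q, r, ionic_strength=0.15, **kw)
        assert e_salt < e_nosalt

    def test_debye_length(self):
        kappa2 = debye_kappa2(0.15, 80.0, 298.15)
        assert 1.0 / np.sqrt(kappa2) == pytest.approx(7.9, abs=0.3)


class TestEnergyBreakdown:
    def test_identities(self):
        bd = EnergyBreakdown.from_components(-33.51, -88.74, 80.73, -9.28)
        assert bd.e_mm == pytest.approx(bd.e_ele + bd.e_vdw + bd.e_int)
        assert bd.g_solv == pytest.approx(bd.g_pb + bd.g_nonp)
        assert bd.g_bind == pytest.approx(bd.e_mm + bd.g_solv)
        assert bd.e_int == 0.0

    def test_entropy_term_optional(self):
        bd = EnergyBreakdown.from_components(-1.0, -2.0, 3.0, -0.5, ts_term=1.5)
        assert bd.g_bind == pytest.approx(-1.0 - 2.0 + 3.0 - 0.5 + 1.5)


def _two_atom_chains(separation=4.0):
    def chain(cid, z):
        res = Residue(cid, 1, "ALA", [
            Atom(1, "CA", "C", [0.0, 0.0, z]),
            Atom(2, "CB", "C", [1.5, 0.0, z]),
        ])
        return (cid, [res])

    return Structure(chains=[chain("A", 0.0), chain("B", separation)])


class TestBindingEnergy:
    def test_lj_only_hand_assembled(self):
        # neutral system: g_bind must equal the LJ cross term plus
        # (gamma * dSASA - beta); the -beta survives the state subtraction
        s = _two_atom_chains()
        table = zero_charge_table()
        param, _ = assign_parameters(s, table)
        ens = Ensemble(topology=param, frames=param.coords()[None, :, :])
        settings = PBSettings(grid_spacing=0.8, box_margin=5.0)
        bd = binding_energy(ens, ["A"], ["B"], settings)

        coords = param.coords()
        rh = np.full(2, 1.908)
        le = np.full(2, 0.086)
        rad = np.full(2, 1.70)
        lj = lj_energy(coords[:2], rh, le, coords[2:], rh, le)
        s_c = sasa_areas(coords, np.full(4, 1.70)).total
        s_r = sasa_areas(coords[:2], rad).total
        s_l = sasa_areas(coords[2:], rad).total
        expected = lj + settings.gamma * (s_c - s_r - s_l) - settings.beta
        assert bd.e_ele == 0.0
        assert bd.g_pb == 0.0
        assert bd.g_bind == pytest.approx(expected, abs=1e-10)

    def test_identities_on_toy(self, toy_ensemble, fast_pb_settings):
        bd = binding_energy(toy_ensemble, ["A"], ["B"], fast_pb_settings)
        assert bd.e_mm == pytest.approx(bd.e_ele + bd.e_vdw)
        assert bd.g_solv == pytest.approx(bd.g_pb + bd.g_nonp)
        assert bd.g_bind == pytest.approx(bd.e_mm + bd.g_solv)
        assert set(bd.sem) == {"e_ele", "e_vdw", "g_pb", "g_nonp"}

    def test_single_frame_equals_framewise(self, toy_complex, gas_settings):
        ens1 = make_ensemble(toy_complex, EnsembleSpec(n_frames=1, per_atom_sigma=0.0))
        bd1 = binding_energy(ens1, ["A"], ["B"], gas_settings)
        ens3 = Ensemble(topology=toy_complex,
                        frames=np.repeat(ens1.frames, 3, axis=0))
        bd3 = binding_energy(ens3, ["A"], ["B"], gas_settings)
        assert bd3.g_bind == pytest.approx(bd1.g_bind, abs=1e-12)
        assert bd3.sem["e_ele"] == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance_of_gas_terms(self, toy_complex, gas_settings):
        ens = make_ensemble(toy_complex, EnsembleSpec(n_frames=1, per_atom_sigma=0.0))
        bd = binding_energy(ens, ["A"], ["B"], gas_settings)
        theta = 0.7
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ])
        moved = Ensemble(topology=toy_complex,
                         frames=ens.frames @ rot.T + np.array([10.0, -3.0, 2.0]))
        bd_m = binding_energy(moved, ["A"], ["B"], gas_settings)
        assert bd_m.e_ele == pytest.approx(bd.e_ele, abs=1e-8)
        assert bd_m.e_vdw == pytest.approx(bd.e_vdw, abs=1e-8)

    def test_moving_one_partner_changes_terms(self, toy_complex, gas_settings):
        ens = make_ensemble(toy_complex, EnsembleSpec(n_frames=1, per_atom_sigma=0.0))
        bd = binding_energy(ens, ["A"], ["B"], gas_settings)
        shifted = ens.frames.copy()
        idx_b = toy_complex.select(chains=["B"], include_hetero=True)
        shifted[:, idx_b, 2] -= 3.0
        bd_s = binding_energy(
            Ensemble(topology=toy_complex, frames=shifted), ["A"], ["B"], gas_settings
        )
        assert bd_s.e_vdw != pytest.approx(bd.e_vdw, abs=1e-6)

    def test_partition_errors(self, toy_ensemble, gas_settings):
        with pytest.raises(PartitionError):
            binding_energy(toy_ensemble, ["A", "B"], ["B"], gas_settings)
        with pytest.raises(PartitionError):
            binding_energy(toy_ensemble, ["A"], [], gas_settings)


class TestDecomposition:
    def test_conserves_totals(self, toy_ensemble, fast_pb_settings):
        bd = binding_energy(toy_ensemble, ["A"], ["B"], fast_pb_settings)
        contribs = per_residue_decomposition(
            toy_ensemble, ["A"], ["B"], fast_pb_settings
        )
        assert sum(c.e_ele for c in contribs) == pytest.approx(bd.e_ele, abs=1e-6)
        assert sum(c.e_vdw for c in contribs) == pytest.approx(bd.e_vdw, abs=1e-6)
        assert sum(c.g_nonp_share for c in contribs) == pytest.approx(bd.g_nonp, abs=1e-6)
        assert sum(c.total for c in contribs) == pytest.approx(bd.g_bind, abs=1e-6)

    def test_symmetric_geometry_equal_shares(self):
        # beyond occlusion range: dSASA vanishes atom-by-atom, so the split
        # is exactly symmetric (quadrature points are not mirror-symmetric)
        s = _two_atom_chains(separation=8.0)
        param, _ = assign_parameters(s, zero_charge_table())
        ens = Ensemble(topology=param, frames=param.coords()[None, :, :])
        settings = PBSettings(include_polar=False)
        contribs = per_residue_decomposition(ens, ["A"], ["B"], settings)
        assert len(contribs) == 2
        assert contribs[0].total == pytest.approx(contribs[1].total, abs=1e-9)

    def test_single_charged_pair_matches_direct(self):
        # one +1/-1 atom per chain: the decomposition must reproduce the
        # plain pairwise Coulomb energy, split half-and-half
        table = ParamTable({
            "version": 0,
            "lj_by_element": {"C": {"rmin_half": 1.9, "epsilon": 0.0}},
            "solv_radius_by_element": {"C": 1.7},
            "fallback_charges": {},
            "formal_charges": {"LYS": 1, "ASP": -1},
            "backbone_charges": {},
            "sidechain_charges": {"LYS": {"CB": 1.0}, "ASP": {"CB": -1.0}},
        })
        r = 6.0
        s = Structure(chains=[
            ("A", [Residue("A", 1, "LYS", [Atom(1, "CB", "C", [0.0, 0, 0])])]),
            ("B", [Residue("B", 1, "ASP", [Atom(2, "CB", "C", [r, 0, 0])])]),
        ])
        param, _ = assign_parameters(s, table)
        ens = Ensemble(topology=param, frames=param.coords()[None, :, :])
        contribs = per_residue_decomposition(
            ens, ["A"], ["B"], PBSettings(include_polar=False)
        )
        direct = COULOMB_CONSTANT * 1.0 * -1.0 / r
        assert sum(c.e_ele for c in contribs) == pytest.approx(direct, abs=1e-10)
        assert contribs[0].e_ele == pytest.approx(direct / 2, abs=1e-10)

    def test_zero_charge_hook_kills_electrostatic_share(self, toy_complex):
        param, _ = assign_parameters(toy_complex)
        for atom in param.chain("A")[1].atoms:  # the ARG residue
            atom.charge = 0.0
        ens = Ensemble(topology=param, frames=param.coords()[None, :, :])
        contribs = per_residue_decomposition(
            ens, ["A"], ["B"], PBSettings(include_polar=False)
        )
        arg = next(c for c in contribs if c.chain_id == "A" and c.res_id == 2)
        assert arg.e_ele == 0.0
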