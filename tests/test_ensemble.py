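import numpy as np
import pytest

from pepbind.ensemble import (
    DegenerateSelectionError,
    Ensemble,
    apply_transform,
    dccm,
    hydrogen_bonds,
    interface_residues,
    rmsd_series,
    rmsf,
    superpose,
)
from pepbind.structures import Atom, Residue, Structure
from pepbind.synthetic import EnsembleSpec, make_ensemble, make_toy_complex


def rotation_z(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotation_euler(a, b, c):
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rz = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    return rz @ ry @ rx


def brute_force_min_rmsd(mobile, reference, levels=4, grid=9):
    """Hierarchical Euler-angle grid search, final resolution < 1e-3 rad."""
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)

    def rmsd_at(angles):
        moved = mob_c @ rotation_euler(*angles).T
        return np.sqrt(np.mean(np.sum((moved - ref_c) ** 2, axis=1)))

    center = np.zeros(3)
    width = np.pi
    best = (np.inf, center)
    for _level in range(levels):
        axes = [np.linspace(c - width, c + width, grid) for c in center]
        for a in axes[0]:
            for b in axes[1]:
                for c in axes[2]:
                    v = rmsd_at((a, b, c))
                    if v < best[0]:
                        best = (v, np.array([a, b, c]))
        center = best[1]
        width = 2 * width / (grid - 1)
    return best[0]


class TestSuperpose:
    def test_pure_translation(self):
        ref = np.random.default_rng(0).normal(size=(10, 3))
        _, _, rmsd = superpose(ref + np.array([5.0, 0.0, 0.0]), ref)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_pure_rotation(self):
        ref = np.random.default_rng(1).normal(size=(10, 3))
        mob = ref @ rotation_z(np.pi / 2).T
        _, _, rmsd = superpose(mob, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_transform_reproduces_rmsd(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(8, 3))
        mob = ref @ rotation_euler(0.3, -0.8, 1.1).T + rng.normal(size=(8, 3)) * 0.1
        rot, tr, rmsd = superpose(mob, ref)
        moved = apply_transform(mob, rot, tr)
        direct = np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1)))
        assert direct == pytest.approx(rmsd, abs=1e-8)

    def test_matches_rotation_grid_oracle(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(4, 3)) * 2.0
        mob = rng.normal(size=(4, 3)) * 2.0
        _, _, kabsch = superpose(mob, ref)
        oracle = brute_force_min_rmsd(mob, ref)
        assert kabsch == pytest.approx(oracle, abs=1e-3)

    def test_no_reflection(self):
        ref = np.random.default_rng(4).normal(size=(6, 3))
        rot, _, _ = superpose(ref * np.array([1.0, 1.0, -1.0]), ref)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_atoms(self):
        with pytest.raises(DegenerateSelectionError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear(self):
        line = np.outer(np.arange(5.0), np.array([1.0, 0.0, 0.0]))
        with pytest.raises(DegenerateSelectionError):
            superpose(line, line)


class TestRMSD:
    def test_static_all_zero(self, toy_complex):
        ens = make_ensemble(toy_complex, EnsembleSpec(n_frames=4, per_atom_sigma=0.0))
        assert np.allclose(rmsd_series(ens).values, 0.0)

    def test_single_frame(self, toy_complex):
        ens = make_ensemble(toy_complex, EnsembleSpec(n_frames=1, per_atom_sigma=0.0))
        series = rmsd_series(ens)
        assert len(series.values) == 1
        assert series.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_noise_level_against_theory(self):
        # Monte-Carlo oracle: for isotropic sigma noise vs a clean reference,
        # E[rmsd] ~ sigma*sqrt(3)*sqrt(1 - 2/N) after the 6-DOF fit.
        sigma, seed = 0.3, 17
        s = make_toy_complex(6, 6, 5.0, seed=1)
        ens = make_ensemble(
            s,
            EnsembleSpec(n_frames=400, per_atom_sigma=sigma, seed=seed,
                         first_frame_is_reference=True),
        )
        sel = s.select(heavy_only=True)
        n_sel = len(sel)
        expected = sigma * np.sqrt(3.0) * np.sqrt(1.0 - 2.0 / n_sel)
        measured = rmsd_series(ens).values[1:].mean()
        assert measured == pytest.approx(expected, rel=0.10)

    def test_rigid_motion_invariance(self, toy_complex):
        ens = make_ensemble(
            toy_complex, EnsembleSpec(n_frames=5, per_atom_sigma=0.2, seed=2)
        )
        rot = rotation_euler(0.2, 0.5, -0.4)
        moved = Ensemble(
            topology=toy_complex,
            frames=np.einsum("fij,kj->fik", ens.frames, rot) + np.array([3.0, -2.0, 1.0]),
        )
        np.testing.assert_allclose(
            rmsd_series(moved).values, rmsd_series(ens).values, atol=1e-8
        )

    def test_trailing_mean(self, toy_complex):
        ens = make_ensemble(
            toy_complex, EnsembleSpec(n_frames=8, per_atom_sigma=0.2, seed=3)
        )
        series = rmsd_series(ens, trailing_fraction=0.25)
        assert series.trailing_mean == pytest.approx(series.values[-2:].mean())


class TestRMSF:
    def test_static_zero(self, toy_complex):
        ens = make_ensemble(toy_complex, EnsembleSpec(n_frames=3, per_atom_sigma=0.0))
        assert np.allclose(rmsf(ens).values, 0.0)

    def test_doubling_sigma_doubles_rmsf(self):
        s = make_toy_complex(3, 3, 6.0, seed=0)
        v = []
        for sigma in (0.2, 0.4):
            ens = make_ensemble(
                s, EnsembleSpec(n_frames=1500, per_atom_sigma=sigma, seed=4)
            )
            v.append(rmsf(ens, align=False).values.mean())
        assert v[1] / v[0] == pytest.approx(2.0, rel=0.05)


class TestInterface:
    def _pair_structure(self, distance):
        res_a = Residue("A", 1, "ALA", [Atom(1, "CB", "C", [0.0, 0.0, 0.0])])
        res_b = Residue("B", 1, "ALA", [Atom(2, "CB", "C", [distance, 0.0, 0.0])])
        return Structure(chains=[("A", [res_a]), ("B", [res_b])])

    def test_inclusive_boundary(self):
        near = interface_residues(self._pair_structure(4.9), "A", "B")
        assert near == {"A": {1}, "B": {1}}
        exact = interface_residues(self._pair_structure(5.0), "A", "B")
        assert exact["A"] == {1}

    def test_beyond_cutoff_empty(self):
        far = interface_residues(self._pair_structure(5.1), "A", "B")
        assert far == {"A": set(), "B": set()}

    def test_matches_brute_force(self):
        s = make_toy_complex(6, 6, 4.2, seed=5, seq_a="ARLSTN", seq_b="AELSKQ")
        result = interface_residues(s, "A", "B", cutoff=5.0)
        expect = {"A": set(), "B": set()}
        for res_a in s.chain("A"):
            for res_b in s.chain("B"):
                for at_a in res_a.atoms:
                    for at_b in res_b.atoms:
                        if not (at_a.is_heavy and at_b.is_heavy):
                            continue
                        if np.linalg.norm(at_a.coords - at_b.coords) <= 5.0:
                            expect["A"].add(res_a.res_id)
                            expect["B"].add(res_b.res_id)
        assert result == expect

    def test_symmetric(self):
        s = make_toy_complex(5, 7, 4.0, seed=6)
        ab = interface_residues(s, "A", "B")
        ba = interface_residues(s, "B", "A")
        assert ab == ba


class TestHydrogenBonds:
    def test_occupancy_permutation_invariant(self):
        from pepbind.synthetic import make_hbond_ensemble

        ens = make_hbond_ensemble(0.4, 50, seed=2)
        perm = np.random.default_rng(0).permutation(50)
        shuffled = Ensemble(topology=ens.topology, frames=ens.frames[perm])
        occ = lambda e: {
            (r.donor, r.acceptor): r.occupancy for r in hydrogen_bonds(e)
        }
        assert occ(ens) == occ(shuffled)

    def test_all_frames_bonded(self):
        from pepbind.synthetic import make_hbond_ensemble

        ens = make_hbond_ensemble(1.0, 30, seed=0)
        top = hydrogen_bonds(ens)[0]
        assert top.occupancy == 100.0

    def test_sorted_descending(self):
        from pepbind.synthetic import make_hbond_ensemble

        records = hydrogen_bonds(make_hbond_ensemble(0.6, 40, seed=1))
        occs = [r.occupancy for r in records]
        assert occs == sorted(occs, reverse=True)


class TestDCCM:
    def _two_atom_ensemble(self, sign, n_frames=300, seed=0):
        res = Residue("A", 1, "ALA", [
            Atom(1, "CA", "C", [0.0, 0.0, 0.0]),
            Atom(2, "CB", "C", [5.0, 0.0, 0.0]),
        ])
        s = Structure(chains=[("A", [res])])
        rng = np.random.default_rng(seed)
        disp = rng.normal(size=(n_frames, 1, 3))
        frames = np.repeat(s.coords()[None], n_frames, axis=0)
        frames[:, 0, :] += disp[:, 0, :]
        frames[:, 1, :] += sign * disp[:, 0, :]
        return Ensemble(topology=s, frames=frames)

    def test_shared_displacement_plus_one(self):
        c = dccm(self._two_atom_ensemble(+1))
        assert c[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_mirrored_minus_one(self):
        c = dccm(self._two_atom_ensemble(-1))
        assert c[0, 1] == pytest.approx(-1.0, abs=1e-9)

    def test_independent_atoms_near_zero(self):
        s = make_toy_complex(2, 2, 8.0, seed=0)
        ens = make_ensemble(
            s, EnsembleSpec(n_frames=5000, per_atom_sigma=0.5, seed=9)
        )
        c = dccm(ens)
        off_diag = c[~np.eye(len(c), dtype=bool)]
        assert np.abs(off_diag).max() < 0.05

    def test_symmetry_and_bounds(self, toy_ensemble):
        c = dccm(toy_ensemble)
        np.testing.assert_allclose(c, c.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(c), 1.0)
        assert c.min() >= -1.0 and c.max() <= 1.0
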