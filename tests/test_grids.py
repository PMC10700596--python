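import numpy as np
import pytest

from aniondock.grids import (
    COULOMB_K,
    DielectricMap,
    Lattice,
    assign_membrane_dielectric,
    build_desolvation_grid,
    build_vdw_grid,
    discrete_gauss_flux,
    generate_matching_spheres,
    occlusion_at_point,
    solve_potential_grid,
)
from aniondock.receptor import Atom, ReceptorModel


def _single_atom(radius=1.5, charge=0.0):
    return ReceptorModel([Atom("C", (0.0, 0.0, 0.0), radius, charge)])


class TestDielectricMap:
    def test_surface_extension_threshold(self):
        """A node at atom_radius + extension is inside the low-dielectric
        region; one just beyond is solvent."""
        # nodes along x at 0.1 Å pitch: exact nodes at 3.3 and 3.5
        lat = Lattice(origin=(-8.0, -8.0, -8.0), spacing=0.1, shape=(161, 161, 161))
        die = assign_membrane_dielectric(
            _single_atom(radius=1.5), None, lat, surface_extension=1.9
        )
        ix = lambda v: int(round((v + 8.0) / 0.1))
        c = ix(0.0)
        assert die.values[ix(3.3), c, c] == die.eps_low
        assert die.values[ix(3.5), c, c] == die.eps_high

    def test_distant_lipid_discarded_by_cutoff(self):
        """Lipid atoms beyond the 17 Å membrane ring contribute no
        low-dielectric volume."""
        lat = Lattice(origin=(-5.0, -5.0, -5.0), spacing=0.5, shape=(101, 101, 101))
        far_lipid = np.array([[20.0, 0.0, 0.0]])
        with_far = assign_membrane_dielectric(_single_atom(), far_lipid, lat)
        without = assign_membrane_dielectric(_single_atom(), None, lat)
        assert np.array_equal(with_far.values, without.values)

    def test_near_lipid_adds_low_dielectric(self):
        lat = Lattice(origin=(-5.0, -5.0, -5.0), spacing=0.5, shape=(41, 41, 41))
        near_lipid = np.array([[5.0, 0.0, 0.0]])
        with_near = assign_membrane_dielectric(_single_atom(), near_lipid, lat)
        without = assign_membrane_dielectric(_single_atom(), None, lat)
        assert (with_near.values == with_near.eps_low).sum() > (
            without.values == without.eps_low
        ).sum()

    def test_matches_brute_force_oracle(self, random_receptor, toy_complex):
        """Classification equals an exhaustive per-node distance check."""
        lat = Lattice(origin=(-8.0, -8.0, -8.0), spacing=0.8, shape=(21, 21, 21))
        lipid = toy_complex.lipid_atoms
        die = assign_membrane_dielectric(
            random_receptor, lipid, lat, lipid_cutoff=17.0, surface_extension=1.9
        )
        # oracle: plain python loops
        rc = random_receptor.coords
        rr = random_receptor.radii
        retained = [
            p for p in lipid
            if min(np.linalg.norm(p - a) for a in rc) <= 17.0
        ]
        ax, ay, az = lat.axes()
        for i in range(0, 21, 4):
            for j in range(0, 21, 4):
                for k in range(0, 21, 4):
                    p = np.array([ax[i], ay[j], az[k]])
                    low = any(
                        np.linalg.norm(p - rc[m]) <= rr[m] + 1.9
                        for m in range(len(rc))
                    ) or any(np.linalg.norm(p - q) <= 1.9 for q in retained)
                    expected = die.eps_low if low else die.eps_high
                    assert die.values[i, j, k] == expected

    def test_empty_receptor_rejected(self):
        lat = Lattice(origin=(-5.0, -5.0, -5.0), spacing=1.0, shape=(11, 11, 11))
        with pytest.raises(ValueError, match="empty"):
            assign_membrane_dielectric(ReceptorModel([]), None, lat)

    def test_lattice_must_cover_receptor(self):
        lat = Lattice(origin=(5.0, 5.0, 5.0), spacing=1.0, shape=(5, 5, 5))
        with pytest.raises(ValueError, match="cover"):
            assign_membrane_dielectric(_single_atom(), None, lat)


class TestPotentialSolver:
    def test_no_charges_gives_zero(self):
        lat = Lattice(origin=(-5.0, -5.0, -5.0), spacing=0.5, shape=(21, 21, 21))
        die = DielectricMap(lat, np.full(lat.shape, 78.0), 2.0, 78.0)
        phi = solve_potential_grid(_single_atom(charge=0.0), die)
        assert np.allclose(phi, 0.0)

    def test_uniform_dielectric_matches_coulomb(self):
        """Point charge in uniform eps=2: phi within 5% of 332.063/(2r)
        between 3 grid spacings and half the box."""
        n, h = 41, 0.5
        lat = Lattice(origin=(-10.0, -10.0, -10.0), spacing=h, shape=(n, n, n))
        die = DielectricMap(lat, np.full(lat.shape, 2.0), 2.0, 2.0)
        phi = solve_potential_grid(_single_atom(charge=1.0), die, tol=1e-8)
        c = n // 2
        for r in (1.5, 2.5, 3.5, 5.0):
            i = int(round((r + 10.0) / h))
            exact = COULOMB_K / (2.0 * r)
            assert phi[i, c, c] == pytest.approx(exact, rel=0.05)

    def test_low_dielectric_slab_enhances_potential(self):
        """A +1 charge 4 Å above a low-dielectric half-space: the image
        charge raises |phi| above the uniform high-dielectric value."""
        n, h = 33, 0.5
        lat = Lattice(origin=(-8.0, -8.0, -8.0), spacing=h, shape=(n, n, n))
        rec = ReceptorModel([Atom("C", (0.0, 0.0, 4.0), 1.5, 1.0)])
        eps_slab = np.full(lat.shape, 78.0)
        ax, ay, az = lat.axes()
        eps_slab[:, :, az <= 0.0] = 2.0
        die_slab = DielectricMap(lat, eps_slab, 2.0, 78.0)
        die_unif = DielectricMap(lat, np.full(lat.shape, 78.0), 2.0, 78.0)
        phi_slab = solve_potential_grid(rec, die_slab, tol=1e-8)
        phi_unif = solve_potential_grid(rec, die_unif, tol=1e-8)
        c = n // 2
        iz = int(round((6.0 + 8.0) / h))  # 2 Å above the charge
        assert abs(phi_slab[c, c, iz]) > abs(phi_unif[c, c, iz])

    def test_discrete_gauss_law(self):
        """Flux of eps*grad(phi) through a box around the charge equals
        -4*pi*q within 3%."""
        n, h = 33, 0.5
        lat = Lattice(origin=(-8.0, -8.0, -8.0), spacing=h, shape=(n, n, n))
        die = DielectricMap(lat, np.full(lat.shape, 4.0), 4.0, 4.0)
        phi = solve_potential_grid(_single_atom(charge=1.0), die, tol=1e-10)
        flux = discrete_gauss_flux(phi, die, (4, 4, 4), (28, 28, 28))
        assert flux == pytest.approx(-4.0 * np.pi, rel=0.03)

    def test_residual_decreases_with_tighter_tolerance(self):
        n, h = 21, 0.5
        lat = Lattice(origin=(-5.0, -5.0, -5.0), spacing=h, shape=(n, n, n))
        die = DielectricMap(lat, np.full(lat.shape, 2.0), 2.0, 2.0)
        phi_loose = solve_potential_grid(_single_atom(charge=1.0), die, tol=1e-3)
        phi_tight = solve_potential_grid(_single_atom(charge=1.0), die, tol=1e-10)
        # loose solution is close to, but measurably different from, tight
        assert not np.allclose(phi_loose, phi_tight, atol=0)
        assert np.allclose(phi_loose, phi_tight, rtol=0.05, atol=1e-3)


class TestVdwGrid:
    def test_empty_receptor_zero_fields(self):
        lat = Lattice(origin=(-2.0, -2.0, -2.0), spacing=1.0, shape=(5, 5, 5))
        va, vb = build_vdw_grid(ReceptorModel([]), lattice=lat)
        assert np.all(va == 0) and np.all(vb == 0)

    def test_missing_element_parameters(self):
        lat = Lattice(origin=(-2.0, -2.0, -2.0), spacing=1.0, shape=(5, 5, 5))
        rec = ReceptorModel([Atom("Zz", (0, 0, 0), 1.5, 0.0)])
        with pytest.raises(KeyError, match="Zz"):
            build_vdw_grid(rec, lattice=lat)

    def test_pair_minimum_reproduced(self):
        """Probe with matching coefficients at the pair's minimum-energy
        distance scores within 2% of the closed-form 6-12 minimum."""
        A, B = 1043080.0, 675.61
        params = {"C": (A, B)}
        a_pair, b_pair = A, B  # sqrtA_i*sqrtA_j = A for identical atoms
        r_min = (2.0 * a_pair / b_pair) ** (1.0 / 6.0)
        e_min = -(b_pair**2) / (4.0 * a_pair)
        # lattice engineered so the probe point is an exact node
        h = r_min / 8.0
        lat = Lattice(origin=(-4 * h, -4 * h, -4 * h), spacing=h, shape=(17, 17, 17))
        va, vb = build_vdw_grid(_single_atom(), params, lat)
        probe = np.array([[r_min, 0.0, 0.0]])
        e = np.sqrt(A) * lat.interpolate(va, probe)[0] - np.sqrt(B) * lat.interpolate(
            vb, probe
        )[0]
        assert e == pytest.approx(e_min, rel=0.02)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(7)
        atoms = [
            Atom("C", tuple(rng.uniform(-3, 3, 3)), 1.7, 0.0) for _ in range(10)
        ]
        rec = ReceptorModel(atoms)
        lat = Lattice(origin=(-5.0, -5.0, -5.0), spacing=1.0, shape=(11, 11, 11))
        va, vb = build_vdw_grid(rec, lattice=lat)
        from aniondock.grids import DEFAULT_VDW_PARAMS, VDW_R_FLOOR

        sA = np.sqrt(DEFAULT_VDW_PARAMS["C"][0])
        sB = np.sqrt(DEFAULT_VDW_PARAMS["C"][1])
        ax, ay, az = lat.axes()
        for idx in [(0, 0, 0), (5, 5, 5), (3, 7, 2), (10, 10, 10)]:
            p = np.array([ax[idx[0]], ay[idx[1]], az[idx[2]]])
            r = np.maximum(
                [np.linalg.norm(p - np.asarray(a.coords)) for a in atoms],
                VDW_R_FLOOR,
            )
            assert va[idx] == pytest.approx(np.sum(sA / r**12), rel=1e-10)
            assert vb[idx] == pytest.approx(np.sum(sB / r**6), rel=1e-10)


class TestDesolvationGrid:
    def test_bulk_solvent_and_buried_limits(self):
        # one small atom in a big box: far corner fully solvated
        lat = Lattice(origin=(-8.0, -8.0, -8.0), spacing=2.0, shape=(9, 9, 9))
        occ = build_desolvation_grid(
            _single_atom(), None, lat, shell_radius=2.0, n_samples=128
        )
        assert occ[0, 0, 0] == 0.0
        # dense block of large atoms: center fully occluded
        rng = np.random.default_rng(3)
        block = ReceptorModel(
            [
                Atom("C", (x, y, z), 3.0, 0.0)
                for x in (-3.0, 0.0, 3.0)
                for y in (-3.0, 0.0, 3.0)
                for z in (-3.0, 0.0, 3.0)
            ]
        )
        occ2 = build_desolvation_grid(
            block, None, lat, shell_radius=2.0, n_samples=128
        )
        assert occ2[4, 4, 4] == 1.0

    def test_mid_surface_matches_monte_carlo_oracle(self):
        """Occlusion near the surface of a sphere agrees with a dense
        independent Monte-Carlo estimate within 0.02."""
        rec = _single_atom(radius=3.0)
        lat = Lattice(origin=(-4.0, -4.0, -4.0), spacing=1.0, shape=(9, 9, 9))
        occ = build_desolvation_grid(
            rec, None, lat, volume_extension=0.5, shell_radius=3.0, n_samples=4096
        )
        # node at (3, 0, 0): just inside the extended surface (r=3.5)
        oracle = occlusion_at_point(
            np.array([3.0, 0.0, 0.0]),
            rec.coords,
            rec.radii + 0.5,
            shell_radius=3.0,
            n_samples=100_000,
            seed=99,
        )
        assert occ[7, 4, 4] == pytest.approx(oracle, abs=0.02)

    def test_lipid_volume_occludes(self, toy_complex):
        lat = Lattice(origin=(-6.0, -6.0, -6.0), spacing=2.0, shape=(7, 7, 7))
        with_lipid = build_desolvation_grid(
            toy_complex.receptor, toy_complex.lipid_atoms, lat,
            shell_radius=4.0, n_samples=64,
        )
        without = build_desolvation_grid(
            toy_complex.receptor, None, lat, shell_radius=4.0, n_samples=64
        )
        assert with_lipid.sum() >= without.sum()


class TestMatchingSpheres:
    def test_all_atoms_become_spheres_under_cap(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-5, 5, (10, 3))
        spheres = generate_matching_spheres(pts, max_spheres=45, dedup_radius=0.1)
        assert len(spheres) == 10
        assert {tuple(np.round(c, 6)) for c in spheres.centers} == {
            tuple(np.round(p, 6)) for p in pts
        }

    def test_truncation_to_45(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-10, 10, (50, 3))
        spheres = generate_matching_spheres(pts, max_spheres=45, dedup_radius=0.1)
        assert len(spheres) == 45
        # kept centers are the 45 closest to the centroid
        centroid = pts.mean(axis=0)
        dists = np.sort(np.linalg.norm(pts - centroid, axis=1))
        kept = np.linalg.norm(spheres.centers - centroid, axis=1)
        assert kept.max() <= dists[44] + 1e-9

    def test_deduplication(self):
        pts = np.array([[0.0, 0.0, 0.0], [0.1, 0.0, 0.0], [5.0, 0.0, 0.0]])
        spheres = generate_matching_spheres(pts, dedup_radius=0.5)
        assert len(spheres) == 2

    def test_too_few_atoms(self):
        with pytest.raises(ValueError, match="3 reference atoms"):
            generate_matching_spheres(np.zeros((2, 3)))


class TestTranslationEquivariance:
    def test_fields_unchanged_under_joint_shift(self, random_receptor):
        shift = np.array([3.25, -1.5, 0.75])
        lat0 = Lattice(origin=(-8.0, -8.0, -8.0), spacing=1.0, shape=(17, 17, 17))
        lat1 = Lattice(
            origin=tuple(np.asarray(lat0.origin) + shift), spacing=1.0,
            shape=(17, 17, 17),
        )
        moved = random_receptor.translated(shift)
        va0, vb0 = build_vdw_grid(random_receptor, lattice=lat0)
        va1, vb1 = build_vdw_grid(moved, lattice=lat1)
        assert np.allclose(va0, va1, atol=1e-10)
        assert np.allclose(vb0, vb1, atol=1e-10)
        die0 = assign_membrane_dielectric(random_receptor, None, lat0)
        die1 = assign_membrane_dielectric(moved, None, lat1)
        assert np.array_equal(die0.values, die1.values)
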