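import itertools

import numpy as np
import pytest

from aniondock.docking import (
    DockingParams,
    LigandConformer,
    Pose,
    ScoreBreakdown,
    dock_molecule,
    orient_ligand,
    rank_library,
    score_pose,
)
from aniondock.grids import (
    DEFAULT_VDW_PARAMS,
    Lattice,
    MatchingSpheres,
    ScoringGrids,
    VDW_R_FLOOR,
)


def _conformer(coords, charges=None, desolv=None, cid="lig"):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return LigandConformer(
        conformer_id=cid,
        elements=["C"] * n,
        coords=coords,
        charges=np.zeros(n) if charges is None else np.asarray(charges, float),
        desolv=np.zeros(n) if desolv is None else np.asarray(desolv, float),
        sqrt_a=np.full(n, np.sqrt(DEFAULT_VDW_PARAMS["H"][0])),
        sqrt_b=np.full(n, np.sqrt(DEFAULT_VDW_PARAMS["H"][1])),
    )


def _flat_grids(lat, phi=0.0, va=0.0, vb=0.0, occ=0.0):
    shape = lat.shape
    return ScoringGrids(
        lat,
        np.full(shape, phi),
        np.full(shape, va),
        np.full(shape, vb),
        np.full(shape, occ),
    )


TRIANGLE = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0], [0.0, 4.0, 0.0]])


class TestOrientLigand:
    def test_congruent_triplet_found(self):
        """A ligand triangle congruent to a sphere triangle yields a pose
        superposing it to sub-0.01 Å RMSD."""
        spheres = MatchingSpheres(TRIANGLE + np.array([10.0, -2.0, 5.0]))
        conf = _conformer(TRIANGLE)
        poses = orient_ligand(conf, spheres, distance_tol=0.01)
        assert poses
        best = min(
            np.sqrt(((p.coords - spheres.centers) ** 2).sum(axis=1).mean())
            for p in poses
        )
        assert best < 0.01

    def test_zero_tolerance_incompatible_distances(self):
        spheres = MatchingSpheres(TRIANGLE * 1.3)
        conf = _conformer(TRIANGLE)
        assert orient_ligand(conf, spheres, distance_tol=0.0) == []

    def test_matches_brute_force_triplet_oracle(self):
        """Accepted (atom-triplet, sphere-triplet) pairs equal the
        exhaustive O(n^3 m^3) distance-compatibility enumeration."""
        rng = np.random.default_rng(5)
        lig = rng.uniform(0, 6, (5, 3))
        sph = rng.uniform(0, 6, (5, 3))
        tol = 0.5
        conf = _conformer(lig)
        poses = orient_ligand(
            conf, MatchingSpheres(sph), distance_tol=tol,
            max_orientations=10**6, min_triangle_area=0.1,
        )

        def area(p):
            return 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))

        expected = 0
        for i, j, k in itertools.combinations(range(5), 3):
            ta = lig[[i, j, k]]
            if area(ta) < 0.1:
                continue
            da = [
                np.linalg.norm(ta[0] - ta[1]),
                np.linalg.norm(ta[0] - ta[2]),
                np.linalg.norm(ta[1] - ta[2]),
            ]
            for a, b, c in itertools.permutations(range(5), 3):
                ts = sph[[a, b, c]]
                if area(ts) < 0.1:
                    continue
                ds = [
                    np.linalg.norm(ts[0] - ts[1]),
                    np.linalg.norm(ts[0] - ts[2]),
                    np.linalg.norm(ts[1] - ts[2]),
                ]
                if all(abs(da[t] - ds[t]) <= tol for t in range(3)):
                    expected += 1
        assert len(poses) == expected

    def test_requires_three_spheres(self):
        with pytest.raises(ValueError, match="3 matching spheres"):
            orient_ligand(_conformer(TRIANGLE), MatchingSpheres(TRIANGLE[:2]))

    def test_rotations_are_proper(self):
        spheres = MatchingSpheres(-TRIANGLE)  # mirrored target
        poses = orient_ligand(_conformer(TRIANGLE), spheres, distance_tol=0.5)
        for p in poses:
            assert np.linalg.det(p.rotation) == pytest.approx(1.0, abs=1e-6)


class TestScorePose:
    def _pose(self, conf):
        return Pose(conf.conformer_id, np.eye(3), np.zeros(3), conf.coords)

    def test_zero_charges_zero_electrostatics(self):
        lat = Lattice(origin=(-5.0, -5.0, -5.0), spacing=1.0, shape=(11, 11, 11))
        grids = _flat_grids(lat, phi=50.0)
        conf = _conformer(TRIANGLE)
        sb = score_pose(self._pose(conf), conf, grids)
        assert sb.e_elec == 0.0

    def test_fully_solvated_zero_desolvation(self):
        lat = Lattice(origin=(-5.0, -5.0, -5.0), spacing=1.0, shape=(11, 11, 11))
        grids = _flat_grids(lat, occ=0.0)
        conf = _conformer(TRIANGLE, desolv=[2.0, 2.0, 2.0])
        assert score_pose(self._pose(conf), conf, grids).e_desolv == 0.0

    def test_decomposition_sums(self):
        lat = Lattice(origin=(-5.0, -5.0, -5.0), spacing=1.0, shape=(11, 11, 11))
        grids = _flat_grids(lat, phi=-3.0, va=1e-4, vb=0.5, occ=0.5)
        conf = _conformer(TRIANGLE, charges=[-0.5, 0.2, 0.0], desolv=[1.0, 0.0, 2.0])
        sb = score_pose(self._pose(conf), conf, grids)
        assert sb.e_total == pytest.approx(sb.e_elec + sb.e_vdw + sb.e_desolv, abs=1e-12)
        assert sb.e_desolv >= 0.0

    def test_matches_gridless_oracle(self):
        """Grid-interpolated terms agree with direct pairwise computation
        within 5% on a one-receptor-atom system."""
        from aniondock.grids import (
            DielectricMap,
            assign_membrane_dielectric,
            build_desolvation_grid,
            build_vdw_grid,
            solve_potential_grid,
        )
        from aniondock.receptor import Atom, ReceptorModel
        from aniondock.grids import COULOMB_K

        rec = ReceptorModel([Atom("C", (0.0, 0.0, 0.0), 1.5, 1.0)])
        lat = Lattice(origin=(-8.0, -8.0, -8.0), spacing=0.4, shape=(41, 41, 41))
        die = DielectricMap(lat, np.full(lat.shape, 2.0), 2.0, 2.0)
        phi = solve_potential_grid(rec, die, tol=1e-8)
        va, vb = build_vdw_grid(rec, lattice=lat)
        occ = np.zeros(lat.shape)
        grids = ScoringGrids(lat, phi, va, vb, occ)
        # probe 4 Å out, plus two far spectators with no charge
        probe = np.array([[4.0, 0.0, 0.0], [6.0, 2.0, 0.0], [6.0, -2.0, 0.0]])
        conf = _conformer(probe, charges=[-1.0, 0.0, 0.0])
        sb = score_pose(self._pose(conf), conf, grids)
        # oracle: Coulomb + direct 6-12 sums
        e_elec_direct = -1.0 * COULOMB_K / (2.0 * 4.0)
        sA, sB = conf.sqrt_a[0], conf.sqrt_b[0]
        aA = np.sqrt(DEFAULT_VDW_PARAMS["C"][0])
        aB = np.sqrt(DEFAULT_VDW_PARAMS["C"][1])
        e_vdw_direct = sum(
            sA * aA / max(np.linalg.norm(p), VDW_R_FLOOR) ** 12
            - sB * aB / max(np.linalg.norm(p), VDW_R_FLOOR) ** 6
            for p in probe
        )
        assert sb.e_elec == pytest.approx(e_elec_direct, rel=0.05)
        assert sb.e_vdw == pytest.approx(e_vdw_direct, rel=0.05, abs=1e-3)

    def test_out_of_box_names_atom(self):
        lat = Lattice(origin=(-5.0, -5.0, -5.0), spacing=1.0, shape=(11, 11, 11))
        grids = _flat_grids(lat)
        coords = TRIANGLE.copy()
        coords[2] = [99.0, 0.0, 0.0]
        conf = _conformer(coords)
        with pytest.raises(ValueError, match="atom index 2"):
            score_pose(self._pose(conf), conf, grids)


class TestDockMolecule:
    def _setup(self):
        lat = Lattice(origin=(-6.0, -6.0, -6.0), spacing=1.0, shape=(13, 13, 13))
        rng = np.random.default_rng(2)
        grids = ScoringGrids(
            lat,
            rng.normal(0, 1, lat.shape),
            np.zeros(lat.shape),
            np.zeros(lat.shape),
            rng.random(lat.shape),
        )
        spheres = MatchingSpheres(
            np.array(
                [[0.0, 0.0, 0.0], [2.0, 0.0, 0.0], [0.0, 2.5, 0.0], [1.0, 1.0, 2.0]]
            )
        )
        return grids, spheres

    def test_duplicated_conformers_idempotent(self):
        grids, spheres = self._setup()
        conf = _conformer(spheres.centers[:3], charges=[0.3, -0.2, 0.1], cid="c0")
        r1 = dock_molecule([conf], grids, spheres)
        r2 = dock_molecule([conf, conf], grids, spheres)
        assert r1 is not None
        assert r1[1].e_total == pytest.approx(r2[1].e_total, abs=1e-12)

    def test_minimum_over_exhaustive_score_table(self):
        """Best score equals the minimum over every scored
        (conformer, orientation) pair."""
        grids, spheres = self._setup()
        rng = np.random.default_rng(9)
        confs = [
            _conformer(
                rng.uniform(-1.5, 1.5, (4, 3)) + spheres.centers[:4] * 0.4,
                charges=rng.uniform(-0.5, 0.5, 4),
                desolv=rng.uniform(0, 1, 4),
                cid=f"c{i}",
            )
            for i in range(3)
        ]
        params = DockingParams(distance_tol=1.0, max_orientations=50)
        result = dock_molecule(confs, grids, spheres, params)
        assert result is not None
        table = []
        for conf in confs:
            for pose in orient_ligand(conf, spheres, 1.0, 50):
                if np.all(grids.lattice.contains(pose.coords)):
                    table.append(score_pose(pose, conf, grids).e_total)
        assert result[1].e_total == pytest.approx(min(table), abs=1e-12)

    def test_unplaced_returns_none(self):
        grids, spheres = self._setup()
        huge = _conformer(TRIANGLE * 50.0)
        assert dock_molecule([huge], grids, spheres,
                             DockingParams(distance_tol=0.01)) is None


class TestRankLibrary:
    def test_single_molecule_ranked_first(self):
        lat = Lattice(origin=(-6.0, -6.0, -6.0), spacing=1.0, shape=(13, 13, 13))
        grids = ScoringGrids(lat, np.zeros(lat.shape), np.zeros(lat.shape),
                             np.zeros(lat.shape), np.zeros(lat.shape))
        spheres = MatchingSpheres(TRIANGLE)
        hits = rank_library([("only", [_conformer(TRIANGLE)])], grids, spheres)
        assert hits[0].compound_id == "only" and hits[0].rank == 1

    def test_ascending_order_and_unplaced_last(self):
        lat = Lattice(origin=(-6.0, -6.0, -6.0), spacing=1.0, shape=(13, 13, 13))
        rng = np.random.default_rng(4)
        grids = ScoringGrids(lat, rng.normal(0, 5, lat.shape), np.zeros(lat.shape),
                             np.zeros(lat.shape), np.zeros(lat.shape))
        spheres = MatchingSpheres(TRIANGLE)
        lib = [
            ("a", [_conformer(TRIANGLE, charges=[1.0, 0, 0])]),
            ("nofit", [_conformer(TRIANGLE * 50.0)]),
            ("b", [_conformer(TRIANGLE, charges=[-1.0, 0, 0])]),
        ]
        hits = rank_library(lib, grids, spheres, DockingParams(distance_tol=0.1))
        placed = [h for h in hits if h.placed]
        assert [h.score.e_total for h in placed] == sorted(
            h.score.e_total for h in placed
        )
        assert hits[-1].compound_id == "nofit" and not hits[-1].placed

    def test_permutation_invariance(self):
        lat = Lattice(origin=(-6.0, -6.0, -6.0), spacing=1.0, shape=(13, 13, 13))
        rng = np.random.default_rng(8)
        grids = ScoringGrids(lat, rng.normal(0, 5, lat.shape), np.zeros(lat.shape),
                             np.zeros(lat.shape), np.zeros(lat.shape))
        spheres = MatchingSpheres(TRIANGLE)
        lib = [
            (f"m{i}", [_conformer(TRIANGLE, charges=[q, 0, 0], cid=f"m{i}")])
            for i, q in enumerate([-1.0, -0.5, 0.5, 1.0, 0.0])
        ]
        order1 = [h.compound_id for h in rank_library(lib, grids, spheres)]
        order2 = [h.compound_id for h in rank_library(lib[::-1], grids, spheres)]
        assert order1 == order2


class TestRigidTransformInvariance:
    def test_joint_translation_leaves_scores_unchanged(self):
        lat = Lattice(origin=(-6.0, -6.0, -6.0), spacing=1.0, shape=(13, 13, 13))
        rng = np.random.default_rng(6)
        field = rng.normal(0, 1, lat.shape)
        shift = np.array([2.0, -1.0, 3.0])
        lat2 = Lattice(tuple(np.asarray(lat.origin) + shift), 1.0, lat.shape)
        g1 = ScoringGrids(lat, field, np.zeros(lat.shape), np.zeros(lat.shape),
                          np.zeros(lat.shape))
        g2 = ScoringGrids(lat2, field, np.zeros(lat.shape), np.zeros(lat.shape),
                          np.zeros(lat.shape))
        s1 = MatchingSpheres(TRIANGLE)
        s2 = MatchingSpheres(TRIANGLE + shift)
        conf = _conformer(TRIANGLE, charges=[0.5, -0.3, 0.1])
        r1 = dock_molecule([conf], g1, s1)
        r2 = dock_molecule([conf], g2, s2)
        assert r1[1].e_total == pytest.approx(r2[1].e_total, abs=1e-6)

    def test_quarter_turn_rotation_leaves_scores_unchanged(self):
        """Rotating receptor frame, spheres and grids together by an
        axis-aligned quarter turn is an exact lattice symmetry."""
        lat = Lattice(origin=(-6.0, -6.0, -6.0), spacing=1.0, shape=(13, 13, 13))
        rng = np.random.default_rng(10)
        field = rng.normal(0, 1, lat.shape)
        # rotate 90° about z: (x, y, z) -> (-y, x, z)
        field_rot = np.rot90(field, k=1, axes=(0, 1))
        g1 = ScoringGrids(lat, field, np.zeros(lat.shape), np.zeros(lat.shape),
                          np.zeros(lat.shape))
        g2 = ScoringGrids(lat, field_rot, np.zeros(lat.shape), np.zeros(lat.shape),
                          np.zeros(lat.shape))
        R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        s1 = MatchingSpheres(TRIANGLE)
        s2 = MatchingSpheres(TRIANGLE @ R.T)
        conf = _conformer(TRIANGLE, charges=[0.5, -0.3, 0.1])
        r1 = dock_molecule([conf], g1, s1)
        r2 = dock_molecule([conf], g2, s2)
        assert r1[1].e_total == pytest.approx(r2[1].e_total, abs=1e-6)
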