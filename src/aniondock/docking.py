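"""Rigid-conformer docking on precomputed grids.

Orientations are generated by superposing ligand heavy-atom triplets onto
matching-sphere triplets whose pairwise distances agree within a tolerance
(least-squares rigid fit), and each pose is scored with the three-term
physics score

    E_total = E_elec + E_vdw + E_desolv

where E_elec is the probe-charge interaction with the precomputed receptor
potential, E_vdw the 6-12 dispersion/repulsion read from the component
grids, and E_desolv a penalty for burying solvated ligand atoms, scaled by
the local occlusion fraction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .grids import MatchingSpheres, ScoringGrids

#: per-atom cap on the repulsive vdW term, kcal/mol
VDW_REPULSION_CAP = 100.0


@dataclass
class LigandConformer:
    """One rigid 3D conformation of a ligand.

    ``desolv`` stores per-atom desolvation penalty magnitudes (kcal/mol,
    >= 0): the cost of fully burying that atom.  ``sqrt_a``/``sqrt_b`` are
    the square-rooted 6-12 coefficients pairing with the component grids.
    """

    conformer_id: str
    elements: list[str]
    coords: np.ndarray            # (n, 3) Å
    charges: np.ndarray           # e
    desolv: np.ndarray            # kcal/mol, >= 0
    sqrt_a: np.ndarray
    sqrt_b: np.ndarray
    bonds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.coords) < 3:
            raise ValueError("conformer needs at least 3 heavy atoms")
        if np.any(np.asarray(self.desolv) < 0):
            raise ValueError("desolvation costs are stored as positive penalties")


@dataclass
class Pose:
    """A placed conformer: proper rigid transform plus transformed coords."""

    conformer_id: str
    rotation: np.ndarray          # (3, 3), det = +1
    translation: np.ndarray       # (3,)
    coords: np.ndarray            # transformed atom coordinates

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("pose rotation must be proper (det = +1)")


@dataclass(frozen=True)
class ScoreBreakdown:
    e_elec: float
    e_vdw: float
    e_desolv: float

    @property
    def e_total(self) -> float:
        return self.e_elec + self.e_vdw + self.e_desolv


@dataclass
class DockingParams:
    distance_tol: float = 0.5     # Å, triplet edge-length agreement
    max_orientations: int = 1000
    min_triangle_area: float = 0.1  # Å²; rejects collinear triplets


def _kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares proper rotation + translation mapping src onto dst."""
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    H = (src - sc).T @ (dst - dc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, dc - R @ sc


def _triangle_area(p: np.ndarray) -> float:
    return 0.5 * float(np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0])))


def orient_ligand(
    conformer: LigandConformer,
    spheres: MatchingSpheres,
    distance_tol: float = 0.5,
    max_orientations: int = 1000,
    min_triangle_area: float = 0.1,
) -> list[Pose]:
    """Enumerate rigid placements by triplet matching.

    Every unordered ligand-atom triplet is compared against every ordered
    sphere triplet; when the three pairwise distances each agree within
    ``distance_tol`` the least-squares rigid fit of atoms onto spheres
    becomes a pose.  Enumeration is lexicographic in (atom triplet, sphere
    triplet) indices, so output order is deterministic; the list is
    truncated at ``max_orientations``.  Near-collinear triplets are skipped
    (the fit would be rotationally degenerate).
    """
    if len(spheres) < 3:
        raise ValueError("at least 3 matching spheres are required")
    if distance_tol < 0:
        raise ValueError("distance_tol must be non-negative")
    coords = conformer.coords
    centers = spheres.centers
    poses: list[Pose] = []
    n, m = len(coords), len(centers)
    for ai, aj, ak in itertools.combinations(range(n), 3):
        tri_a = coords[[ai, aj, ak]]
        if _triangle_area(tri_a) < min_triangle_area:
            continue
        da = (
            np.linalg.norm(tri_a[0] - tri_a[1]),
            np.linalg.norm(tri_a[0] - tri_a[2]),
            np.linalg.norm(tri_a[1] - tri_a[2]),
        )
        for si, sj, sk in itertools.permutations(range(m), 3):
            tri_s = centers[[si, sj, sk]]
            if _triangle_area(tri_s) < min_triangle_area:
                continue
            ds = (
                np.linalg.norm(tri_s[0] - tri_s[1]),
                np.linalg.norm(tri_s[0] - tri_s[2]),
                np.linalg.norm(tri_s[1] - tri_s[2]),
            )
            if any(abs(da[t] - ds[t]) > distance_tol for t in range(3)):
                continue
            R, t = _kabsch(tri_a, tri_s)
            poses.append(
                Pose(
                    conformer_id=conformer.conformer_id,
                    rotation=R,
                    translation=t,
                    coords=coords @ R.T + t,
                )
            )
            if len(poses) >= max_orientations:
                return poses
    return poses


def score_pose(
    pose: Pose, conformer: LigandConformer, grids: ScoringGrids
) -> ScoreBreakdown:
    """Three-term grid score of a pose (trilinear interpolation).

    Raises ``ValueError`` naming the first offending atom if any atom lies
    outside the grid box.
    """
    lat = grids.lattice
    inside = lat.contains(pose.coords)
    if not np.all(inside):
        bad = int(np.argmin(inside))
        raise ValueError(f"atom index {bad} of pose lies outside the grid box")
    phi = lat.interpolate(grids.potential, pose.coords)
    ga = lat.interpolate(grids.vdw_a, pose.coords)
    gb = lat.interpolate(grids.vdw_b, pose.coords)
    occ = lat.interpolate(grids.desolv_occlusion, pose.coords)

    e_elec = float(np.dot(conformer.charges, phi))
    repulsion = np.minimum(conformer.sqrt_a * ga, VDW_REPULSION_CAP)
    e_vdw = float(np.sum(repulsion - conformer.sqrt_b * gb))
    e_desolv = float(np.dot(conformer.desolv, np.clip(occ, 0.0, 1.0)))
    return ScoreBreakdown(e_elec=e_elec, e_vdw=e_vdw, e_desolv=e_desolv)


#: sentinel for molecules with no geometrically feasible placement
UNPLACED = None


def dock_molecule(
    conformers: Sequence[LigandConformer],
    grids: ScoringGrids,
    spheres: MatchingSpheres,
    params: DockingParams | None = None,
) -> tuple[Pose, ScoreBreakdown] | None:
    """Best (minimum E_total) pose over all conformers and orientations.

    Deterministic: ties are broken by enumeration order (conformer order,
    then orientation order).  Returns ``None`` when no conformer admits any
    in-box orientation.
    """
    if not conformers:
        raise ValueError("at least one conformer is required")
    params = params or DockingParams()
    best: tuple[Pose, ScoreBreakdown] | None = None
    for conf in conformers:
        for pose in orient_ligand(
            conf,
            spheres,
            distance_tol=params.distance_tol,
            max_orientations=params.max_orientations,
            min_triangle_area=params.min_triangle_area,
        ):
            if not np.all(grids.lattice.contains(pose.coords)):
                continue
            sb = score_pose(pose, conf, grids)
            if best is None or sb.e_total < best[1].e_total - 1e-12:
                best = (pose, sb)
    return best


@dataclass
class RankedHit:
    compound_id: str
    score: ScoreBreakdown | None
    pose: Pose | None
    rank: int = -1

    @property
    def placed(self) -> bool:
        return self.score is not None


def rank_library(
    library: Iterable[tuple[str, Sequence[LigandConformer]]],
    grids: ScoringGrids,
    spheres: MatchingSpheres,
    params: DockingParams | None = None,
) -> list[RankedHit]:
    """Dock every molecule and return hits sorted ascending by E_total.

    The sort is stable (input order breaks ties); unplaced molecules are
    appended after all placed ones, flagged by ``placed == False``.
    """
    placed: list[RankedHit] = []
    unplaced: list[RankedHit] = []
    for compound_id, conformers in library:
        result = dock_molecule(conformers, grids, spheres, params)
        if result is None:
            unplaced.append(RankedHit(compound_id, None, None))
        else:
            placed.append(RankedHit(compound_id, result[1], result[0]))
    placed.sort(key=lambda h: h.score.e_total)  # stable
    out = placed + unplaced
    for i, h in enumerate(out):
        h.rank = i + 1
    return out


def write_scores_tsv(path, hits: list[RankedHit]) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["id", "e_elec", "e_vdw", "e_desolv", "e_total", "rank"])
        for h in hits:
            if h.placed:
                w.writerow(
                    [h.compound_id, f"{h.score.e_elec:.4f}", f"{h.score.e_vdw:.4f}",
                     f"{h.score.e_desolv:.4f}", f"{h.score.e_total:.4f}", h.rank]
                )
            else:
                w.writerow([h.compound_id, "NA", "NA", "NA", "NA", h.rank])
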