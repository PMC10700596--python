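"""Membrane-aware scoring grids.

Four lattices share one geometry: a two-valued dielectric map (protein/lipid
interior vs. aqueous), the electrostatic potential solved from the Poisson
equation on that map, the van der Waals attraction/repulsion component grids,
and a desolvation-occlusion grid measuring how buried a point is.  Matching
spheres — hot-spot points derived from a reference ligand — complete the set
the docking engine needs.

Conventions: coordinates in Å, charges in elementary units, potential in
kcal/(mol·e).  The electrostatic conversion constant 332.063 kcal·Å/(mol·e²)
links the two unit systems.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import cg

from .receptor import ReceptorModel

#: Coulomb constant in kcal·Å/(mol·e²): phi(r) = COULOMB_K * q / (eps * r)
COULOMB_K = 332.063


# ---------------------------------------------------------------------------
# Lattice geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Lattice:
    """Uniform cubic-cell lattice: ``origin`` is the corner node, ``spacing``
    the node separation in Å, ``shape`` the node counts per axis."""

    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("lattice spacing must be positive")
        if any(n < 2 for n in self.shape):
            raise ValueError("lattice needs at least 2 nodes per axis")

    @property
    def extent(self) -> np.ndarray:
        """(min, max) corner coordinates, shape (2, 3)."""
        o = np.asarray(self.origin, dtype=float)
        return np.stack([o, o + self.spacing * (np.asarray(self.shape) - 1)])

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        o = self.origin
        return tuple(
            o[k] + self.spacing * np.arange(self.shape[k]) for k in range(3)
        )

    def node_coords(self) -> np.ndarray:
        """All node coordinates, shape (nx, ny, nz, 3)."""
        ax, ay, az = self.axes()
        gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        lo, hi = self.extent
        return np.all((p >= lo + margin) & (p <= hi - margin), axis=1)

    def covers_receptor(self, receptor: ReceptorModel, margin: float = 0.0) -> bool:
        return bool(np.all(self.contains(receptor.coords, margin=margin)))

    def interpolate(self, fld: np.ndarray, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of a node field at arbitrary points."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        if not np.all(self.contains(p)):
            bad = int(np.argmin(self.contains(p)))
            raise ValueError(f"point index {bad} lies outside the lattice")
        f = (p - np.asarray(self.origin)) / self.spacing
        i0 = np.floor(f).astype(int)
        i0 = np.minimum(i0, np.asarray(self.shape) - 2)
        i0 = np.maximum(i0, 0)
        t = f - i0
        out = np.zeros(len(p))
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = (
                        (t[:, 0] if dx else 1 - t[:, 0])
                        * (t[:, 1] if dy else 1 - t[:, 1])
                        * (t[:, 2] if dz else 1 - t[:, 2])
                    )
                    out += w * fld[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
        return out

    @classmethod
    def around(
        cls,
        points: np.ndarray,
        spacing: float = 0.4,
        margin: float = 6.0,
    ) -> "Lattice":
        """Smallest lattice covering ``points`` with the given margin."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        lo = p.min(axis=0) - margin
        hi = p.max(axis=0) + margin
        shape = tuple(int(np.ceil((hi[k] - lo[k]) / spacing)) + 1 for k in range(3))
        return cls(origin=tuple(lo), spacing=spacing, shape=shape)


# ---------------------------------------------------------------------------
# Dielectric map
# ---------------------------------------------------------------------------

@dataclass
class DielectricMap:
    """Two-valued relative-dielectric lattice: ``eps_low`` inside the
    (extended) protein/lipid volume, ``eps_high`` in the aqueous region."""

    lattice: Lattice
    values: np.ndarray
    eps_low: float = 2.0
    eps_high: float = 78.0

    def __post_init__(self) -> None:
        if self.values.shape != self.lattice.shape:
            raise ValueError("dielectric values do not match lattice shape")


def _points_within_spheres(
    node_xyz: np.ndarray, centers: np.ndarray, radii: np.ndarray
) -> np.ndarray:
    """Boolean mask over flattened nodes: inside any sphere.  Chunked to
    bound memory; exact (no tree approximations) so it can be checked
    against a brute-force oracle."""
    n = len(node_xyz)
    mask = np.zeros(n, dtype=bool)
    if len(centers) == 0:
        return mask
    chunk = max(1, 4_000_000 // max(len(centers), 1))
    for s in range(0, n, chunk):
        d2 = (
            (node_xyz[s : s + chunk, None, :] - centers[None, :, :]) ** 2
        ).sum(axis=2)
        mask[s : s + chunk] = np.any(d2 <= radii[None, :] ** 2, axis=1)
    return mask


def assign_membrane_dielectric(
    receptor: ReceptorModel,
    lipid_atoms: np.ndarray | None,
    lattice: Lattice,
    lipid_cutoff: float = 17.0,
    surface_extension: float = 1.9,
    eps_low: float = 2.0,
    eps_high: float = 78.0,
    lipid_radius: float = 1.9,
) -> DielectricMap:
    """Classify every lattice node as low or high dielectric.

    A node is low-dielectric iff it lies within ``atom_radius +
    surface_extension`` of any receptor atom, or within ``lipid_radius`` of
    any retained lipid atom.  Lipid atoms farther than ``lipid_cutoff`` from
    every receptor atom are discarded, so only the membrane ring hugging the
    receptor contributes.

    Returns the map; raises ``ValueError`` on an empty receptor or a lattice
    that does not cover it.
    """
    if not receptor.atoms:
        raise ValueError("receptor is empty")
    if not lattice.covers_receptor(receptor):
        raise ValueError("lattice does not cover the receptor")

    rc = receptor.coords
    centers = [rc]
    radii = [receptor.radii + surface_extension]

    if lipid_atoms is not None and len(lipid_atoms) > 0:
        lip = np.atleast_2d(np.asarray(lipid_atoms, dtype=float))
        d2 = ((lip[:, None, :] - rc[None, :, :]) ** 2).sum(axis=2)
        retained = lip[np.any(d2 <= lipid_cutoff**2, axis=1)]
        if len(retained):
            centers.append(retained)
            radii.append(np.full(len(retained), lipid_radius))

    node_xyz = lattice.node_coords().reshape(-1, 3)
    inside = _points_within_spheres(
        node_xyz, np.vstack(centers), np.concatenate(radii)
    )
    values = np.where(inside.reshape(lattice.shape), eps_low, eps_high)
    return DielectricMap(lattice, values.astype(float), eps_low, eps_high)


# ---------------------------------------------------------------------------
# Poisson solver
# ---------------------------------------------------------------------------

def _spread_charges(
    lattice: Lattice, coords: np.ndarray, charges: np.ndarray
) -> np.ndarray:
    """Trilinear (cloud-in-cell) assignment of point charges to nodes."""
    rho = np.zeros(lattice.shape)
    f = (coords - np.asarray(lattice.origin)) / lattice.spacing
    i0 = np.floor(f).astype(int)
    i0 = np.minimum(i0, np.asarray(lattice.shape) - 2)
    i0 = np.maximum(i0, 0)
    t = f - i0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (t[:, 0] if dx else 1 - t[:, 0])
                    * (t[:, 1] if dy else 1 - t[:, 1])
                    * (t[:, 2] if dz else 1 - t[:, 2])
                )
                np.add.at(
                    rho, (i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz), w * charges
                )
    return rho / lattice.spacing**3


def solve_potential_grid(
    receptor: ReceptorModel,
    dielectric: DielectricMap,
    tol: float = 1e-8,
    max_iter: int = 20000,
) -> np.ndarray:
    """Finite-difference solution of ``∇·(ε∇φ) = −4πρ`` at zero ionic
    strength on the dielectric map's lattice.

    Face dielectric values are harmonic means of the node values; the
    Dirichlet boundary is the Coulomb potential of all charges screened by
    ``eps_high``.  Returns the potential field in kcal/(mol·e).

    Raises ``RuntimeError`` (with the residual) if conjugate gradients do
    not reach the requested relative residual.
    """
    lat = dielectric.lattice
    charged = np.abs(receptor.charges) > 0
    if np.any(charged) and not np.all(
        lat.contains(receptor.coords[charged], margin=lat.spacing)
    ):
        raise ValueError("all charged atoms must lie strictly inside the lattice")

    nx, ny, nz = lat.shape
    h = lat.spacing
    eps = dielectric.values
    rho = _spread_charges(lat, receptor.coords, receptor.charges)

    # Dirichlet boundary: Coulomb sum screened by eps_high (gauss units e/Å)
    phi = np.zeros(lat.shape)
    boundary = np.zeros(lat.shape, dtype=bool)
    boundary[0, :, :] = boundary[-1, :, :] = True
    boundary[:, 0, :] = boundary[:, -1, :] = True
    boundary[:, :, 0] = boundary[:, :, -1] = True
    if np.any(charged):
        bxyz = lat.node_coords()[boundary]
        qc = receptor.charges[charged]
        cc = receptor.coords[charged]
        d = np.sqrt(((bxyz[:, None, :] - cc[None, :, :]) ** 2).sum(axis=2))
        d = np.maximum(d, 1e-6)
        phi[boundary] = (qc[None, :] / d).sum(axis=1) / dielectric.eps_high

    # Interior unknowns: 7-point stencil of -∇·(ε∇φ) = 4πρ (SPD system)
    idx = -np.ones(lat.shape, dtype=np.int64)
    interior = ~boundary
    n_unknown = int(interior.sum())
    idx[interior] = np.arange(n_unknown)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    # stencil multiplied through by h^2: Σ_f ε_f(φ_nbr − φ_i) = −4π ρ_i h²
    b = 4.0 * np.pi * rho[interior] * h * h

    ii, jj, kk = np.nonzero(interior)
    center = idx[ii, jj, kk]
    diag = np.zeros(n_unknown)
    for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
        ni, nj, nk = ii + di, jj + dj, kk + dk
        eps_face = 2.0 * eps[ii, jj, kk] * eps[ni, nj, nk] / (
            eps[ii, jj, kk] + eps[ni, nj, nk]
        )
        diag += eps_face
        nbr = idx[ni, nj, nk]
        known = nbr < 0
        # boundary neighbours move to the right-hand side
        b[center[known]] += eps_face[known] * phi[ni[known], nj[known], nk[known]]
        free = ~known
        rows.append(center[free])
        cols.append(nbr[free])
        vals.append(-eps_face[free])
    rows.append(center)
    cols.append(center)
    vals.append(diag)
    A = coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_unknown, n_unknown),
    ).tocsr()

    x0 = phi[interior]
    x, info = cg(A, b, x0=x0, rtol=tol, maxiter=max_iter)
    if info != 0:
        resid = float(np.linalg.norm(A @ x - b) / max(np.linalg.norm(b), 1e-300))
        raise RuntimeError(
            f"Poisson solver did not converge (info={info}, relative residual={resid:.3e})"
        )
    phi[interior] = x
    return phi * COULOMB_K


def discrete_gauss_flux(
    phi: np.ndarray, dielectric: DielectricMap, box_lo: Sequence[int], box_hi: Sequence[int]
) -> float:
    """Discrete flux ``∮ ε∇φ·dA`` (gauss units) through the faces of the
    node-index box ``[box_lo, box_hi]``; equals ``−4π Σq`` enclosed for an
    exact solution.  Used to verify charge conservation of the solver."""
    lat = dielectric.lattice
    h = lat.spacing
    eps = dielectric.values
    p = phi / COULOMB_K
    lo = tuple(int(v) for v in box_lo)
    hi = tuple(int(v) for v in box_hi)
    flux = 0.0

    def face_flux(axis: int, index: int, outward: int) -> float:
        sl_in = [slice(lo[k], hi[k] + 1) for k in range(3)]
        sl_out = list(sl_in)
        sl_in[axis] = index
        sl_out[axis] = index + outward
        eps_face = 2.0 * eps[tuple(sl_in)] * eps[tuple(sl_out)] / (
            eps[tuple(sl_in)] + eps[tuple(sl_out)]
        )
        dphi = (p[tuple(sl_out)] - p[tuple(sl_in)]) / h
        return float((eps_face * dphi).sum() * h * h)

    for axis in range(3):
        flux += face_flux(axis, hi[axis], +1)
        flux += face_flux(axis, lo[axis], -1)
    return flux


# ---------------------------------------------------------------------------
# Van der Waals grids
# ---------------------------------------------------------------------------

#: AMBER-style united-atom 6-12 coefficients, keyed by element:
#: A in kcal·Å¹²/mol, B in kcal·Å⁶/mol (grid stores Σ√A/r¹² and Σ√B/r⁶).
DEFAULT_VDW_PARAMS: dict[str, tuple[float, float]] = {
    "C": (1043080.0, 675.61),
    "N": (540675.0, 588.24),
    "O": (230584.0, 429.50),
    "S": (1132528.0, 1086.30),
    "P": (1132528.0, 1086.30),
    "H": (81.92, 2.56),
    "F": (131072.0, 290.0),
    "X": (500000.0, 500.0),  # generic pseudo-atom
}

VDW_R_FLOOR = 0.8  # Å; caps the 1/r singularity at grid nodes inside atoms


def build_vdw_grid(
    receptor: ReceptorModel,
    vdw_params: dict[str, tuple[float, float]] | None = None,
    lattice: Lattice | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Precompute ``vdw_a(x) = Σ_j √A_j / r_jx¹²`` and
    ``vdw_b(x) = Σ_j √B_j / r_jx⁶`` over the lattice.

    Lipid atoms must not be included in ``receptor`` — the membrane shapes
    the dielectric and desolvation environment but exerts no dispersion
    pull on docked ligands.  Distances are clamped at 0.8 Å.
    """
    if lattice is None:
        raise ValueError("a lattice is required")
    params = vdw_params if vdw_params is not None else DEFAULT_VDW_PARAMS
    missing = sorted({a.element for a in receptor.atoms} - set(params))
    if missing:
        raise KeyError(f"no van der Waals parameters for element(s): {missing}")

    node_xyz = lattice.node_coords().reshape(-1, 3)
    vdw_a = np.zeros(len(node_xyz))
    vdw_b = np.zeros(len(node_xyz))
    sqrt_a = np.array([np.sqrt(params[a.element][0]) for a in receptor.atoms])
    sqrt_b = np.array([np.sqrt(params[a.element][1]) for a in receptor.atoms])
    coords = receptor.coords
    chunk = max(1, 2_000_000 // max(len(coords), 1))
    for s in range(0, len(node_xyz), chunk):
        d = np.sqrt(
            ((node_xyz[s : s + chunk, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        )
        d = np.maximum(d, VDW_R_FLOOR)
        vdw_a[s : s + chunk] = (sqrt_a[None, :] / d**12).sum(axis=1)
        vdw_b[s : s + chunk] = (sqrt_b[None, :] / d**6).sum(axis=1)
    return vdw_a.reshape(lattice.shape), vdw_b.reshape(lattice.shape)


# ---------------------------------------------------------------------------
# Desolvation-occlusion grid
# ---------------------------------------------------------------------------

def _ball_samples(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-ball sample cloud (fixed stream)."""
    rng = np.random.default_rng(20240901)
    pts = rng.standard_normal((n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    radii = rng.random(n) ** (1.0 / 3.0)
    return pts * radii[:, None]


def build_desolvation_grid(
    receptor: ReceptorModel,
    lipid_atoms: np.ndarray | None,
    lattice: Lattice,
    volume_extension: float = 0.5,
    shell_radius: float = 6.0,
    lipid_radius: float = 1.9,
    n_samples: int = 256,
) -> np.ndarray:
    """Occlusion field in [0, 1]: the fraction of a probe ball of radius
    ``shell_radius`` around each node that falls inside the receptor-or-lipid
    volume (receptor atom radii extended by ``volume_extension``).

    A fully solvated point scores 0, a deeply buried one 1; ligand
    desolvation penalties scale with this fraction at score time.
    """
    centers = [receptor.coords]
    radii = [receptor.radii + volume_extension]
    if lipid_atoms is not None and len(lipid_atoms) > 0:
        lip = np.atleast_2d(np.asarray(lipid_atoms, dtype=float))
        centers.append(lip)
        radii.append(np.full(len(lip), lipid_radius))
    all_c = np.vstack(centers)
    all_r = np.concatenate(radii)

    node_xyz = lattice.node_coords().reshape(-1, 3)
    counts = np.zeros(len(node_xyz))
    for offset in _ball_samples(n_samples) * shell_radius:
        counts += _points_within_spheres(node_xyz + offset, all_c, all_r)
    return (counts / n_samples).reshape(lattice.shape)


def occlusion_at_point(
    point: np.ndarray,
    centers: np.ndarray,
    radii: np.ndarray,
    shell_radius: float,
    n_samples: int,
    seed: int = 0,
) -> float:
    """Monte-Carlo occlusion oracle at a single point (independent sampling
    stream); used to cross-check the grid builder."""
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((n_samples, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts *= (rng.random(n_samples) ** (1 / 3))[:, None] * shell_radius
    pts += np.asarray(point)
    return float(_points_within_spheres(pts, centers, radii).mean())


# ---------------------------------------------------------------------------
# Matching spheres
# ---------------------------------------------------------------------------

@dataclass
class MatchingSpheres:
    """Hot-spot points (reference-ligand heavy-atom positions) onto which
    ligand atom triplets are superposed during orientation sampling."""

    centers: np.ndarray

    def __len__(self) -> int:
        return len(self.centers)


def generate_matching_spheres(
    reference_atoms: np.ndarray,
    max_spheres: int = 45,
    dedup_radius: float = 0.25,
) -> MatchingSpheres:
    """Derive matching spheres from reference heavy-atom coordinates.

    Positions are deduplicated greedily in input order (a point within
    ``dedup_radius`` of a kept point is dropped), then truncated to
    ``max_spheres`` keeping those closest to the reference centroid —
    hot-spots near the pocket core are the most transferable.
    """
    pts = np.atleast_2d(np.asarray(reference_atoms, dtype=float))
    if len(pts) < 3:
        raise ValueError("at least 3 reference atoms are required")
    kept: list[np.ndarray] = []
    for p in pts:
        if all(np.linalg.norm(p - k) >= dedup_radius for k in kept):
            kept.append(p)
    arr = np.array(kept)
    centroid = pts.mean(axis=0)
    order = np.argsort(
        np.linalg.norm(arr - centroid, axis=1), kind="stable"
    )
    return MatchingSpheres(arr[order[:max_spheres]])


# ---------------------------------------------------------------------------
# Scoring-grid container and I/O
# ---------------------------------------------------------------------------

@dataclass
class ScoringGrids:
    """The four congruent scoring lattices plus their geometry."""

    lattice: Lattice
    potential: np.ndarray       # kcal/(mol·e)
    vdw_a: np.ndarray           # Σ√A/r¹²
    vdw_b: np.ndarray           # Σ√B/r⁶
    desolv_occlusion: np.ndarray  # fraction in [0, 1]

    def __post_init__(self) -> None:
        for name in ("potential", "vdw_a", "vdw_b", "desolv_occlusion"):
            if getattr(self, name).shape != self.lattice.shape:
                raise ValueError(f"{name} grid does not match the lattice shape")
        occ = self.desolv_occlusion
        if occ.min() < -1e-9 or occ.max() > 1 + 1e-9:
            raise ValueError("desolvation occlusion must lie in [0, 1]")

    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.npz`` (fields) + ``<prefix>.hdr.json`` (geometry)."""
        prefix = Path(prefix)
        np.savez_compressed(
            prefix.with_suffix(".npz"),
            potential=self.potential,
            vdw_a=self.vdw_a,
            vdw_b=self.vdw_b,
            desolv_occlusion=self.desolv_occlusion,
        )
        header = {
            "origin": list(self.lattice.origin),
            "spacing": self.lattice.spacing,
            "dims": list(self.lattice.shape),
            "units": {"potential": "kcal/(mol*e)", "length": "angstrom"},
        }
        prefix.with_suffix(".hdr.json").write_text(json.dumps(header, indent=2))

    @classmethod
    def load(cls, prefix: str | Path) -> "ScoringGrids":
        prefix = Path(prefix)
        header = json.loads(prefix.with_suffix(".hdr.json").read_text())
        lat = Lattice(
            origin=tuple(header["origin"]),
            spacing=float(header["spacing"]),
            shape=tuple(header["dims"]),
        )
        with np.load(prefix.with_suffix(".npz")) as z:
            return cls(
                lattice=lat,
                potential=z["potential"],
                vdw_a=z["vdw_a"],
                vdw_b=z["vdw_b"],
                desolv_occlusion=z["desolv_occlusion"],
            )
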