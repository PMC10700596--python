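"""End-to-end convenience assemblies of the pipeline stages.

These are the compositions the control calculations use: build all four
scoring grids for a receptor/membrane system in one call, and run the
paired perturbed-vs-unperturbed docking experiment that probes whether
strengthening the pocket's polar dipoles improves anion recognition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .docking import DockingParams, LigandConformer, dock_molecule
from .grids import (
    DEFAULT_VDW_PARAMS,
    Lattice,
    MatchingSpheres,
    ScoringGrids,
    assign_membrane_dielectric,
    build_desolvation_grid,
    build_vdw_grid,
    generate_matching_spheres,
    solve_potential_grid,
)
from .receptor import ReceptorModel, perturb_polar_charges
from .synthetic import ToyComplex, make_toy_complex


def build_scoring_grids(
    receptor: ReceptorModel,
    lipid_atoms: np.ndarray | None,
    spacing: float = 0.5,
    margin: float = 6.0,
    lipid_cutoff: float = 17.0,
    surface_extension: float = 1.9,
    eps_low: float = 2.0,
    eps_high: float = 78.0,
    desolv_shell: float = 4.0,
    desolv_samples: int = 64,
    pb_tol: float = 1e-8,
) -> ScoringGrids:
    """Dielectric map → Poisson potential → vdW → desolvation, all on one
    lattice sized to the receptor plus ``margin``."""
    lat = Lattice.around(receptor.coords, spacing=spacing, margin=margin)
    die = assign_membrane_dielectric(
        receptor, lipid_atoms, lat,
        lipid_cutoff=lipid_cutoff, surface_extension=surface_extension,
        eps_low=eps_low, eps_high=eps_high,
    )
    phi = solve_potential_grid(receptor, die, tol=pb_tol)
    vdw_a, vdw_b = build_vdw_grid(receptor, lattice=lat)
    occ = build_desolvation_grid(
        receptor, lipid_atoms, lat,
        shell_radius=desolv_shell, n_samples=desolv_samples,
    )
    return ScoringGrids(lat, phi, vdw_a, vdw_b, occ)


def probe_ligand(coords: np.ndarray, net_charge: float,
                 desolv_per_atom: float = 0.5) -> LigandConformer:
    """A minimal rigid probe: the given heavy-atom coordinates with the
    net charge spread evenly and soft (hydrogen-like) 6-12 parameters."""
    n = len(coords)
    return LigandConformer(
        conformer_id=f"probe_q{net_charge:+.0f}",
        elements=["C"] * n,
        coords=np.asarray(coords, dtype=float),
        charges=np.full(n, net_charge / n),
        desolv=np.full(n, desolv_per_atom),
        sqrt_a=np.full(n, np.sqrt(DEFAULT_VDW_PARAMS["H"][0])),
        sqrt_b=np.full(n, np.sqrt(DEFAULT_VDW_PARAMS["H"][1])),
    )


@dataclass
class AnionRecognitionResult:
    anion_unperturbed: float
    anion_perturbed: float
    cation_unperturbed: float
    cation_perturbed: float

    @property
    def anion_gain(self) -> float:
        """Score improvement (positive = better) of the monoanion under the
        perturbed grids."""
        return self.anion_unperturbed - self.anion_perturbed

    @property
    def direction_holds(self) -> bool:
        """Perturbation helps the anion and the anion beats its
        charge-inverted twin on the perturbed grids."""
        return (
            self.anion_perturbed < self.anion_unperturbed
            and self.anion_perturbed < self.cation_perturbed
        )


def anion_recognition_experiment(
    toy: ToyComplex | None = None,
    seed: int = 1,
    spacing: float = 0.75,
    distance_tol: float = 0.3,
    max_orientations: int = 200,
) -> AnionRecognitionResult:
    """Dock a planted monoanion and its charge-inverted twin against the
    toy pocket with and without the polar-charge perturbation.

    The perturbation strengthens the pocket's local dipoles, so the
    monoanion's best score should improve relative to the unperturbed
    grids while the cation's does not.
    """
    if toy is None:
        toy = make_toy_complex(40, 15.0, seed=seed)
    perturbed_rec = perturb_polar_charges(toy.receptor, toy.polar_targets, 0.4)
    spheres = generate_matching_spheres(toy.reference_ligand_atoms)
    params = DockingParams(distance_tol=distance_tol,
                           max_orientations=max_orientations)
    anion = probe_ligand(toy.reference_ligand_atoms[:4], -1.0)
    cation = probe_ligand(toy.reference_ligand_atoms[:4], +1.0)

    scores = {}
    for tag, receptor in (("unperturbed", toy.receptor),
                          ("perturbed", perturbed_rec)):
        grids = build_scoring_grids(receptor, toy.lipid_atoms, spacing=spacing)
        for name, lig in (("anion", anion), ("cation", cation)):
            result = dock_molecule([lig], grids, spheres, params)
            if result is None:
                raise RuntimeError(f"{name} probe could not be placed")
            scores[(name, tag)] = result[1].e_total
    return AnionRecognitionResult(
        anion_unperturbed=scores[("anion", "unperturbed")],
        anion_perturbed=scores[("anion", "perturbed")],
        cation_unperturbed=scores[("cation", "unperturbed")],
        cation_perturbed=scores[("cation", "perturbed")],
    )
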