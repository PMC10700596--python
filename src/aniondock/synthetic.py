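"""Synthetic fixtures for every pipeline stage.

A toy membrane-receptor complex (a rigid pseudo-atom cup embedded between
two apolar lipid planes), compound libraries of known class composition,
planted-separation enrichment benchmarks, 4PL assay tables and
one-compartment PK profiles.  Everything is deterministic for a fixed
seed, with one seeded generator per call and no global state.

The toy complex is not a force-field model: charges are hand-assigned in
{-0.4, 0, +0.4, +1} e and radii in {1.5, 1.9} Å, spanning the charge
perturbation and electrostatics test space; the lipid slab is two parallel
planes of apolar points, the minimal geometry creating an anisotropic
dielectric environment around the pocket.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .libprep import CompoundRecord, assign_protonation, compute_properties
from .pharmacology import DoseResponse, PKProfile
from .receptor import Atom, ReceptorModel


# ---------------------------------------------------------------------------
# Toy membrane-receptor complex
# ---------------------------------------------------------------------------

@dataclass
class ToyComplex:
    receptor: ReceptorModel
    lipid_atoms: np.ndarray          # (n, 3) Å, apolar, uncharged
    pocket_center: np.ndarray        # (3,) Å
    reference_ligand_atoms: np.ndarray  # (m, 3) Å, inside the pocket

    #: residues whose hydroxyl H / backbone O pairs take the polar
    #: charge perturbation (res_num, H name, O name)
    polar_targets: list[tuple[int, str, str]] = field(default_factory=list)


def make_toy_complex(
    n_receptor_atoms: int = 50,
    slab_z: float = 15.0,
    seed: int = 0,
    cup_radius: float = 8.0,
    slab_extent: float = 24.0,
    slab_spacing: float = 8.0,
    mouth_clearance: float = 12.0,
) -> ToyComplex:
    """Build the toy complex: a concave receptor cup opening toward +z,
    flanked by two lipid planes at z = ±slab_z/2 whose +z face has a hole
    over the pocket mouth (the ligand's approach path); the −z face is
    closed.

    The first three "residues" carry hydroxyl-H / carbonyl-O atom pairs so
    the polar-charge perturbation has named targets; a +1 e pseudo-atom
    sits at the pocket floor to give the pocket its anion-recognition
    character.  Deterministic for a fixed seed.
    """
    if n_receptor_atoms < 10:
        raise ValueError("n_receptor_atoms must be >= 10")
    if slab_z <= 0:
        raise ValueError("slab_z must be positive")
    rng = np.random.default_rng(seed)

    atoms: list[Atom] = []
    # pocket floor: Arg-like +1 pseudo-atom
    atoms.append(
        Atom("N", (0.0, 0.0, -cup_radius + 1.0), 1.9, 1.0, name="NH1",
             res_name="ARG", res_num=100)
    )
    # three polar residues on the cup wall: hydroxyl H + backbone O pairs
    polar_targets = []
    for k, phi in enumerate((0.0, 2.0 * math.pi / 3.0, 4.0 * math.pi / 3.0)):
        x, y = cup_radius * math.cos(phi), cup_radius * math.sin(phi)
        res = k + 1
        atoms.append(
            Atom("H", (0.9 * x, 0.9 * y, -1.0), 1.5, 0.4, name="HG1",
                 res_name="THR", res_num=res)
        )
        atoms.append(
            Atom("O", (x, y, -3.0), 1.5, -0.4, name="O",
                 res_name="THR", res_num=res)
        )
        polar_targets.append((res, "HG1", "O"))
    # guaranteed neutral atom
    atoms.append(
        Atom("C", (0.0, cup_radius, 2.0), 1.9, 0.0, name="CA",
             res_name="GLY", res_num=200)
    )

    # remaining atoms: lower-hemisphere shell points (cup wall, mouth at +z).
    # Wall charges follow a balanced hand-assigned cycle so the pocket's
    # net polarity comes from the designed +1 floor atom and the polar
    # residues, not from the luck of the draw — the pocket must stay
    # anion-recognizing for every seed.
    n_rest = n_receptor_atoms - len(atoms)
    res_num = 300
    charge_cycle = (-0.4, 0.0, 0.4, 0.0)
    radii = np.array([1.5, 1.9])
    for k in range(n_rest):
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v)
        if v[2] > 0.35:  # keep the mouth open toward +z
            v[2] = -v[2]
        pos = v * cup_radius * (1.0 + 0.05 * rng.standard_normal())
        atoms.append(
            Atom(
                "C",
                tuple(pos),
                float(rng.choice(radii)),
                charge_cycle[k % 4],
                name="CB",
                res_name="UNK",
                res_num=res_num,
            )
        )
        res_num += 1

    # lipid slab: two planes of apolar points at ±slab_z/2, square lattice
    axis_vals = np.arange(-slab_extent, slab_extent + 1e-9, slab_spacing)
    lipid = []
    for zsign in (+1.0, -1.0):
        z = zsign * slab_z / 2.0
        for x in axis_vals:
            for y in axis_vals:
                if zsign > 0 and math.hypot(x, y) < mouth_clearance:
                    continue  # hole over the pocket mouth, +z face only
                lipid.append((x, y, z))

    # reference ligand: jittered chain of points inside the pocket bowl
    n_ref = 6
    ref = np.zeros((n_ref, 3))
    for i in range(n_ref):
        ref[i] = (
            2.5 * math.cos(2.0 * math.pi * i / n_ref),
            2.5 * math.sin(2.0 * math.pi * i / n_ref),
            -3.0 + i * 0.8,
        )
    ref += 0.2 * rng.standard_normal(ref.shape)

    return ToyComplex(
        receptor=ReceptorModel(atoms),
        lipid_atoms=np.array(lipid),
        pocket_center=np.zeros(3),
        reference_ligand_atoms=ref,
        polar_targets=polar_targets,
    )


# ---------------------------------------------------------------------------
# Compound libraries with known composition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticLibrarySpec:
    n_total: int
    fraction_carboxylate: float = 0.5
    fraction_bioisostere: float = 0.2
    fraction_neutral: float = 0.2
    fraction_cation: float = 0.1
    mwt_range: tuple[float, float] = (120.0, 500.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mwt_range[0] > self.mwt_range[1]:
            raise ValueError("mwt_range must be ordered")
        fr = (
            self.fraction_carboxylate,
            self.fraction_bioisostere,
            self.fraction_neutral,
            self.fraction_cation,
        )
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if any(f < 0 for f in fr):
            raise ValueError("fractions must be non-negative")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


_CLASS_NAMES = ("carboxylate", "bioisostere", "neutral", "cation")

# decoration sets: para substituents guaranteed inert w.r.t. the acid
# patterns and the protonation rules; mixed light/heavy for MWT spread
_ARYL_SUBS = [
    "", "C", "c2ccc3ccccc3c2", "CC", "Oc2ccccc2", "F", "Cc2ccccc2",
    "Cl", "CCC", "C(F)(F)F", "OC", "CCCC", "C(C)C", "CCc2ccccc2",
]


def _carboxylate_smiles(i: int) -> str:
    k, sub = divmod(i, len(_ARYL_SUBS))
    s = _ARYL_SUBS[sub]
    aryl = f"c1ccc({s})cc1" if s else "c1ccccc1"
    return "OC(=O)" + "C" * k + aryl


def _bioisostere_smiles(i: int) -> str:
    templates = [
        lambda chain, aryl: f"{aryl}-c1nnn[nH]1" if not chain else f"C({chain}{aryl})c1nnn[nH]1",
        lambda chain, aryl: f"O=C({chain}{aryl})NS(C)(=O)=O",
        lambda chain, aryl: f"O=S(=O)(O){chain}{aryl}",
    ]
    t, rest = divmod(i, len(templates))
    k, sub = divmod(rest, len(_ARYL_SUBS))
    s = _ARYL_SUBS[sub]
    aryl = f"c1ccc({s})cc1" if s else "c1ccccc1"
    return templates[t % len(templates)]("C" * (k + t // len(templates)), aryl)


def _neutral_smiles(i: int) -> str:
    k, sub = divmod(i, len(_ARYL_SUBS))
    s = _ARYL_SUBS[sub]
    aryl = f"c1ccc({s})cn1" if s else "c1ccccn1"
    return "C(=O)(N(C)C)" + "C" * k + aryl


def _cation_smiles(i: int) -> str:
    k, sub = divmod(i, len(_ARYL_SUBS))
    s = _ARYL_SUBS[sub]
    aryl = f"c1ccc({s})cc1" if s else "c1ccccc1"
    return "NCC" + "C" * k + aryl


_CLASS_GENERATORS = {
    "carboxylate": _carboxylate_smiles,
    "bioisostere": _bioisostere_smiles,
    "neutral": _neutral_smiles,
    "cation": _cation_smiles,
}


def largest_remainder_counts(n_total: int, fractions: list[float]) -> list[int]:
    """Deterministic largest-remainder apportionment of n_total."""
    raw = [n_total * f for f in fractions]
    counts = [int(math.floor(r)) for r in raw]
    remainder = n_total - sum(counts)
    order = sorted(
        range(len(fractions)), key=lambda j: (-(raw[j] - counts[j]), j)
    )
    for j in order[:remainder]:
        counts[j] += 1
    return counts


def make_compound_library(spec: SyntheticLibrarySpec) -> list[CompoundRecord]:
    """Generate a library whose per-class composition matches the spec
    after largest-remainder rounding.

    Each molecule is built from a curated class template (so the pattern
    ground truth is known by construction), pH-7 protonated, and fully
    property-annotated.  The true class label is stored under
    ``extra["true_class"]``.
    """
    fractions = [
        spec.fraction_carboxylate,
        spec.fraction_bioisostere,
        spec.fraction_neutral,
        spec.fraction_cation,
    ]
    counts = largest_remainder_counts(spec.n_total, fractions)
    rng = np.random.default_rng(spec.seed)
    records: list[CompoundRecord] = []
    lo, hi = spec.mwt_range
    for cls, n_cls in zip(_CLASS_NAMES, counts):
        gen = _CLASS_GENERATORS[cls]
        made = 0
        candidate = 0
        limit = 50 * n_cls + 1000
        while made < n_cls:
            if candidate >= limit:
                raise ValueError(
                    f"cannot realize {n_cls} {cls} molecules inside MWT "
                    f"range {spec.mwt_range}"
                )
            neutral_smiles = gen(candidate)
            candidate += 1
            charged, q = assign_protonation(neutral_smiles)
            rec = compute_properties(charged, mol_id=f"{cls}_{made:05d}")
            if not (lo <= rec.mwt <= hi):
                continue
            rec.extra["true_class"] = cls
            rec.extra["neutral_smiles"] = neutral_smiles
            records.append(rec)
            made += 1
    # deterministic interleave so class blocks do not trivially order
    perm = rng.permutation(len(records))
    return [records[j] for j in perm]


# ---------------------------------------------------------------------------
# Planted enrichment benchmark
# ---------------------------------------------------------------------------

def make_planted_benchmark(
    n_ligands: int = 21,
    n_decoys: int = 658,
    score_gap: float = 3.0,
    seed: int = 0,
    score_sd: float = 1.0,
) -> list[tuple[float, bool]]:
    """Labelled docking-score list with ligand scores shifted ``score_gap``
    below (better than) the decoy distribution.

    Scores are docking energies: lower is better.  ``score_gap = inf``
    yields complete separation.  Returns ``(score, is_ligand)`` tuples,
    ligands first; deterministic for a fixed seed.
    """
    if n_ligands <= 0 or n_decoys <= 0:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    decoys = rng.normal(0.0, score_sd, n_decoys)
    if math.isinf(score_gap):
        ligands = -1e6 + rng.normal(0.0, score_sd, n_ligands)
    else:
        ligands = rng.normal(-score_gap, score_sd, n_ligands)
    return [(float(s), True) for s in ligands] + [
        (float(s), False) for s in decoys
    ]


# ---------------------------------------------------------------------------
# 4PL assay data
# ---------------------------------------------------------------------------

def make_dose_response(
    true_ic50: float,
    hill: float = 1.0,
    top: float = 100.0,
    bottom: float = 0.0,
    concentrations: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    model: str = "inhibition",
    replicates: int = 3,
) -> DoseResponse:
    """Responses on an exact 4PL curve plus additive Gaussian noise
    (``noise_sd`` in % of control; 0 gives exact curve values).

    The emulated design is the standard plate layout: each concentration
    measured in ``replicates`` independent wells (noise drawn per well).
    """
    if true_ic50 <= 0:
        raise ValueError("true_ic50 must be positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if concentrations is None:
        # standard half-log dilution series bracketing the midpoint
        concentrations = true_ic50 * np.logspace(-3, 3, 13)
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be positive and strictly increasing")
    from .pharmacology import four_pl

    conc_all = np.repeat(conc, replicates)
    groups = np.tile(np.arange(replicates), len(conc))
    y = four_pl(conc_all, math.log10(true_ic50), hill, top, bottom, model)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, len(conc_all))
    return DoseResponse(concentrations=conc_all, responses=y, groups=groups)


# ---------------------------------------------------------------------------
# One-compartment PK profiles
# ---------------------------------------------------------------------------

def make_pk_profile(
    dose: float,
    route: str,
    ka: float,
    ke: float,
    vd: float,
    f_true: float = 1.0,
    lloq: float = 10.0,
    timepoints: np.ndarray | None = None,
    seed: int = 0,
    noise_cv: float = 0.0,
) -> PKProfile:
    """One-compartment concentration-time profile with LLOQ censoring.

    iv bolus: C(t) = (dose·10⁶ / Vd)·exp(−ke·t); oral or ip: the Bateman
    form scaled by the absorbed fraction ``f_true``.  Units: dose mg/kg,
    Vd ml/kg, concentrations ng/ml, rate constants 1/min.  Samples below
    ``lloq`` are reported censored.  Optional multiplicative log-normal
    noise with coefficient of variation ``noise_cv``.
    """
    if route not in ("iv", "oral", "ip"):
        raise ValueError(f"unknown route {route!r}")
    if dose <= 0 or ka <= 0 or ke <= 0 or vd <= 0:
        raise ValueError("dose, ka, ke and Vd must be positive")
    if not (0.0 <= f_true <= 1.0):
        raise ValueError("f_true must lie in [0, 1]")
    if route in ("oral", "ip") and abs(ka - ke) < 1e-12:
        raise ValueError("ka must differ from ke (degenerate Bateman form)")
    if timepoints is None:
        timepoints = np.array([5, 15, 30, 60, 120, 240, 360, 480, 1440], dtype=float)
    t = np.asarray(timepoints, dtype=float)

    c0 = dose * 1e6 / vd  # mg/kg -> ng, per ml/kg
    if route == "iv":
        conc = c0 * np.exp(-ke * t)
    else:
        conc = (
            f_true * c0 * ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))
        )
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        conc = conc * rng.lognormal(-0.5 * sigma**2, sigma, len(t))
    censored = conc < lloq
    return PKProfile(
        timepoints=t,
        concentrations=np.where(censored, 0.0, conc),
        censored=censored,
        lloq=lloq,
        dose=dose,
        route=route,  # type: ignore[arg-type]
    )
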