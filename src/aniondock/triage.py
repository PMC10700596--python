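"""Hit-picking cascade over ranked docking output.

Stages mirror the screen's triage order: top-N selection, greedy
fingerprint leader clustering (structural diversity), novelty filtering
against known ligands, torsion-strain filtering of docked poses, and
codified required-interaction checks standing in for visual inspection.
Every stage logs its in/out counts and rejected ids so the full cascade
telescopes into an auditable report.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdMolTransforms

from .libprep import CompoundRecord, compute_properties, tanimoto
from .receptor import ReceptorModel


# ---------------------------------------------------------------------------
# Report plumbing
# ---------------------------------------------------------------------------

@dataclass
class TriageStage:
    name: str
    parameters: dict
    in_count: int
    out_count: int
    rejected_ids: list[str]


@dataclass
class TriageReport:
    input_size: int
    stages: list[TriageStage] = field(default_factory=list)
    survivors: list[str] = field(default_factory=list)

    def log(self, name: str, parameters: dict, in_ids: Sequence[str],
            out_ids: Sequence[str]) -> None:
        rejected = [i for i in in_ids if i not in set(out_ids)]
        self.stages.append(
            TriageStage(name, parameters, len(in_ids), len(out_ids), rejected)
        )
        self.survivors = list(out_ids)

    def validate(self) -> None:
        """Stage counts must telescope and rejected ∪ survivors = input."""
        for k in range(1, len(self.stages)):
            if self.stages[k].in_count != self.stages[k - 1].out_count:
                raise AssertionError(
                    f"stage {k} in-count {self.stages[k].in_count} != "
                    f"stage {k-1} out-count {self.stages[k-1].out_count}"
                )
        for st in self.stages:
            if st.in_count != st.out_count + len(st.rejected_ids):
                raise AssertionError(f"stage {st.name} counts do not add up")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "input_size": self.input_size,
            "stages": [
                {
                    "name": s.name,
                    "parameters": s.parameters,
                    "in_count": s.in_count,
                    "out_count": s.out_count,
                    "rejected_ids": s.rejected_ids,
                }
                for s in self.stages
            ],
            "survivors": self.survivors,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# Greedy fingerprint clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    heads: list[CompoundRecord]
    assignments: dict[str, str]   # record id -> head id


def cluster_by_fingerprint(
    ranked_records: Sequence[CompoundRecord], tc_cutoff: float = 0.5
) -> ClusterResult:
    """Greedy leader clustering in rank order.

    Records must arrive best-score-first.  Each record joins the first
    existing cluster head with Tanimoto >= ``tc_cutoff`` (inclusive), else
    founds a new cluster — so heads are each cluster's best-scoring member
    by construction and remain pairwise below the cutoff.
    """
    heads: list[CompoundRecord] = []
    assignments: dict[str, str] = {}
    for rec in ranked_records:
        placed = False
        for head in heads:
            if tanimoto(rec.fingerprint, head.fingerprint) >= tc_cutoff:
                assignments[rec.id] = head.id
                placed = True
                break
        if not placed:
            heads.append(rec)
            assignments[rec.id] = rec.id
    return ClusterResult(heads=heads, assignments=assignments)


# ---------------------------------------------------------------------------
# Novelty filter
# ---------------------------------------------------------------------------

@dataclass
class NoveltyResult:
    retained: list[CompoundRecord]
    removed: dict[str, tuple[str, float]]  # id -> (offending known id, Tc)


def novelty_filter(
    heads: Sequence[CompoundRecord],
    known_ligands: Sequence[tuple[str, str]] | Sequence[str],
    tc_cutoff: float = 0.35,
) -> NoveltyResult:
    """Remove heads with Tc >= ``tc_cutoff`` (inclusive) to any known
    ligand; the offending known ligand and similarity are logged.  An
    empty known set retains everything (with a warning)."""
    import warnings

    known: list[tuple[str, object]] = []
    for i, item in enumerate(known_ligands):
        if isinstance(item, tuple):
            kid, smi = item
        else:
            kid, smi = f"known{i}", item
        known.append((kid, compute_properties(smi, mol_id=kid).fingerprint))
    if not known:
        warnings.warn("empty known-ligand set: novelty filter retains all heads")
        return NoveltyResult(list(heads), {})
    retained = []
    removed = {}
    for rec in heads:
        sims = [(tanimoto(rec.fingerprint, fp), kid) for kid, fp in known]
        best_tc, best_id = max(sims)
        if best_tc >= tc_cutoff:
            removed[rec.id] = (best_id, best_tc)
        else:
            retained.append(rec)
    return NoveltyResult(retained, removed)


# ---------------------------------------------------------------------------
# Torsion strain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TorsionRule:
    """A dihedral SMARTS (4 mapped atoms; the rotor is the central bond)
    with a piecewise-linear strain profile in torsion energy units (TEU)
    over the folded angle range [0°, 180°]."""

    rule_id: str
    smarts: str
    profile: tuple[tuple[float, float], ...]   # (angle°, TEU), sorted

    def teu_at(self, angle_deg: float) -> float:
        a = abs(((angle_deg + 180.0) % 360.0) - 180.0)  # fold to [0, 180]
        angles = [p[0] for p in self.profile]
        teus = [p[1] for p in self.profile]
        if a <= angles[0]:
            return teus[0]
        if a >= angles[-1]:
            return teus[-1]
        j = bisect_right(angles, a)
        t = (a - angles[j - 1]) / (angles[j] - angles[j - 1])
        return teus[j - 1] + t * (teus[j] - teus[j - 1])


#: Built-in strain rules for the common rotor chemotypes.  First-match
#: precedence in this order; the table is overridable from TSV.
DEFAULT_TORSION_RULES: tuple[TorsionRule, ...] = (
    TorsionRule(
        "amide_cis_trans",
        "[OX1]=[CX3]!@[NX3][#6]",
        ((0.0, 3.0), (90.0, 4.0), (180.0, 0.0)),
    ),
    TorsionRule(
        "ester",
        "[OX1]=[CX3]!@[OX2][#6]",
        ((0.0, 2.0), (90.0, 4.5), (180.0, 0.0)),
    ),
    TorsionRule(
        "biaryl",
        "[c][c]-!@[c][c]",
        ((0.0, 1.6), (40.0, 0.0), (90.0, 0.8), (140.0, 0.0), (180.0, 1.6)),
    ),
    TorsionRule(
        "alpha_carbonyl",
        "[OX1]=[CX3]!@[CX4][#6]",
        ((0.0, 0.2), (90.0, 1.0), (180.0, 0.2)),
    ),
)


def load_torsion_rules(path: str | Path) -> tuple[TorsionRule, ...]:
    """TSV columns: rule_id, SMARTS, profile as 'angle:teu,angle:teu,...'."""
    rules = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rule_id, smarts, prof = line.split("\t")[:3]
        profile = tuple(
            (float(a), float(t))
            for a, t in (pair.split(":") for pair in prof.split(","))
        )
        rules.append(TorsionRule(rule_id, smarts, profile))
    return tuple(rules)


@dataclass
class StrainResult:
    per_dihedral: list[tuple[str, float, float]]   # (rule id, angle°, TEU)
    uncovered_bonds: list[tuple[int, int]]

    @property
    def max_teu(self) -> float:
        return max((t for _, _, t in self.per_dihedral), default=0.0)


_ROTATABLE = Chem.MolFromSmarts("[!$(*#*)&!D1]-!@[!$(*#*)&!D1]")


def compute_strain(
    mol: Chem.Mol,
    rules: Sequence[TorsionRule] = DEFAULT_TORSION_RULES,
    conf_id: int = -1,
) -> StrainResult:
    """Per-rotatable-dihedral TEU lookup on a 3D pose.

    Each rotatable bond takes the TEU of the first rule (in table order)
    whose dihedral pattern spans it, evaluated at the pose's dihedral
    angle; bonds no rule covers score 0 and are reported uncovered.
    """
    if mol.GetNumConformers() == 0:
        raise ValueError("molecule has no 3D conformer")
    conf = mol.GetConformer(conf_id)
    rot_bonds = {
        tuple(sorted(m)) for m in mol.GetSubstructMatches(_ROTATABLE)
    }
    per_dihedral: list[tuple[str, float, float]] = []
    covered: set[tuple[int, int]] = set()
    for rule in rules:
        q = Chem.MolFromSmarts(rule.smarts)
        for match in mol.GetSubstructMatches(q):
            a, b, c, d = match[:4]
            bond = tuple(sorted((b, c)))
            if bond not in rot_bonds or bond in covered:
                continue
            covered.add(bond)
            angle = rdMolTransforms.GetDihedralDeg(conf, a, b, c, d)
            per_dihedral.append((rule.rule_id, angle, rule.teu_at(angle)))
    uncovered = sorted(rot_bonds - covered)
    return StrainResult(per_dihedral=per_dihedral, uncovered_bonds=uncovered)


def strain_filter(
    posed_records: Sequence[tuple[str, Chem.Mol]],
    rules: Sequence[TorsionRule] = DEFAULT_TORSION_RULES,
    teu_cutoff: float = 1.5,
) -> tuple[list[str], dict[str, StrainResult]]:
    """Keep records whose single most strained dihedral is <= ``teu_cutoff``
    (inclusive).  Returns (retained ids, per-record strain results)."""
    retained = []
    results = {}
    for rec_id, mol in posed_records:
        sr = compute_strain(mol, rules)
        results[rec_id] = sr
        if sr.max_teu <= teu_cutoff:
            retained.append(rec_id)
    return retained, results


# ---------------------------------------------------------------------------
# Required-interaction checks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LigandAtom:
    element: str
    coords: tuple[float, float, float]
    formal_charge: int = 0


@dataclass(frozen=True)
class Contact:
    residue: int
    contact_type: str            # "hbond" | "ionic"
    distance: float              # Å, heavy-atom
    angle: float | None          # °, donor angle for hbonds


HBOND_DIST_MAX = 3.5     # Å heavy-atom donor-acceptor (inclusive)
HBOND_ANGLE_MIN = 120.0  # ° at the donor hydrogen (inclusive)
IONIC_DIST_MAX = 4.0     # Å heavy-atom (inclusive)
IONIC_MIN_PARTIAL = 0.5  # |e| for a receptor atom to count as charged


def _angle_deg(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    v1, v2 = p0 - p1, p2 - p1
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def interaction_filter(
    ligand_atoms: Sequence[LigandAtom],
    ligand_bonds: Sequence[tuple[int, int]],
    receptor: ReceptorModel,
    required: Sequence[tuple[int, str]],
) -> tuple[bool, list[Contact]]:
    """Check that the pose forms every required contact.

    ``required`` lists ``(residue number, "hbond" | "ionic")``.  Hydrogen
    bonds need a ligand or receptor N/O donor bearing a hydrogen, a
    partner N/O acceptor, heavy-atom distance <= 3.5 Å and an angle at the
    donor hydrogen >= 120° (both inclusive).  Ionic contacts need opposite
    formal charges within 4.0 Å; receptor atoms with |partial charge| >=
    0.5 e count as formally charged.  A required residue missing from the
    receptor raises ``KeyError``.
    """
    lig_xyz = np.array([a.coords for a in ligand_atoms], dtype=float)
    neighbors: dict[int, list[int]] = {}
    for i, j in ligand_bonds:
        neighbors.setdefault(i, []).append(j)
        neighbors.setdefault(j, []).append(i)

    contacts: list[Contact] = []
    satisfied: set[tuple[int, str]] = set()
    for res_num, ctype in required:
        res_atoms = receptor.atoms_of_residue(res_num)
        if not res_atoms:
            raise KeyError(f"required residue {res_num} absent from receptor")
        found = None
        if ctype == "ionic":
            for li, la in enumerate(ligand_atoms):
                if la.formal_charge == 0 or la.element == "H":
                    continue
                for ra in res_atoms:
                    if ra.element == "H" and abs(ra.charge) < IONIC_MIN_PARTIAL:
                        continue
                    if abs(ra.charge) < IONIC_MIN_PARTIAL:
                        continue
                    if la.formal_charge * ra.charge >= 0:
                        continue
                    d = float(np.linalg.norm(lig_xyz[li] - np.asarray(ra.coords)))
                    if d <= IONIC_DIST_MAX:
                        found = Contact(res_num, "ionic", d, None)
                        break
                if found:
                    break
        elif ctype == "hbond":
            # ligand donor -> receptor acceptor
            for li, la in enumerate(ligand_atoms):
                if la.element not in ("N", "O"):
                    continue
                h_idx = [
                    k for k in neighbors.get(li, ())
                    if ligand_atoms[k].element == "H"
                ]
                for ra in res_atoms:
                    if ra.element not in ("N", "O"):
                        continue
                    d = float(np.linalg.norm(lig_xyz[li] - np.asarray(ra.coords)))
                    if d > HBOND_DIST_MAX:
                        continue
                    for hk in h_idx:
                        ang = _angle_deg(
                            lig_xyz[li], lig_xyz[hk], np.asarray(ra.coords)
                        )
                        if ang >= HBOND_ANGLE_MIN:
                            found = Contact(res_num, "hbond", d, ang)
                            break
                    if found:
                        break
                if found:
                    break
            # receptor donor (H attached to the residue) -> ligand acceptor
            if not found:
                res_h = [a for a in res_atoms if a.element == "H"]
                res_heavy = [a for a in res_atoms if a.element in ("N", "O")]
                for h in res_h:
                    donors = sorted(
                        res_heavy,
                        key=lambda a: np.linalg.norm(
                            np.asarray(a.coords) - np.asarray(h.coords)
                        ),
                    )
                    if not donors:
                        continue
                    dheavy = np.asarray(donors[0].coords)
                    for li, la in enumerate(ligand_atoms):
                        if la.element not in ("N", "O"):
                            continue
                        d = float(np.linalg.norm(lig_xyz[li] - dheavy))
                        if d > HBOND_DIST_MAX:
                            continue
                        ang = _angle_deg(
                            dheavy, np.asarray(h.coords), lig_xyz[li]
                        )
                        if ang >= HBOND_ANGLE_MIN:
                            found = Contact(res_num, "hbond", d, ang)
                            break
                    if found:
                        break
        else:
            raise ValueError(f"unknown contact type {ctype!r}")
        if found:
            contacts.append(found)
            satisfied.add((res_num, ctype))
    ok = all((r, t) in satisfied for r, t in required)
    return ok, contacts
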