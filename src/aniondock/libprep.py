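"""Screening-library construction.

Harvests anions from SMILES streams by carboxylate/bioisostere substructure
patterns, assigns rule-based pH-7 protonation states, computes the
properties and fingerprints every downstream stage consumes, applies
lead-like property filters, and enumerates synthesizable analogs by
building-block decomposition and re-coupling.

The bioisostere pattern table shipped here is a curated stand-in covering
the common acidic carboxylate surrogates (tetrazole, acylsulfonamide,
hydroxamic acid, sulfonic/sulfinic/phosphonic acids, squaramide,
oxadiazolone, thiazolidinedione, hydroxyisoxazole, ...); it is fully
overridable from a TSV file so an exact external pattern set can be
substituted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, Crippen, DataStructs, Descriptors, rdMolDescriptors
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CompoundRecord:
    """A property-annotated library member."""

    id: str
    smiles: str
    mwt: float
    clogp: float
    net_charge: int
    heavy_atoms: int
    rotatable_bonds: int
    hbd: int
    hba: int
    fingerprint: object            # RDKit ExplicitBitVect (radius-2, 2048 bits)
    matched_patterns: list[str] = field(default_factory=list)
    charge_class: str = ""
    extra: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PatternEntry:
    pattern_id: str
    smarts: str
    pattern_class: str             # "carboxylate" | "bioisostere"


class PatternTable:
    """Validated SMARTS pattern set with unique ids."""

    def __init__(self, entries: Sequence[PatternEntry]):
        ids = [e.pattern_id for e in entries]
        if len(set(ids)) != len(ids):
            raise ValueError("pattern ids must be unique")
        self.entries = list(entries)
        self._mols = {}
        for e in entries:
            q = Chem.MolFromSmarts(e.smarts)
            if q is None:
                raise ValueError(f"SMARTS for pattern {e.pattern_id!r} does not parse")
            self._mols[e.pattern_id] = q

    def query(self, pattern_id: str):
        return self._mols[pattern_id]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PatternTable":
        entries = []
        with open(path) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                entries.append(PatternEntry(row[0], row[1], row[2]))
        return cls(entries)


#: Default acidic-fragment patterns.  Each matches both the neutral acid
#: and its conjugate base so harvesting is protonation-state independent.
DEFAULT_PATTERNS = PatternTable(
    [
        PatternEntry("carboxylate", "[CX3](=[OX1])[OX2H1,OX1-]", "carboxylate"),
        PatternEntry("tetrazole", "c1nnn[nH,n-]1", "bioisostere"),
        PatternEntry(
            "acylsulfonamide",
            "[CX3](=[OX1])[NX3H1,NX2-][SX4](=[OX1])(=[OX1])",
            "bioisostere",
        ),
        PatternEntry(
            "hydroxamic_acid", "[CX3](=[OX1])[NX3H1][OX2H1,OX1-]", "bioisostere"
        ),
        PatternEntry(
            "sulfonamide_nh",
            "[SX4](=[OX1])(=[OX1])([#6])[NX3H1,NX2-][#6]",
            "bioisostere",
        ),
        PatternEntry("sulfonic_acid", "[SX4](=[OX1])(=[OX1])[OX2H1,OX1-]", "bioisostere"),
        PatternEntry("sulfinic_acid", "[SX3](=[OX1])[OX2H1,OX1-]", "bioisostere"),
        PatternEntry(
            "phosphonic_acid", "[PX4](=[OX1])([OX2H1,OX1-])[OX2H1,OX1-,OX2]", "bioisostere"
        ),
        PatternEntry(
            "squaramide",
            "[#8X1]=[#6]1~[#6](=[#8X1])~[#6](~[#7X3])~[#6]~1~[#7X3]",
            "bioisostere",
        ),
        PatternEntry(
            "oxadiazolone",
            "[#8X1]=[#6]1~[#8]~[#7]~[#6]~[#7X3H1,#7X2-]~1",
            "bioisostere",
        ),
        PatternEntry(
            "thiazolidinedione", "O=C1CSC(=O)[NX3H1,NX2-]1", "bioisostere"
        ),
        PatternEntry(
            "hydroxyisoxazole", "[OX2H1,OX1-]c1ccon1", "bioisostere"
        ),
    ]
)


# ---------------------------------------------------------------------------
# Harvesting
# ---------------------------------------------------------------------------

@dataclass
class HarvestResult:
    records: list[CompoundRecord]
    class_counts: dict[str, int]
    n_rejected_parse: int


def harvest_acids(
    smiles_stream: Iterable[tuple[str, str] | str],
    patterns: PatternTable = DEFAULT_PATTERNS,
) -> HarvestResult:
    """Retain molecules matching at least one acidic pattern.

    ``smiles_stream`` yields SMILES strings or ``(id, smiles)`` pairs.
    Matched pattern ids are recorded per molecule; a molecule counts once
    per pattern *class* (carboxylate beats bioisostere when both match,
    mirroring class-exclusive composition reporting).  Unparseable SMILES
    are skipped and tallied.
    """
    records: list[CompoundRecord] = []
    class_counts: dict[str, int] = {}
    rejects = 0
    for i, item in enumerate(smiles_stream):
        if isinstance(item, tuple):
            mol_id, smi = item
        else:
            mol_id, smi = f"mol{i}", item
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            rejects += 1
            continue
        matched = [
            e.pattern_id for e in patterns if mol.HasSubstructMatch(patterns.query(e.pattern_id))
        ]
        if not matched:
            continue
        rec = compute_properties(smi, mol_id=mol_id)
        rec.matched_patterns = matched
        records.append(rec)
        classes = {e.pattern_class for e in patterns if e.pattern_id in matched}
        cls = "carboxylate" if "carboxylate" in classes else sorted(classes)[0]
        class_counts[cls] = class_counts.get(cls, 0) + 1
    return HarvestResult(records, class_counts, rejects)


# ---------------------------------------------------------------------------
# pH-7 protonation rules
# ---------------------------------------------------------------------------

# (name, SMARTS with the titratable atom as match position 0, charge shift,
#  group position).  Applied in order; each rule fires on every match except
#  that matches sharing the atom at ``group position`` fire once (e.g. a
#  phosphonic acid loses only its first proton at pH 7).
_PROTONATION_RULES: list[tuple[str, str, int, int | None]] = [
    ("carboxylic_acid", "[OX2H1][CX3]=[OX1]", -1, None),
    ("sulfonic_acid", "[OX2H1][SX4](=[OX1])=[OX1]", -1, None),
    ("sulfinic_acid", "[OX2H1][SX3]=[OX1]", -1, None),
    # only the first proton leaves at pH 7 (pKa2 above neutrality); the
    # !$(P[O-]) guard keeps the rule idempotent on the monoanion
    ("phosphonic_acid_1", "[OX2H1][PX4;!$([P][OX1-])](=[OX1])", -1, 1),
    ("tetrazole", "[nH]1nnnc1", -1, None),
    ("acylsulfonamide", "[NX3H1]([CX3]=[OX1])[SX4](=[OX1])=[OX1]", -1, None),
    (
        "aliphatic_amine",
        "[NX3;H2,H1,H0;+0;!$([N]C=[O,S,N]);!$([N]S(=O)=O);!$([N]a);!$([N]=*);"
        "!$([N][O,N])]",
        +1,
        None,
    ),
    ("amidinium", "[NX2;+0]=[CX3]([NX3])", +1, None),
]

_PROTONATION_QUERIES = [
    (name, Chem.MolFromSmarts(smarts), shift, group)
    for name, smarts, shift, group in _PROTONATION_RULES
]


def assign_protonation(smiles: str, ph: float = 7.0) -> tuple[str, int]:
    """Rule-based pH-7 protonation: strong acids lose a proton, aliphatic
    amines/amidines gain one.  Molecules matching no rule pass through
    unchanged.  Idempotent: charged products match none of the neutral-form
    rules.  Returns ``(canonical charged SMILES, net formal charge)``.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    # pH is accepted for interface completeness; the rule set encodes pH 7.
    rw = Chem.RWMol(mol)
    for name, query, shift, group in _PROTONATION_QUERIES:
        if query is None:
            raise RuntimeError(f"internal protonation SMARTS {name} invalid")
        seen_groups: set[int] = set()
        for match in rw.GetMol().GetSubstructMatches(query):
            if group is not None:
                if match[group] in seen_groups:
                    continue
                seen_groups.add(match[group])
            atom = rw.GetAtomWithIdx(match[0])
            if shift < 0:
                if atom.GetFormalCharge() != 0:
                    continue
                atom.SetFormalCharge(-1)
                atom.SetNumExplicitHs(max(atom.GetTotalNumHs() - 1, 0))
                atom.SetNoImplicit(True)
            else:
                if atom.GetFormalCharge() != 0:
                    continue
                atom.SetFormalCharge(+1)
                atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
                atom.SetNoImplicit(True)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out), Chem.GetFormalCharge(out)


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------

def charge_class(net_charge: int) -> str:
    """Bucket a net formal charge into the screening composition classes."""
    if net_charge <= -2:
        return "<=-2"
    return {-1: "-1", 0: "0", 1: "+1"}.get(net_charge, f"{net_charge:+d}")


def compute_properties(smiles: str, mol_id: str = "") -> CompoundRecord:
    """Property-annotate one molecule.

    MWT is the average-isotope molecular weight; clogP the Crippen
    atomic-contribution estimate; the fingerprint a radius-2 2048-bit
    circular bit vector.  Deterministic for a given SMILES.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    q = Chem.GetFormalCharge(mol)
    return CompoundRecord(
        id=mol_id or Chem.MolToSmiles(mol),
        smiles=Chem.MolToSmiles(mol),
        mwt=Descriptors.MolWt(mol),
        clogp=Crippen.MolLogP(mol),
        net_charge=q,
        heavy_atoms=mol.GetNumHeavyAtoms(),
        rotatable_bonds=rdMolDescriptors.CalcNumRotatableBonds(mol),
        hbd=rdMolDescriptors.CalcNumHBD(mol),
        hba=rdMolDescriptors.CalcNumHBA(mol),
        fingerprint=_MORGAN.GetFingerprint(mol),
        charge_class=charge_class(q),
    )


def tanimoto(fp1, fp2) -> float:
    return DataStructs.TanimotoSimilarity(fp1, fp2)


# ---------------------------------------------------------------------------
# Lead-like filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterResult:
    passed: list[CompoundRecord]
    rejection_counts: dict[str, int]


def filter_leadlike(
    records: Sequence[CompoundRecord],
    mwt_range: tuple[float, float] | None = (250.0, 400.0),
    clogp_range: tuple[float, float] | None = None,
    allowed_charges: set[int] | None = frozenset({-2, -1, 0}),
) -> FilterResult:
    """Keep records satisfying all property predicates; boundaries inclusive.

    ``allowed_charges`` containing −2 admits every charge ≤ −2 (the anion
    screens exclude cations but keep polyanions).  A rejected record is
    counted under the first failing rule, in order MWT → clogP → charge,
    so the counts sum to the number rejected.
    """
    if mwt_range is not None and mwt_range[0] > mwt_range[1]:
        raise ValueError("mwt_range must be ordered")
    if clogp_range is not None and clogp_range[0] > clogp_range[1]:
        raise ValueError("clogp_range must be ordered")
    passed: list[CompoundRecord] = []
    counts = {"mwt": 0, "clogp": 0, "charge": 0}

    def charge_ok(q: int) -> bool:
        if allowed_charges is None:
            return True
        return q in allowed_charges or (q <= -2 and -2 in allowed_charges)

    for r in records:
        if mwt_range is not None and not (mwt_range[0] <= r.mwt <= mwt_range[1]):
            counts["mwt"] += 1
        elif clogp_range is not None and not (
            clogp_range[0] <= r.clogp <= clogp_range[1]
        ):
            counts["clogp"] += 1
        elif not charge_ok(r.net_charge):
            counts["charge"] += 1
        else:
            passed.append(r)
    return FilterResult(passed, counts)


# ---------------------------------------------------------------------------
# Analog enumeration from building blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReactionScheme:
    """A make-on-demand coupling: a retro transform cutting the product into
    role-labelled reagents and the forward transform re-coupling them."""

    scheme_id: str
    retro_smarts: str            # product >> fragment.fragment
    forward_smarts: str          # fragment.fragment >> product
    roles: tuple[str, str]


AMIDE_COUPLING = ReactionScheme(
    scheme_id="amide",
    retro_smarts="[CX3:1](=[OX1:2])[NX3;!$(N(C=O)C=O):3]>>[C:1](=[O:2])[OX2H1].[N:3]",
    forward_smarts="[CX3:1](=[OX1:2])[OX2H1].[NX3;H2,H1;!$(NC=O):3]>>[C:1](=[O:2])[N:3]",
    roles=("acid", "amine"),
)

ARYL_AMINATION = ReactionScheme(
    scheme_id="aryl_amination",
    retro_smarts="[c:1][NX3;H1,H0;!$(NC=O):2]>>[c:1]Cl.[N:2]",
    forward_smarts="[c:1]Cl.[NX3;H2,H1;!$(NC=O):2]>>[c:1][N:2]",
    roles=("aryl_halide", "amine"),
)


def _canon(mol) -> str:
    return Chem.MolToSmiles(mol)


def decompose_product(product_smiles: str, scheme: ReactionScheme) -> dict[str, str]:
    """Retro-cut a product into its role-labelled building blocks.

    The product must contain the scheme's cut pattern exactly once;
    zero or multiple cut sites raise ``ValueError``.
    """
    mol = Chem.MolFromSmiles(product_smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {product_smiles!r}")
    rxn = AllChem.ReactionFromSmarts(scheme.retro_smarts)
    pattern = rxn.GetReactantTemplate(0)
    n_sites = len(mol.GetSubstructMatches(pattern))
    if n_sites != 1:
        raise ValueError(
            f"scheme {scheme.scheme_id!r} requires exactly one cut site; "
            f"found {n_sites} in {product_smiles!r}"
        )
    products = rxn.RunReactants((mol,))
    frags = products[0]
    out = {}
    for role, frag in zip(scheme.roles, frags):
        Chem.SanitizeMol(frag)
        out[role] = _canon(frag)
    return out


def enumerate_analogs(
    scheme: ReactionScheme,
    reagent_pools: dict[str, Sequence[str]],
) -> list[str]:
    """Forward cross-product enumeration over the reagent pools.

    Products are canonicalized and deduplicated preserving first-seen
    order; with structurally distinct pools the count equals the product
    of the pool sizes.
    """
    rxn = AllChem.ReactionFromSmarts(scheme.forward_smarts)
    pools = []
    for role in scheme.roles:
        mols = []
        for smi in reagent_pools[role]:
            m = Chem.MolFromSmiles(smi)
            if m is None:
                raise ValueError(f"unparseable reagent SMILES: {smi!r}")
            mols.append(m)
        pools.append(mols)
    seen: dict[str, None] = {}
    for a in pools[0]:
        for b in pools[1]:
            for prod_set in rxn.RunReactants((a, b)):
                p = prod_set[0]
                try:
                    Chem.SanitizeMol(p)
                except Exception:
                    continue
                seen.setdefault(_canon(p), None)
    return list(seen)


def decompose_and_enumerate(
    product_smiles: str,
    scheme: ReactionScheme,
    reagent_pools: dict[str, Sequence[str]],
) -> list[str]:
    """Retro-cut the hit, then enumerate all pool cross-products.

    When the original fragments are present in the pools the original
    product reappears in the output (round-trip property of the scheme).
    """
    decompose_product(product_smiles, scheme)  # validates single cut site
    return enumerate_analogs(scheme, reagent_pools)


# ---------------------------------------------------------------------------
# SMILES / SDF I/O
# ---------------------------------------------------------------------------

def read_smi(path: str | Path) -> list[tuple[str, str]]:
    """Whitespace-separated SMILES file: ``SMILES id`` per line."""
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        parts = line.split()
        if not parts:
            continue
        smi = parts[0]
        mol_id = parts[1] if len(parts) > 1 else f"mol{i}"
        out.append((mol_id, smi))
    return out


def write_smi(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    """Write ``(id, smiles)`` pairs as ``SMILES id`` lines."""
    with open(path, "w") as fh:
        for mol_id, smi in records:
            fh.write(f"{smi} {mol_id}\n")


def write_sdf(path: str | Path, records: Sequence[CompoundRecord]) -> None:
    writer = Chem.SDWriter(str(path))
    for r in records:
        mol = Chem.MolFromSmiles(r.smiles)
        mol.SetProp("_Name", r.id)
        mol.SetProp("net_charge", str(r.net_charge))
        writer.write(mol)
    writer.close()
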