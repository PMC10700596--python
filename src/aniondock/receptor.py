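"""Receptor representation and polar-charge perturbation.

A receptor is a rigid collection of point atoms carrying coordinates (Å),
a hard-sphere radius (Å) and a partial charge (e).  Charges and radii are
either constructed programmatically (toy complexes) or read from a
whitespace-delimited parameter table keyed by residue and atom name, since
PDB files carry neither.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True)
class Atom:
    """A single receptor atom (united-atom convention: no apolar hydrogens)."""

    element: str
    coords: tuple[float, float, float]
    radius: float
    charge: float
    name: str = ""
    res_name: str = ""
    res_num: int = 0
    chain: str = "A"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"atom radius must be positive, got {self.radius}")


@dataclass
class ReceptorModel:
    """Rigid receptor: atoms with coordinates, radii and partial charges."""

    atoms: list[Atom]

    @property
    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    def atoms_of_residue(self, res_num: int, chain: str | None = None) -> list[Atom]:
        return [
            a
            for a in self.atoms
            if a.res_num == res_num and (chain is None or a.chain == chain)
        ]

    def find_atom(self, res_num: int, atom_name: str, chain: str | None = None) -> int:
        for i, a in enumerate(self.atoms):
            if (
                a.res_num == res_num
                and a.name == atom_name
                and (chain is None or a.chain == chain)
            ):
                return i
        raise KeyError(
            f"residue {res_num} has no atom named {atom_name!r}"
            + (f" on chain {chain}" if chain else "")
        )

    def translated(self, shift: Sequence[float]) -> "ReceptorModel":
        s = np.asarray(shift, dtype=float)
        return ReceptorModel(
            [replace(a, coords=tuple(np.asarray(a.coords) + s)) for a in self.atoms]
        )


def perturb_polar_charges(
    receptor: ReceptorModel,
    targets: Iterable[tuple[int, str, str]],
    delta: float = 0.4,
) -> ReceptorModel:
    """Shift charge between a side-chain hydroxyl hydrogen and the backbone
    carbonyl oxygen of the same residue.

    For each target ``(res_num, hydroxyl_h_name, backbone_o_name)`` the
    hydroxyl hydrogen gains ``delta`` elementary charge units and the
    backbone oxygen loses the same amount, strengthening the local dipole
    while leaving the per-residue and total net charge unchanged.  This is
    the anion-recognition tweak applied to pocket residues before grid
    generation.

    Raises
    ------
    KeyError
        If a target residue lacks either named atom.
    """
    atoms = list(receptor.atoms)
    for res_num, h_name, o_name in targets:
        hi = receptor.find_atom(res_num, h_name)
        oi = receptor.find_atom(res_num, o_name)
        atoms[hi] = replace(atoms[hi], charge=atoms[hi].charge + delta)
        atoms[oi] = replace(atoms[oi], charge=atoms[oi].charge - delta)
    return ReceptorModel(atoms)


# ---------------------------------------------------------------------------
# PDB I/O (via gemmi) and the charge/radius parameter table
# ---------------------------------------------------------------------------

def write_pdb(path: str | Path, receptor: ReceptorModel, hetatm: bool = False) -> None:
    import gemmi

    st = gemmi.Structure()
    st.name = "aniondock"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for a in receptor.atoms:
        ch = chains.get(a.chain)
        if ch is None:
            ch = gemmi.Chain(a.chain)
            chains[a.chain] = ch
        res = None
        for r in ch:
            if r.seqid.num == a.res_num and r.name == (a.res_name or "UNK"):
                res = r
                break
        if res is None:
            res = gemmi.Residue()
            res.name = a.res_name or "UNK"
            res.seqid = gemmi.SeqId(a.res_num, " ")
            res.het_flag = "H" if hetatm else "A"
            ch.add_residue(res)
            res = ch[len(ch) - 1]
        at = gemmi.Atom()
        at.name = a.name or a.element
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.coords)
        res.add_atom(at)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def read_pdb(
    path: str | Path,
    param_table: dict[tuple[str, str], tuple[float, float]] | None = None,
    default_radius: float = 1.7,
    default_charge: float = 0.0,
) -> ReceptorModel:
    """Read ATOM/HETATM records; occupancy and B-factor are ignored.

    ``param_table`` maps ``(res_name, atom_name)`` to ``(radius, charge)``;
    unlisted atoms fall back to the defaults.
    """
    import gemmi

    st = gemmi.read_pdb(str(path))
    atoms: list[Atom] = []
    for model in st:
        for chain in model:
            for res in chain:
                for at in res:
                    radius, charge = default_radius, default_charge
                    if param_table is not None:
                        key = (res.name, at.name)
                        if key in param_table:
                            radius, charge = param_table[key]
                    atoms.append(
                        Atom(
                            element=at.element.name,
                            coords=(at.pos.x, at.pos.y, at.pos.z),
                            radius=radius,
                            charge=charge,
                            name=at.name,
                            res_name=res.name,
                            res_num=res.seqid.num,
                            chain=chain.name,
                        )
                    )
        break  # first model only
    return ReceptorModel(atoms)


def read_param_table(path: str | Path) -> dict[tuple[str, str], tuple[float, float]]:
    """Whitespace-delimited table: res_name atom_name radius charge."""
    table: dict[tuple[str, str], tuple[float, float]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        res, atom, radius, charge = line.split()[:4]
        table[(res, atom)] = (float(radius), float(charge))
    return table
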