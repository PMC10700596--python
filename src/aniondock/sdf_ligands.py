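"""SDF conformer I/O for the docking engine.

Multi-record SDF, one conformer per record.  Records sharing the molecule
id tag (``_Name``) are grouped as conformers of one ligand.  Per-atom
partial charges and desolvation penalties ride in the data fields
``atom_charges`` and ``atom_desolv`` (whitespace-separated floats, one per
atom); 6-12 coefficients default to the element table when the
``atom_sqrt_a``/``atom_sqrt_b`` fields are absent.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from rdkit import Chem

from .docking import LigandConformer
from .grids import DEFAULT_VDW_PARAMS


def _field(mol: Chem.Mol, name: str, n: int) -> np.ndarray | None:
    if not mol.HasProp(name):
        return None
    vals = np.array([float(v) for v in mol.GetProp(name).split()])
    if len(vals) != n:
        raise ValueError(
            f"SDF field {name!r} has {len(vals)} values for {n} atoms"
        )
    return vals


def read_conformer_sdf(path: str | Path) -> dict[str, list[LigandConformer]]:
    """Read conformers grouped by molecule id."""
    out: dict[str, list[LigandConformer]] = {}
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    for k, mol in enumerate(supplier):
        if mol is None:
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{k}"
        n = mol.GetNumAtoms()
        conf = mol.GetConformer()
        coords = conf.GetPositions()
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        charges = _field(mol, "atom_charges", n)
        if charges is None:
            charges = np.array([a.GetFormalCharge() for a in mol.GetAtoms()],
                               dtype=float)
        desolv = _field(mol, "atom_desolv", n)
        if desolv is None:
            desolv = np.zeros(n)
        sqrt_a = _field(mol, "atom_sqrt_a", n)
        sqrt_b = _field(mol, "atom_sqrt_b", n)
        if sqrt_a is None or sqrt_b is None:
            ab = np.array(
                [DEFAULT_VDW_PARAMS.get(e, DEFAULT_VDW_PARAMS["X"]) for e in elements]
            )
            sqrt_a = np.sqrt(ab[:, 0])
            sqrt_b = np.sqrt(ab[:, 1])
        bonds = [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()
        ]
        conformers = out.setdefault(name, [])
        conformers.append(
            LigandConformer(
                conformer_id=f"{name}/{len(conformers)}",
                elements=elements,
                coords=coords,
                charges=charges,
                desolv=desolv,
                sqrt_a=sqrt_a,
                sqrt_b=sqrt_b,
                bonds=bonds,
            )
        )
    return out


def write_conformer_sdf(
    path: str | Path, conformers: dict[str, list[tuple[Chem.Mol, dict]]]
) -> None:
    """Write conformers with per-atom data fields.

    ``conformers`` maps molecule ids to ``(mol-with-3D-conformer, fields)``
    pairs, where ``fields`` maps data-field names to per-atom float arrays.
    """
    writer = Chem.SDWriter(str(path))
    for name, entries in conformers.items():
        for mol, fields in entries:
            mol = Chem.Mol(mol)
            mol.SetProp("_Name", name)
            for fname, vals in fields.items():
                mol.SetProp(fname, " ".join(f"{v:.6g}" for v in vals))
            writer.write(mol)
    writer.close()
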