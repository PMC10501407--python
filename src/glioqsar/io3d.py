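"""3D structure input for the field branch: SDF (V2000) and MOL2 readers.

Structures are accepted pre-minimized and pre-aligned.  Atom-level field
properties come from an optional per-atom property table; otherwise they
are assigned by the toolkit layer (Gasteiger-style partial charges when
RDKit is available, Bondi radii, an element-typed hydrophobicity lookup,
and simple donor/acceptor rules: N-H/O-H donate, N and O accept).
"""

from __future__ import annotations

from pathlib import Path


import numpy as np
import pandas as pd

from glioqsar.comsia import (
    BONDI_RADII,
    HYDROPHOBICITY,
    AlignedMolecule,
)


def _rdkit_supplier(path: Path):
    from rdkit import Chem  # deferred: structure input only

    if path.suffix.lower() == ".mol2":
        mol = Chem.MolFromMol2File(str(path), removeHs=False, sanitize=False)
        if mol is None:
            raise ValueError(f"could not parse MOL2 file {path}")
        return [mol]
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    mols = [m for m in supplier if m is not None]
    if not mols:
        raise ValueError(f"no parsable molecules in {path}")
    return mols


def _gasteiger_charges(mol) -> np.ndarray:
    from rdkit import Chem
    from rdkit.Chem import AllChem

    try:
        Chem.SanitizeMol(mol)
        AllChem.ComputeGasteigerCharges(mol)
        q = np.array(
            [float(a.GetProp("_GasteigerCharge")) for a in mol.GetAtoms()]
        )
        q[~np.isfinite(q)] = 0.0
        return q
    except Exception:  # noqa: BLE001 - synthetic/bond-less inputs
        return np.zeros(mol.GetNumAtoms())


def _donor_flags(mol) -> np.ndarray:
    flags = np.zeros(mol.GetNumAtoms(), dtype=bool)
    for atom in mol.GetAtoms():
        if atom.GetSymbol() in ("N", "O"):
            has_h = atom.GetTotalNumHs() > 0 or any(
                nb.GetSymbol() == "H" for nb in atom.GetNeighbors()
            )
            flags[atom.GetIdx()] = has_h
    return flags


def load_structures(
    path: str | Path,
    property_table: str | Path | None = None,
) -> list[AlignedMolecule]:
    """Read aligned molecules from SDF or MOL2 into AlignedMolecule records.

    ``property_table`` (delimited; columns molecule, atom, charge, radius,
    hydrophobicity, donor, acceptor) overrides computed per-atom properties.
    """
    path = Path(path)
    mols = _rdkit_supplier(path)
    props = None
    if property_table is not None:
        props = pd.read_csv(property_table)
        props = props.set_index(["molecule", "atom"]).sort_index()
    out: list[AlignedMolecule] = []
    for k, mol in enumerate(mols):
        name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{k + 1}"
        conf = mol.GetConformer()
        n = mol.GetNumAtoms()
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        coords = np.array([list(conf.GetAtomPosition(i)) for i in range(n)])
        if props is not None and name in props.index.get_level_values(0):
            block = props.loc[name]
            charges = block["charge"].to_numpy(dtype=float)
            radii = block["radius"].to_numpy(dtype=float)
            hydro = block["hydrophobicity"].to_numpy(dtype=float)
            donor = block["donor"].to_numpy(dtype=bool)
            acceptor = block["acceptor"].to_numpy(dtype=bool)
        else:
            charges = _gasteiger_charges(mol)
            radii = np.array([BONDI_RADII.get(e, 1.7) for e in elements])
            hydro = np.array([HYDROPHOBICITY.get(e, 0.0) for e in elements])
            donor = _donor_flags(mol)
            acceptor = np.array([e in ("N", "O") for e in elements])
        out.append(
            AlignedMolecule(
                id=name,
                elements=elements,
                coords=coords,
                charges=charges,
                radii=radii,
                hydrophobicity=hydro,
                donor=donor,
                acceptor=acceptor,
            )
        )
    return out
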