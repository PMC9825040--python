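"""Small shared RDKit helpers: canonicalization, fragment handling, assembly.

Fragments carry exactly one attachment point written as a dummy atom
(``*`` in canonical output, ``[*:1]`` accepted on input).
"""

from __future__ import annotations

from functools import lru_cache

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")


class StructureError(ValueError):
    """Raised when a line notation string cannot be used as a structure."""


def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparseable SMILES: {smiles!r}")
    return mol


@lru_cache(maxsize=200_000)
def canonical_smiles(smiles: str) -> str:
    return Chem.MolToSmiles(mol_from_smiles(smiles))


def is_single_fragment(smiles: str) -> bool:
    """True when the structure is one connected molecule (no salts/mixtures)."""
    try:
        return "." not in canonical_smiles(smiles)
    except StructureError:
        return False


def heavy_atom_count(smiles: str) -> int:
    """Number of non-hydrogen, non-dummy atoms."""
    mol = mol_from_smiles(smiles)
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def molecular_mass(smiles: str) -> float:
    return Descriptors.MolWt(mol_from_smiles(smiles))


def n_attachment_points(smiles: str) -> int:
    mol = mol_from_smiles(smiles)
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 0)


def _with_map_number(smiles: str, map_num: int = 1) -> Chem.Mol:
    mol = Chem.RWMol(mol_from_smiles(smiles))
    dummies = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != 1:
        raise StructureError(
            f"fragment must carry exactly one attachment point: {smiles!r}"
        )
    dummies[0].SetAtomMapNum(map_num)
    return mol.GetMol()


def attach(core_smiles: str, substituent_smiles: str) -> str:
    """Join a one-attachment core and substituent into a whole molecule.

    Returns the canonical SMILES of the assembled structure.
    """
    core = _with_map_number(core_smiles)
    sub = _with_map_number(substituent_smiles)
    combined = Chem.CombineMols(core, sub)
    joined = Chem.molzip(combined)
    Chem.SanitizeMol(joined)
    return Chem.MolToSmiles(joined)
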