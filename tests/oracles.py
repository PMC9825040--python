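"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive results through different code paths than
the package (RWMol surgery instead of FragmentOnBonds, explicit rule
lists, sklearn metrics from reconstructed label vectors) so agreement
is informative.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem


def brute_force_fragmentations(smiles: str) -> set[tuple[str, str]]:
    """All (core, substituent) single-cut splits, core the larger side.

    Independent path: copy the molecule, delete one bond with RWMol,
    attach explicit dummy atoms to both cut ends, split into fragments.
    """
    mol = Chem.MolFromSmiles(smiles)
    out = set()
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if (
            mol.GetAtomWithIdx(i).GetAtomicNum() <= 1
            or mol.GetAtomWithIdx(j).GetAtomicNum() <= 1
        ):
            continue
        rw = Chem.RWMol(mol)
        rw.RemoveBond(i, j)
        di = rw.AddAtom(Chem.Atom(0))
        dj = rw.AddAtom(Chem.Atom(0))
        rw.AddBond(i, di, Chem.BondType.SINGLE)
        rw.AddBond(j, dj, Chem.BondType.SINGLE)
        pieces = Chem.GetMolFrags(rw.GetMol(), asMols=True, sanitizeFrags=True)
        assert len(pieces) == 2
        counted = [
            (
                Chem.MolToSmiles(p),
                sum(1 for a in p.GetAtoms() if a.GetAtomicNum() > 1),
            )
            for p in pieces
        ]
        (sa, na), (sb, nb) = counted
        if na >= nb:
            out.add((sa, sb))
        if nb >= na:
            out.add((sb, sa))
    return out


def random_molecule(rng: np.random.Generator, max_heavy: int = 30) -> str | None:
    """Random small organic molecule built by tree growth + ring closure."""
    elements = ["C", "C", "C", "C", "N", "O", "S"]
    n_atoms = int(rng.integers(3, max_heavy + 1))
    rw = Chem.RWMol()
    rw.AddAtom(Chem.Atom(elements[rng.integers(len(elements))]))
    for _ in range(n_atoms - 1):
        parent = int(rng.integers(rw.GetNumAtoms()))
        idx = rw.AddAtom(Chem.Atom(elements[rng.integers(len(elements))]))
        rw.AddBond(parent, idx, Chem.BondType.SINGLE)
    # a few ring closures between non-adjacent atoms
    for _ in range(int(rng.integers(0, 3))):
        a, b = rng.integers(rw.GetNumAtoms(), size=2)
        a, b = int(a), int(b)
        if a != b and rw.GetBondBetweenAtoms(a, b) is None:
            rw.AddBond(a, b, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    if len(Chem.GetMolFrags(mol)) != 1:
        return None
    return Chem.MolToSmiles(mol)


def size_filter_rules(core_n: int, sub_a_n: int, sub_b_n: int) -> bool:
    """The five printed size rules, written out one by one."""
    rule1 = sub_a_n <= 13
    rule2 = sub_b_n <= 13
    rule3 = core_n >= 10
    rule4 = core_n >= 2 * sub_a_n and core_n >= 2 * sub_b_n
    rule5 = abs(sub_a_n - sub_b_n) <= 8
    return rule1 and rule2 and rule3 and rule4 and rule5


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int) -> dict:
    """BA/MCC/recall/precision via sklearn on reconstructed label vectors."""
    from sklearn.metrics import (
        balanced_accuracy_score,
        matthews_corrcoef,
        precision_score,
        recall_score,
    )

    y_true = [1] * tp + [1] * fn + [0] * tn + [0] * fp
    y_pred = [1] * tp + [0] * fn + [0] * tn + [1] * fp
    out = {}
    out["mcc"] = matthews_corrcoef(y_true, y_pred) if y_true else 0.0
    out["recall"] = recall_score(y_true, y_pred) if tp + fn > 0 else None
    out["precision"] = precision_score(y_true, y_pred, zero_division=np.nan)
    if np.isnan(out["precision"]):
        out["precision"] = None
    out["ba"] = (
        balanced_accuracy_score(y_true, y_pred)
        if tp + fn > 0 and tn + fp > 0
        else None
    )
    return out


def environment_count_oracle(fragment_smiles: str, radii=(1, 2)) -> int:
    """Distinct circular environments by rooted canonical subgraph SMILES.

    Atoms are written with their whole-molecule invariants (element,
    degree, H count, charge, aromaticity), mirroring how circular
    environments carry atom context, but derived by explicit subgraph
    enumeration instead of iterative hashing.
    """
    mol = Chem.MolFromSmiles(fragment_smiles)
    symbols = [
        f"[{a.GetSymbol()}:{a.GetDegree()}:{a.GetTotalNumHs()}"
        f":{a.GetFormalCharge()}:{int(a.GetIsAromatic())}]"
        for a in mol.GetAtoms()
    ]
    seen = set()
    seen_bond_sets = set()
    # radius-0 environments are the skipped smallest tier but still claim
    # their (empty) coverage; start claiming from radius 1 upward
    for radius in sorted(radii):
        for atom in mol.GetAtoms():
            bond_ids = Chem.FindAtomEnvironmentOfRadiusN(
                mol, radius, atom.GetIdx(), useHs=False
            )
            if len(bond_ids) == 0:
                continue
            # an environment is only a new feature if no earlier (smaller
            # or same radius) environment covered the same bond set
            bond_set = frozenset(bond_ids)
            if bond_set in seen_bond_sets:
                continue
            seen_bond_sets.add(bond_set)
            atoms = set()
            for b in bond_ids:
                bond = mol.GetBondWithIdx(b)
                atoms.add(bond.GetBeginAtomIdx())
                atoms.add(bond.GetEndAtomIdx())
            atoms.add(atom.GetIdx())
            smi = Chem.MolFragmentToSmiles(
                mol,
                atomsToUse=sorted(atoms),
                bondsToUse=list(bond_ids),
                rootedAtAtom=atom.GetIdx(),
                atomSymbols=symbols,
                canonical=True,
            )
            seen.add((radius, smi))
    return len(seen)
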