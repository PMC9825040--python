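"""Matched-molecular-pair enumeration via single-cut fragmentation.

A molecule is fragmented at every acyclic single bond between two heavy
atoms into a (core, substituent) pair, with the core the larger side.
Fragmentations from different compounds of one activity class are
indexed by canonical core; two compounds sharing a core but differing
in the substituent form an MMP, subject to size constraints:

* each substituent has at most 13 heavy atoms,
* the core has at least 10 heavy atoms,
* the core is at least twice as large as either substituent,
* the exchanged substituents differ by at most 8 heavy atoms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from rdkit import Chem

from .chem import StructureError, attach, canonical_smiles, mol_from_smiles
from .io import ActivityClass

#: maximum substituent size in heavy atoms
MAX_SUBSTITUENT_ATOMS = 13
#: minimum core size in heavy atoms
MIN_CORE_ATOMS = 10
#: core must be at least this multiple of the larger substituent
CORE_SUBSTITUENT_RATIO = 2
#: maximum heavy-atom difference between exchanged substituents
MAX_SUBSTITUENT_DIFFERENCE = 8


@dataclass(frozen=True)
class Fragmentation:
    compound_id: str
    core: str  # canonical SMILES with one * attachment
    substituent: str
    core_heavy_atoms: int
    sub_heavy_atoms: int


@dataclass(frozen=True)
class MatchedMolecularPair:
    core: str
    sub_low: str
    sub_high: str
    cid_low: str
    cid_high: str
    pki_low: float
    pki_high: float

    def __post_init__(self):
        if self.sub_low == self.sub_high:
            raise ValueError("MMP substituents must differ")
        if self.pki_high < self.pki_low:
            raise ValueError("MMP must be oriented low-potency first")

    @property
    def delta(self) -> float:
        return self.pki_high - self.pki_low

    @property
    def key(self) -> str:
        """Stable identifier: the unordered compound pair."""
        return f"{self.cid_low}|{self.cid_high}"

    @property
    def compound_ids(self) -> frozenset:
        return frozenset((self.cid_low, self.cid_high))


def passes_size_filters(core_n: int, sub_a_n: int, sub_b_n: int) -> bool:
    """Apply the four MMP size rules to heavy-atom counts."""
    if core_n <= 0 or sub_a_n <= 0 or sub_b_n <= 0:
        raise ValueError("heavy-atom counts must be positive")
    return (
        sub_a_n <= MAX_SUBSTITUENT_ATOMS
        and sub_b_n <= MAX_SUBSTITUENT_ATOMS
        and core_n >= MIN_CORE_ATOMS
        and core_n >= CORE_SUBSTITUENT_RATIO * max(sub_a_n, sub_b_n)
        and abs(sub_a_n - sub_b_n) <= MAX_SUBSTITUENT_DIFFERENCE
    )


def _heavy(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def enumerate_single_cut_fragmentations(
    smiles: str, compound_id: str = ""
) -> frozenset[Fragmentation]:
    """All (core, substituent) splits across acyclic single heavy-atom bonds.

    The larger side is the core; when both sides are equally large both
    orientations are emitted. No size filtering happens here — filters
    apply when pairs are assembled.
    """
    mol = mol_from_smiles(smiles)
    if len(Chem.GetMolFrags(mol)) != 1:
        raise StructureError(f"expected a single connected molecule: {smiles!r}")
    out = set()
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        if bond.GetBeginAtom().GetAtomicNum() <= 1 or bond.GetEndAtom().GetAtomicNum() <= 1:
            continue
        frag = Chem.FragmentOnBonds(
            mol, [bond.GetIdx()], addDummies=True, dummyLabels=[(0, 0)]
        )
        pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=True)
        assert len(pieces) == 2
        (smi_a, n_a), (smi_b, n_b) = (
            (Chem.MolToSmiles(p), _heavy(p)) for p in pieces
        )
        candidates = []
        if n_a >= n_b:
            candidates.append((smi_a, smi_b, n_a, n_b))
        if n_b >= n_a:
            candidates.append((smi_b, smi_a, n_b, n_a))
        for core, sub, n_core, n_sub in candidates:
            out.add(
                Fragmentation(
                    compound_id=compound_id,
                    core=core,
                    substituent=sub,
                    core_heavy_atoms=n_core,
                    sub_heavy_atoms=n_sub,
                )
            )
    return frozenset(out)


def reassemble(frag: Fragmentation) -> str:
    """Canonical SMILES of the molecule rebuilt from core + substituent."""
    return attach(frag.core, frag.substituent)


def build_mmps(cls: ActivityClass) -> list[MatchedMolecularPair]:
    """Enumerate all MMPs of an activity class.

    Fragmentations are grouped by canonical core; every compound pair
    sharing a core with differing substituents and passing the size
    filters yields one MMP. A pair qualifying through several cores is
    kept once, with the largest core (ties broken by the
    lexicographically smallest core string). Output is sorted by
    (cid_low, cid_high) and independent of input order.
    """
    by_core: dict[str, dict[str, Fragmentation]] = {}
    pki = {}
    for comp in cls.compounds:
        pki[comp.compound_id] = comp.pki
        for frag in enumerate_single_cut_fragmentations(comp.smiles, comp.compound_id):
            group = by_core.setdefault(frag.core, {})
            # one fragmentation per (core, compound); same core from two cut
            # sites of one molecule implies identical substituents anyway
            group.setdefault(comp.compound_id, frag)

    best: dict[frozenset, tuple[int, str, Fragmentation, Fragmentation]] = {}
    for core, group in by_core.items():
        for (cid_a, fa), (cid_b, fb) in itertools.combinations(sorted(group.items()), 2):
            if fa.substituent == fb.substituent:
                continue
            if not passes_size_filters(
                fa.core_heavy_atoms, fa.sub_heavy_atoms, fb.sub_heavy_atoms
            ):
                continue
            pair = frozenset((cid_a, cid_b))
            rank = (fa.core_heavy_atoms, core)
            prev = best.get(pair)
            if prev is None or (-rank[0], rank[1]) < (-prev[0], prev[1]):
                best[pair] = (rank[0], core, fa, fb)

    mmps = []
    for pair, (_, core, fa, fb) in best.items():
        lo, hi = sorted(
            (fa, fb), key=lambda f: (pki[f.compound_id], f.compound_id)
        )
        mmps.append(
            MatchedMolecularPair(
                core=core,
                sub_low=lo.substituent,
                sub_high=hi.substituent,
                cid_low=lo.compound_id,
                cid_high=hi.compound_id,
                pki_low=pki[lo.compound_id],
                pki_high=pki[hi.compound_id],
            )
        )
    mmps.sort(key=lambda m: (m.cid_low, m.cid_high))
    return mmps


def canonical_fragment(smiles: str) -> str:
    """Canonical form of a one-attachment fragment (marker kept generic)."""
    return canonical_smiles(smiles)
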