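"""MMP encodings: three-block circular fingerprints and CGR graphs.

Fingerprints
------------
Circular (ECFP-style) atom environments are computed per fragment with
the attachment point as a distinct atom type. The smallest environments
(radius 0, single atoms) are omitted; radii 1 and 2 (bond diameters 2
and 4) are kept by default. Per activity class, observed environment
identifiers are sorted ascending and mapped bijectively to bits — no
hashing, no collisions — so fingerprint length is class-specific.
An MMP fingerprint concatenates three blocks: core features, features
unique to one of the exchanged substituents (symmetric difference), and
features common to both (intersection).

CGR graphs
----------
The shared core and both substituents form one connected pseudo-molecule:
the substituent of the weakly potent compound attaches to the core
attachment atom through an order-1 edge, that of the highly potent
compound through a hypothetical order-0 edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chem import mol_from_smiles
from .mmp import MatchedMolecularPair

DEFAULT_RADII = frozenset({1, 2})

BLOCKS = ("core", "sub_unique", "sub_common")


class InsufficientDataError(ValueError):
    pass


@lru_cache(maxsize=100_000)
def fragment_features(
    fragment_smiles: str, radii: frozenset[int] = DEFAULT_RADII
) -> frozenset[int]:
    """Canonical circular-environment identifiers of a fragment.

    Identifiers are input-order invariant; only environments whose
    radius is in ``radii`` are retained.
    """
    mol = mol_from_smiles(fragment_smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=max(radii))
    extra = rdFingerprintGenerator.AdditionalOutput()
    extra.AllocateBitInfoMap()
    gen.GetSparseCountFingerprint(mol, additionalOutput=extra)
    feats = set()
    for fid, envs in extra.GetBitInfoMap().items():
        if any(radius in radii for _, radius in envs):
            feats.add(int(fid))
    return frozenset(feats)


@dataclass(frozen=True)
class FeatureVocabulary:
    """Bijective map feature_id -> bit index, ascending in feature_id."""

    block: str
    index_of: dict[int, int]

    def __len__(self) -> int:
        return len(self.index_of)

    def encode(self, features: frozenset[int]) -> np.ndarray:
        bits = np.zeros(len(self.index_of), dtype=np.uint8)
        for f in features:
            idx = self.index_of.get(f)
            if idx is not None:  # unseen ids are silently dropped
                bits[idx] = 1
        return bits


def build_vocabulary(feature_sets, block: str = "core") -> FeatureVocabulary:
    """Ascending-sorted bijection over all feature ids seen in training."""
    ids = sorted(set().union(*feature_sets)) if feature_sets else []
    if not feature_sets or not ids:
        raise InsufficientDataError("cannot build a vocabulary from no features")
    return FeatureVocabulary(block=block, index_of={f: i for i, f in enumerate(ids)})


@dataclass(frozen=True)
class MMPFingerprint:
    core_bits: np.ndarray
    unique_bits: np.ndarray
    common_bits: np.ndarray

    def __len__(self) -> int:
        return len(self.core_bits) + len(self.unique_bits) + len(self.common_bits)

    @property
    def substituent_bits(self) -> np.ndarray:
        return np.concatenate([self.unique_bits, self.common_bits])

    @property
    def full(self) -> np.ndarray:
        return np.concatenate([self.core_bits, self.unique_bits, self.common_bits])


@dataclass(frozen=True)
class MMPVocabularies:
    """Class-level vocabularies: one for cores, one shared by the two
    substituent blocks (unique and common use the same bit layout)."""

    core: FeatureVocabulary
    substituent: FeatureVocabulary
    radii: frozenset[int] = DEFAULT_RADII


def build_vocabularies(
    training_mmps: list[MatchedMolecularPair],
    radii: frozenset[int] = DEFAULT_RADII,
) -> MMPVocabularies:
    if not training_mmps:
        raise InsufficientDataError("no training MMPs")
    core_sets = [fragment_features(m.core, radii) for m in training_mmps]
    sub_sets = [fragment_features(m.sub_low, radii) for m in training_mmps]
    sub_sets += [fragment_features(m.sub_high, radii) for m in training_mmps]
    return MMPVocabularies(
        core=build_vocabulary(core_sets, "core"),
        substituent=build_vocabulary(sub_sets, "substituent"),
        radii=radii,
    )


def encode_mmp_fingerprint(
    mmp: MatchedMolecularPair, vocabularies: MMPVocabularies
) -> MMPFingerprint:
    radii = vocabularies.radii
    core_f = fragment_features(mmp.core, radii)
    low_f = fragment_features(mmp.sub_low, radii)
    high_f = fragment_features(mmp.sub_high, radii)
    return MMPFingerprint(
        core_bits=vocabularies.core.encode(core_f),
        unique_bits=vocabularies.substituent.encode(low_f ^ high_f),
        common_bits=vocabularies.substituent.encode(low_f & high_f),
    )


# --- CGR ---------------------------------------------------------------

ELEMENT_PALETTE = ("C", "N", "O", "F", "P", "S", "Cl", "Br", "I")
BOND_ORDERS = (0.0, 1.0, 1.5, 2.0, 3.0)

ROLE_CORE, ROLE_SUB_LOW, ROLE_SUB_HIGH = "core", "sub_low", "sub_high"

#: element one-hot (+other) | degree | formal charge | aromatic | in-ring | n_H
ATOM_FEATURE_DIM = len(ELEMENT_PALETTE) + 1 + 5
#: order one-hot | conjugated | in-ring
BOND_FEATURE_DIM = len(BOND_ORDERS) + 2


@dataclass(frozen=True)
class CGRGraph:
    node_features: np.ndarray  # (n_nodes, ATOM_FEATURE_DIM)
    edges: tuple[tuple[int, int], ...]
    edge_features: np.ndarray  # (n_edges, BOND_FEATURE_DIM)
    roles: tuple[str, ...]

    @property
    def n_nodes(self) -> int:
        return len(self.roles)

    def edge_orders(self) -> list[float]:
        out = []
        for feat in self.edge_features:
            out.append(BOND_ORDERS[int(np.argmax(feat[: len(BOND_ORDERS)]))])
        return out


def _atom_feature(atom: Chem.Atom, extra_degree: int = 0) -> np.ndarray:
    vec = np.zeros(ATOM_FEATURE_DIM, dtype=np.float32)
    sym = atom.GetSymbol()
    vec[ELEMENT_PALETTE.index(sym) if sym in ELEMENT_PALETTE else len(ELEMENT_PALETTE)] = 1.0
    base = len(ELEMENT_PALETTE) + 1
    heavy_deg = sum(1 for n in atom.GetNeighbors() if n.GetAtomicNum() > 1)
    vec[base + 0] = heavy_deg + extra_degree
    vec[base + 1] = atom.GetFormalCharge()
    vec[base + 2] = float(atom.GetIsAromatic())
    vec[base + 3] = float(atom.IsInRing())
    vec[base + 4] = atom.GetTotalNumHs()
    return vec


def _bond_feature(order: float, conjugated: bool, in_ring: bool) -> np.ndarray:
    vec = np.zeros(BOND_FEATURE_DIM, dtype=np.float32)
    vec[BOND_ORDERS.index(order)] = 1.0
    vec[len(BOND_ORDERS) + 0] = float(conjugated)
    vec[len(BOND_ORDERS) + 1] = float(in_ring)
    return vec


def _fragment_graph(fragment_smiles: str):
    """Atoms (dummy removed, canonical order), bonds, and the index of
    the attachment atom (the dummy's single heavy neighbor)."""
    mol = mol_from_smiles(fragment_smiles)
    order = list(
        Chem.CanonicalRankAtoms(mol, breakTies=True)
    )  # rank per atom; build canonical position list
    atoms = sorted(
        (a for a in mol.GetAtoms() if a.GetAtomicNum() > 0),
        key=lambda a: order[a.GetIdx()],
    )
    index_of = {a.GetIdx(): i for i, a in enumerate(atoms)}
    attach_local = None
    for a in mol.GetAtoms():
        if a.GetAtomicNum() == 0:
            neighbors = [n for n in a.GetNeighbors() if n.GetAtomicNum() > 0]
            assert len(neighbors) == 1
            attach_local = index_of[neighbors[0].GetIdx()]
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtom(), b.GetEndAtom()
        if i.GetAtomicNum() == 0 or j.GetAtomicNum() == 0:
            continue
        bonds.append(
            (
                index_of[i.GetIdx()],
                index_of[j.GetIdx()],
                float(b.GetBondTypeAsDouble()),
                b.GetIsConjugated(),
                b.IsInRing(),
            )
        )
    feats = [
        _atom_feature(a, extra_degree=1 if index_of[a.GetIdx()] == attach_local else 0)
        for a in atoms
    ]
    return feats, bonds, attach_local


def build_cgr(mmp: MatchedMolecularPair) -> CGRGraph:
    """Assemble the MMP pseudo-molecule graph.

    Node order: core atoms, then the weak-compound substituent, then the
    potent-compound substituent, each canonically ordered. The weak
    substituent joins the core through an order-1 edge, the potent one
    through an order-0 edge.
    """
    nodes, edges, edge_feats, roles = [], [], [], []
    attach_points = {}
    for role, frag in (
        (ROLE_CORE, mmp.core),
        (ROLE_SUB_LOW, mmp.sub_low),
        (ROLE_SUB_HIGH, mmp.sub_high),
    ):
        feats, bonds, attach_local = _fragment_graph(frag)
        offset = len(nodes)
        nodes.extend(feats)
        roles.extend([role] * len(feats))
        attach_points[role] = offset + attach_local
        for i, j, order, conj, ring in bonds:
            edges.append((offset + i, offset + j))
            edge_feats.append(_bond_feature(order, conj, ring))
    # weak substituent: real single bond; potent substituent: zero-order bond
    edges.append((attach_points[ROLE_CORE], attach_points[ROLE_SUB_LOW]))
    edge_feats.append(_bond_feature(1.0, False, False))
    edges.append((attach_points[ROLE_CORE], attach_points[ROLE_SUB_HIGH]))
    edge_feats.append(_bond_feature(0.0, False, False))
    return CGRGraph(
        node_features=np.array(nodes, dtype=np.float32),
        edges=tuple(edges),
        edge_features=np.array(edge_feats, dtype=np.float32),
        roles=tuple(roles),
    )
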