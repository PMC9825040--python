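"""Reading, curating, and writing per-class compound-activity tables.

A compound record holds a canonical SMILES and an aggregated pKi
(negative decadic logarithm of a molar Ki/Kd). Potencies given in M or
nM are converted on input; replicate measurements for one compound are
averaged unless they disagree by more than one log unit, in which case
the compound is discarded as unreliable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import pandas as pd
from rdkit import Chem

from .chem import (
    StructureError,
    canonical_smiles,
    heavy_atom_count,
    is_single_fragment,
    molecular_mass,
)

logger = logging.getLogger(__name__)

#: replicate pKi values spanning more than this range discard the compound
MAX_REPLICATE_RANGE = 1.0

VALID_UNITS = ("M", "nM", "pKi")

MMP_TABLE_COLUMNS = [
    "core_smiles",
    "sub_low_smiles",
    "sub_high_smiles",
    "cid_low",
    "cid_high",
    "pki_low",
    "pki_high",
    "delta",
    "label",
]


class ConfigurationError(ValueError):
    """A declared column/unit/format does not match the input."""


class EmptyInputError(ValueError):
    """No usable rows after parsing and curation."""


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    smiles: str
    pki: float
    n_measurements: int = 1
    heavy_atom_count: int = 0

    def __post_init__(self):
        if not math.isfinite(self.pki):
            raise ValueError(f"non-finite pKi for {self.compound_id}")


@dataclass
class ActivityClass:
    class_id: str
    compounds: list[CompoundRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [c.compound_id for c in self.compounds]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate compound ids in class {self.class_id}")

    def __len__(self) -> int:
        return len(self.compounds)

    def pki_of(self, compound_id: str) -> float:
        for c in self.compounds:
            if c.compound_id == compound_id:
                return c.pki
        raise KeyError(compound_id)


def potency_to_pki(value: float, unit: str) -> float:
    """Convert a potency reading to pKi = -log10(Ki in mol/L)."""
    if unit == "pKi":
        return float(value)
    if unit == "M":
        molar = float(value)
    elif unit == "nM":
        molar = float(value) * 1e-9
    else:
        raise ConfigurationError(f"unknown potency unit {unit!r}")
    if molar <= 0:
        raise ValueError("potency must be positive to take a logarithm")
    return -math.log10(molar)


def aggregate_potency(values: list[float]) -> float | None:
    """Combine replicate pKi values for one compound.

    Returns the arithmetic mean when the replicates agree to within
    ``MAX_REPLICATE_RANGE`` log units, otherwise ``None`` (discard signal).
    """
    if len(values) == 0:
        raise ValueError("aggregate_potency requires at least one value")
    if any(not math.isfinite(v) for v in values):
        raise ValueError("non-finite replicate value")
    if max(values) - min(values) > MAX_REPLICATE_RANGE:
        return None
    # summing in sorted order makes the mean exactly permutation-invariant
    return float(sum(sorted(values))) / len(values)


def _rows_from_file(path, fmt, potency_column, smiles_column, id_column):
    if fmt in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if fmt == "csv" else "\t")
        for col in (id_column, smiles_column, potency_column):
            if col not in df.columns:
                raise ConfigurationError(f"missing column {col!r} in {path}")
        return list(
            zip(
                df[id_column].astype(str),
                df[smiles_column].astype(str),
                df[potency_column],
            )
        )
    if fmt == "smi":
        # whitespace-delimited, headerless: id, SMILES, potency sidecar column
        rows = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if len(parts) < 3:
                    raise ConfigurationError(
                        f"SMI line needs id, SMILES and potency: {line!r}"
                    )
                rows.append((parts[0], parts[1], parts[2]))
        return rows
    if fmt == "sdf":
        rows = []
        supplier = Chem.SDMolSupplier(str(path))
        for i, mol in enumerate(supplier):
            if mol is None:
                rows.append((f"mol{i}", "", float("nan")))
                continue
            if not mol.HasProp(potency_column):
                raise ConfigurationError(
                    f"SDF record {i} lacks property {potency_column!r}"
                )
            cid = mol.GetProp("_Name") or f"mol{i}"
            rows.append((cid, Chem.MolToSmiles(mol), mol.GetProp(potency_column)))
        return rows
    raise ConfigurationError(f"unknown format {fmt!r}")


def read_compound_table(
    path,
    fmt: str = "tsv",
    potency_column: str = "potency",
    unit: str = "nM",
    class_id: str | None = None,
    smiles_column: str = "smiles",
    id_column: str = "compound_id",
) -> ActivityClass:
    """Read one activity class from a CSV/TSV/SMI/SDF compound table.

    Rows with unparseable or disconnected structures or non-numeric
    potencies are dropped (counted in the log); replicates of one
    compound id are aggregated, compounds with discordant replicates
    are discarded.
    """
    if unit not in VALID_UNITS:
        raise ConfigurationError(f"unit must be one of {VALID_UNITS}")
    rows = _rows_from_file(path, fmt, potency_column, smiles_column, id_column)

    by_id: dict[str, tuple[str, list[float]]] = {}
    n_dropped = 0
    for cid, smi, value in rows:
        try:
            value = float(value)
            if not math.isfinite(value):
                raise ValueError
            if not is_single_fragment(smi):
                raise StructureError(smi)
            can = canonical_smiles(smi)
            pki = potency_to_pki(value, unit)
        except (ValueError, StructureError):
            n_dropped += 1
            continue
        by_id.setdefault(cid, (can, []))[1].append(pki)
    if n_dropped:
        logger.info("%s: dropped %d unparseable/non-numeric rows", path, n_dropped)

    compounds = []
    n_discarded = 0
    for cid, (can, pkis) in by_id.items():
        agg = aggregate_potency(pkis)
        if agg is None:
            n_discarded += 1
            continue
        compounds.append(
            CompoundRecord(
                compound_id=cid,
                smiles=can,
                pki=agg,
                n_measurements=len(pkis),
                heavy_atom_count=heavy_atom_count(can),
            )
        )
    if n_discarded:
        logger.info("%s: discarded %d compounds (replicate disagreement)", path, n_discarded)
    if not compounds:
        raise EmptyInputError(f"no valid compounds in {path}")
    return ActivityClass(
        class_id=class_id or str(path),
        compounds=sorted(compounds, key=lambda c: c.compound_id),
    )


def apply_curation_filters(cls: ActivityClass, max_mass: float = 1000.0) -> ActivityClass:
    """Drop compounds at or above ``max_mass`` Da; keep the rest unchanged."""
    kept = [c for c in cls.compounds if molecular_mass(c.smiles) < max_mass]
    removed = len(cls.compounds) - len(kept)
    if removed:
        logger.info("%s: mass filter removed %d compounds", cls.class_id, removed)
    out = replace(cls, compounds=kept)
    if not kept:
        out.metadata = dict(out.metadata, empty_after_curation=True)
    return out


def write_class(cls: ActivityClass, path) -> None:
    df = pd.DataFrame(
        {
            "compound_id": [c.compound_id for c in cls.compounds],
            "smiles": [c.smiles for c in cls.compounds],
            "pki": [c.pki for c in cls.compounds],
            "n_measurements": [c.n_measurements for c in cls.compounds],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_class(path, class_id: str | None = None) -> ActivityClass:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    compounds = [
        CompoundRecord(
            compound_id=str(r.compound_id),
            smiles=r.smiles,
            pki=float(r.pki),
            n_measurements=int(r.n_measurements),
            heavy_atom_count=heavy_atom_count(r.smiles),
        )
        for r in df.itertuples()
    ]
    return ActivityClass(
        class_id=class_id or str(path),
        compounds=sorted(compounds, key=lambda c: c.compound_id),
    )


def write_mmp_table(mmps, path) -> None:
    """Write MMPs (plain or labeled) to a round-trippable TSV."""
    rows = []
    for m in mmps:
        label = ""
        if hasattr(m, "mmp"):  # LabeledMMP
            label = m.label
            m = m.mmp
        rows.append(
            {
                "core_smiles": m.core,
                "sub_low_smiles": m.sub_low,
                "sub_high_smiles": m.sub_high,
                "cid_low": m.cid_low,
                "cid_high": m.cid_high,
                "pki_low": m.pki_low,
                "pki_high": m.pki_high,
                "delta": m.delta,
                "label": label,
            }
        )
    pd.DataFrame(rows, columns=MMP_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_mmp_table(path):
    from .mmp import MatchedMolecularPair  # local import: avoid cycle

    df = pd.read_csv(
        path, sep="\t", keep_default_na=False, float_precision="round_trip"
    )
    return [
        MatchedMolecularPair(
            core=r.core_smiles,
            sub_low=r.sub_low_smiles,
            sub_high=r.sub_high_smiles,
            cid_low=str(r.cid_low),
            cid_high=str(r.cid_high),
            pki_low=float(r.pki_low),
            pki_high=float(r.pki_high),
        )
        for r in df.itertuples()
    ]
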