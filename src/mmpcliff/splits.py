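"""Train/test partitions of labeled MMPs with and without data leakage.

Random splits partition MMPs directly, so a compound can appear in both
sets (leakage possible). The advanced cross-validation (AXV) split
holds out compounds *before* pairing: MMPs with neither compound in the
hold-out go to training, with both to test, and mixed pairs are
discarded — train and test MMPs then share no compounds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .io import ActivityClass
from .labeling import AC, NONAC, LabeledMMP
from .mmp import MatchedMolecularPair, build_mmps

logger = logging.getLogger(__name__)

RANDOM, AXV = "random", "axv"


class InsufficientDataError(ValueError):
    pass


@dataclass
class SplitResult:
    train_ids: frozenset[str]
    test_ids: frozenset[str]
    discarded_ids: frozenset[str]
    mode: str
    seed: int
    holdout_compounds: frozenset[str] = field(default_factory=frozenset)
    flagged_unusable: bool = False

    def __post_init__(self):
        assert not (self.train_ids & self.test_ids)

    def to_manifest(self) -> dict:
        return {
            "mode": self.mode,
            "seed": self.seed,
            "train_ids": sorted(self.train_ids),
            "test_ids": sorted(self.test_ids),
            "discarded_ids": sorted(self.discarded_ids),
            "holdout_compounds": sorted(self.holdout_compounds),
            "flagged_unusable": self.flagged_unusable,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_manifest(), fh, indent=1)

    @classmethod
    def from_manifest(cls, data: dict) -> "SplitResult":
        return cls(
            train_ids=frozenset(data["train_ids"]),
            test_ids=frozenset(data["test_ids"]),
            discarded_ids=frozenset(data["discarded_ids"]),
            mode=data["mode"],
            seed=data["seed"],
            holdout_compounds=frozenset(data["holdout_compounds"]),
            flagged_unusable=data.get("flagged_unusable", False),
        )


def _round_half_even(x: float) -> int:
    return int(round(x))


def random_split(
    mmps: list[MatchedMolecularPair], test_fraction: float = 0.2, seed: int = 0
) -> SplitResult:
    """Uniform MMP-level partition; leakage through shared compounds is
    possible by construction."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    if len(mmps) < 2:
        raise InsufficientDataError("need at least two MMPs to split")
    ids = sorted(m.key for m in mmps)
    n_test = max(1, _round_half_even(len(ids) * test_fraction))
    if n_test >= len(ids):
        raise InsufficientDataError("test fraction leaves no training MMPs")
    rng = np.random.default_rng(seed)
    test = frozenset(
        ids[i] for i in rng.choice(len(ids), size=n_test, replace=False)
    )
    return SplitResult(
        train_ids=frozenset(ids) - test,
        test_ids=test,
        discarded_ids=frozenset(),
        mode=RANDOM,
        seed=seed,
    )


def axv_split(
    cls: ActivityClass,
    holdout_fraction: float = 0.2,
    seed: int = 0,
    mmp_builder=build_mmps,
) -> SplitResult:
    """Compound-level hold-out before MMP generation (zero leakage)."""
    if len(cls) < 5:
        raise InsufficientDataError("AXV needs at least five compounds")
    cids = sorted(c.compound_id for c in cls.compounds)
    n_hold = _round_half_even(len(cids) * holdout_fraction)
    rng = np.random.default_rng(seed)
    holdout = frozenset(
        cids[i] for i in rng.choice(len(cids), size=n_hold, replace=False)
    )
    train, test, discarded = set(), set(), set()
    for m in mmp_builder(cls):
        inside = len(m.compound_ids & holdout)
        if inside == 0:
            train.add(m.key)
        elif inside == 2:
            test.add(m.key)
        else:
            discarded.add(m.key)
    result = SplitResult(
        train_ids=frozenset(train),
        test_ids=frozenset(test),
        discarded_ids=frozenset(discarded),
        mode=AXV,
        seed=seed,
        holdout_compounds=holdout,
        flagged_unusable=not test or not train,
    )
    if result.flagged_unusable:
        logger.warning(
            "%s: AXV split at seed %d left an empty train or test set",
            cls.class_id,
            seed,
        )
    return result


def compound_ids_of(mmps: list[MatchedMolecularPair], keys) -> frozenset[str]:
    keys = set(keys)
    out = set()
    for m in mmps:
        if m.key in keys:
            out |= m.compound_ids
    return frozenset(out)


def balance_training(
    train_labeled: list[LabeledMMP], seed: int = 0
) -> list[LabeledMMP]:
    """Undersample nonACs (without replacement) down to the AC count.

    Returns the set unchanged (with a warning) when nonACs are not in
    excess. Test sets are never balanced.
    """
    acs = [lm for lm in train_labeled if lm.label == AC]
    nonacs = [lm for lm in train_labeled if lm.label == NONAC]
    if not acs or not nonacs:
        raise ValueError("balancing requires both labels in the training set")
    if len(nonacs) <= len(acs):
        logger.warning("nonACs not in excess (%d <= %d); unchanged", len(nonacs), len(acs))
        return list(train_labeled)
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(nonacs), size=len(acs), replace=False)
    kept = [nonacs[i] for i in sorted(keep)]
    out = acs + kept
    out.sort(key=lambda lm: lm.mmp.key)
    return out
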