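"""Class-dependent activity-cliff thresholds and MMP labeling.

An MMP is an activity cliff (AC) when its potency difference reaches
the class threshold T, a nonAC when the difference is below one log
unit (less than tenfold), and excluded when it falls in the buffer
zone between the two — a guard against boundary effects.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass

from .io import ActivityClass
from .mmp import MatchedMolecularPair

logger = logging.getLogger(__name__)

AC = "AC"
NONAC = "nonAC"
EXCLUDED = "excluded"

#: below this potency difference (log units) an MMP is a nonAC
NONAC_DELTA = 1.0

THRESHOLD_KINDS = ("diffdist_mean_plus_2sd", "potency_mean_plus_2sd", "fixed")


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class ThresholdPolicy:
    """How the class AC threshold is derived.

    ``diffdist_mean_plus_2sd`` (default): mean + 2 sample SD of the class's
    MMP potency-difference distribution. ``potency_mean_plus_2sd``: the same
    statistic over the compound potency values themselves.  ``fixed``: a
    constant, e.g. 2.0 for the classical 100-fold criterion.
    """

    kind: str = "diffdist_mean_plus_2sd"
    fixed_value: float = 2.0

    def __post_init__(self):
        if self.kind not in THRESHOLD_KINDS:
            raise ValueError(f"unknown threshold policy {self.kind!r}")
        if self.kind == "fixed" and not self.fixed_value > 0:
            raise ValueError("fixed threshold must be positive")


@dataclass(frozen=True)
class LabeledMMP:
    mmp: MatchedMolecularPair
    label: str
    threshold_used: float

    @property
    def is_ac(self) -> bool:
        return self.label == AC


def compute_class_threshold(
    cls: ActivityClass,
    mmps: list[MatchedMolecularPair],
    policy: ThresholdPolicy = ThresholdPolicy(),
) -> float:
    """Class AC threshold in log units under the given policy."""
    if policy.kind == "fixed":
        return policy.fixed_value
    if policy.kind == "potency_mean_plus_2sd":
        values = [c.pki for c in cls.compounds]
        what = "compounds"
    else:
        values = [m.delta for m in mmps]
        what = "MMPs"
    if len(values) < 2:
        raise InsufficientDataError(
            f"{policy.kind} needs at least two {what} in class {cls.class_id}"
        )
    return statistics.mean(values) + 2.0 * statistics.stdev(values)


def label_mmps(
    mmps: list[MatchedMolecularPair], threshold: float
) -> list[LabeledMMP]:
    """Partition MMPs into AC (delta >= T), nonAC (delta < 1), excluded."""
    if threshold < NONAC_DELTA:
        logger.warning(
            "threshold %.3f < %.1f: AC and nonAC bands overlap", threshold, NONAC_DELTA
        )
    out = []
    for m in mmps:
        if m.delta >= threshold:
            label = AC
        elif m.delta < NONAC_DELTA:
            label = NONAC
        else:
            label = EXCLUDED
        out.append(LabeledMMP(mmp=m, label=label, threshold_used=threshold))
    counts = label_counts(out)
    logger.info("labeled %d MMPs: %s", len(out), counts)
    return out


def label_counts(labeled: list[LabeledMMP]) -> dict[str, int]:
    counts = {AC: 0, NONAC: 0, EXCLUDED: 0}
    for lm in labeled:
        counts[lm.label] += 1
    return counts


def select_classes(
    labeled_classes: dict[str, list[LabeledMMP]], min_acs: int = 20
) -> dict[str, list[LabeledMMP]]:
    """Keep only classes yielding at least ``min_acs`` activity cliffs."""
    return {
        cid: labeled
        for cid, labeled in labeled_classes.items()
        if label_counts(labeled)[AC] >= min_acs
    }
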