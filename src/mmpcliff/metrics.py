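"""Confusion-matrix performance measures for AC prediction.

The activity cliff is the positive class throughout. Precision is
reported as an explicit ``None`` marker when no positive prediction was
made, so trial averages stay honest; the MCC zero-denominator
convention is 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .labeling import AC, NONAC

logger = logging.getLogger(__name__)

METRIC_NAMES = ("ba", "mcc", "recall", "precision")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(true_labels, predicted_labels) -> ConfusionCounts:
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors differ in length")
    tp = fp = tn = fn = 0
    for t, p in zip(true_labels, predicted_labels):
        if t not in (AC, NONAC) or p not in (AC, NONAC):
            raise ValueError(f"labels must be binary {AC}/{NONAC}: got {t!r}, {p!r}")
        if t == AC:
            if p == AC:
                tp += 1
            else:
                fn += 1
        else:
            if p == AC:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def compute_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """BA, MCC, recall, precision from confusion counts.

    A metric whose denominator vanishes is ``None`` (undefined marker),
    except MCC which is 0 by convention when any factor is 0.
    """
    recall = c.tp / (c.tp + c.fn) if c.tp + c.fn > 0 else None
    precision = c.tp / (c.tp + c.fp) if c.tp + c.fp > 0 else None
    specificity = c.tn / (c.tn + c.fp) if c.tn + c.fp > 0 else None
    ba = (
        (recall + specificity) / 2.0
        if recall is not None and specificity is not None
        else None
    )
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = (
        (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom) if denom > 0 else 0.0
    )
    return {"ba": ba, "mcc": mcc, "recall": recall, "precision": precision}


@dataclass
class MetricsReport:
    """One evaluated trial (or an aggregate over trials)."""

    class_id: str
    method: str
    split_mode: str
    balance_mode: str
    seed: int | None
    metrics: dict[str, float | None]
    n_test: int = 0
    n_train: int = 0

    def key(self) -> tuple:
        return (self.class_id, self.method, self.split_mode, self.balance_mode)

    def as_row(self) -> dict:
        row = {
            "class_id": self.class_id,
            "method": self.method,
            "split_mode": self.split_mode,
            "balance_mode": self.balance_mode,
            "seed": self.seed,
            "n_train": self.n_train,
            "n_test": self.n_test,
        }
        row.update(self.metrics)
        return row


def aggregate_trials(reports: list[MetricsReport]) -> MetricsReport:
    """Arithmetic mean per metric over trials of one experiment cell,
    skipping undefined markers (their count is logged)."""
    if not reports:
        raise ValueError("nothing to aggregate")
    keys = {r.key() for r in reports}
    if len(keys) > 1:
        raise ValueError(f"mixed experiment keys: {sorted(keys)}")
    metrics: dict[str, float | None] = {}
    for name in METRIC_NAMES:
        values = [r.metrics[name] for r in reports]
        defined = [v for v in values if v is not None]
        if len(defined) < len(values):
            logger.info(
                "aggregate %s: %d undefined %s values skipped",
                reports[0].key(),
                len(values) - len(defined),
                name,
            )
        metrics[name] = sum(defined) / len(defined) if defined else None
    first = reports[0]
    return MetricsReport(
        class_id=first.class_id,
        method=first.method,
        split_mode=first.split_mode,
        balance_mode=first.balance_mode,
        seed=None,
        metrics=metrics,
        n_test=int(round(sum(r.n_test for r in reports) / len(reports))),
        n_train=int(round(sum(r.n_train for r in reports) / len(reports))),
    )
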