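"""End-to-end experiment orchestration.

One experiment runs, for every activity class: MMP enumeration, class
threshold + labeling (buffer-zone MMPs removed before splitting),
train/test splitting under the requested leakage regimes, per-split
feature vocabularies (training MMPs only), model training with internal
hyperparameter search, and test-set evaluation. Results are emitted as
tidy per-trial and aggregated tables, each traceable to a split
manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import labeling as lab
from .io import ActivityClass, read_class
from .labeling import LabeledMMP, ThresholdPolicy
from .metrics import MetricsReport, aggregate_trials, compute_metrics, confusion
from .mmp import MatchedMolecularPair, build_mmps
from .models import ModelSpec, train_model
from .representations import build_cgr, build_vocabularies, encode_mmp_fingerprint
from .splits import AXV, RANDOM, SplitResult, axv_split, balance_training, random_split
from .synthetic import SyntheticClassConfig, generate_benchmark_suite

logger = logging.getLogger(__name__)

IMBALANCED, BALANCED = "imbalanced", "balanced"


@dataclass
class ExperimentConfig:
    class_paths: tuple[str, ...] = ()  # compound table TSVs; empty -> synthetic
    n_synthetic_classes: int = 10
    synthetic: SyntheticClassConfig = field(default_factory=SyntheticClassConfig)
    threshold_policy: ThresholdPolicy = field(default_factory=ThresholdPolicy)
    split_modes: tuple[str, ...] = (RANDOM,)
    balance_modes: tuple[str, ...] = (IMBALANCED,)
    methods: tuple[str, ...] = ("svm_mmp", "knn1")
    trials: int = 3
    hpo_trials: int = 10
    hpo_folds: int = 3
    test_fraction: float = 0.2
    min_acs: int = 20
    min_class_instances: int = 40
    keep_classes: tuple[str, ...] = ()  # empty -> all eligible classes
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw:
            raw["synthetic"] = SyntheticClassConfig(**raw["synthetic"])
        if "threshold_policy" in raw:
            raw["threshold_policy"] = ThresholdPolicy(**raw["threshold_policy"])
        for key in ("class_paths", "split_modes", "balance_modes", "methods"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def load_classes(config: ExperimentConfig) -> list[ActivityClass]:
    if config.class_paths:
        return [read_class(p, class_id=Path(p).stem) for p in config.class_paths]
    suite = generate_benchmark_suite(
        config.n_synthetic_classes, config.synthetic, seed=config.seed
    )
    return [cls for cls, _ in suite]


def prepare_class(cls: ActivityClass, policy: ThresholdPolicy):
    """MMPs, class threshold, and labeled MMPs with the buffer zone removed."""
    mmps = build_mmps(cls)
    threshold = lab.compute_class_threshold(cls, mmps, policy)
    labeled = lab.label_mmps(mmps, threshold)
    kept = [lm for lm in labeled if lm.label != lab.EXCLUDED]
    return mmps, threshold, labeled, kept


def split_labeled(
    cls: ActivityClass,
    kept: list[LabeledMMP],
    mmps: list[MatchedMolecularPair],
    mode: str,
    test_fraction: float,
    seed: int,
) -> tuple[SplitResult, list[LabeledMMP], list[LabeledMMP]]:
    by_key = {lm.mmp.key: lm for lm in kept}
    if mode == RANDOM:
        split = random_split([lm.mmp for lm in kept], test_fraction, seed)
    elif mode == AXV:
        split = axv_split(cls, test_fraction, seed, mmp_builder=lambda _: mmps)
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    train = [by_key[k] for k in sorted(split.train_ids) if k in by_key]
    test = [by_key[k] for k in sorted(split.test_ids) if k in by_key]
    return split, train, test


def audit_leakage(split: SplitResult, mmps: list[MatchedMolecularPair]) -> dict:
    """Compound-overlap report between the train and test MMPs of a split."""
    by_key = {m.key: m for m in mmps}
    dangling = (split.train_ids | split.test_ids) - set(by_key)
    if dangling:
        raise ValueError(f"split references unknown MMP ids: {sorted(dangling)[:5]}")
    train_compounds = set()
    for k in split.train_ids:
        train_compounds |= by_key[k].compound_ids
    test_compounds = set()
    n_sharing = 0
    for k in split.test_ids:
        cids = by_key[k].compound_ids
        test_compounds |= cids
        if cids & train_compounds:
            n_sharing += 1
    n_test = len(split.test_ids)
    return {
        "mode": split.mode,
        "n_train": len(split.train_ids),
        "n_test": n_test,
        "compound_intersection": len(train_compounds & test_compounds),
        "test_fraction_sharing": (n_sharing / n_test) if n_test else None,
        "unusable": n_test == 0 or len(split.train_ids) == 0,
    }


def _evaluate(model, test: list[LabeledMMP], instances) -> dict:
    pred, _ = model.predict(instances)
    c = confusion([lm.label for lm in test], pred)
    return compute_metrics(c)


def run_experiment(config: ExperimentConfig):
    """Execute the full grid; returns (per-trial, aggregated) DataFrames."""
    classes = load_classes(config)
    if config.keep_classes:
        classes = [c for c in classes if c.class_id in config.keep_classes]
    reports: list[MetricsReport] = []
    manifests = {}
    failures = []
    for cls in classes:
        t0 = time.perf_counter()
        try:
            mmps, threshold, labeled, kept = prepare_class(
                cls, config.threshold_policy
            )
        except Exception as exc:  # pragma: no cover - defensive
            failures.append({"class": cls.class_id, "stage": "prepare", "error": str(exc)})
            continue
        counts = lab.label_counts(labeled)
        if counts[lab.AC] < config.min_acs or len(kept) < config.min_class_instances:
            logger.info(
                "%s skipped (%d ACs, %d usable MMPs)",
                cls.class_id,
                counts[lab.AC],
                len(kept),
            )
            continue
        graphs_by_key = None
        for trial in range(config.trials):
            trial_seed = (config.seed + 9973 * trial) % (2**31)
            for mode in config.split_modes:
                try:
                    split, train, test = split_labeled(
                        cls, kept, mmps, mode, config.test_fraction, trial_seed
                    )
                except Exception as exc:
                    failures.append(
                        {"class": cls.class_id, "stage": f"split:{mode}", "error": str(exc)}
                    )
                    continue
                manifests[(cls.class_id, mode, trial)] = split
                if not test or len({lm.label for lm in train}) < 2:
                    logger.warning(
                        "%s %s trial %d unusable split", cls.class_id, mode, trial
                    )
                    continue
                vocab = build_vocabularies([lm.mmp for lm in train])
                fp_of = {
                    lm.mmp.key: encode_mmp_fingerprint(lm.mmp, vocab)
                    for lm in train + test
                }
                needs_graphs = any(m.startswith("mpnn") for m in config.methods)
                if needs_graphs and graphs_by_key is None:
                    graphs_by_key = {lm.mmp.key: build_cgr(lm.mmp) for lm in kept}
                for balance in config.balance_modes:
                    train_b = (
                        balance_training(train, seed=trial_seed)
                        if balance == BALANCED
                        else train
                    )
                    if len({lm.label for lm in train_b}) < 2:
                        continue
                    for method in config.methods:
                        spec = ModelSpec.default(
                            method,
                            hpo_trials=config.hpo_trials,
                            hpo_folds=config.hpo_folds,
                            seed=trial_seed,
                        )
                        inst_of = (
                            graphs_by_key
                            if spec.representation == "cgr"
                            else fp_of
                        )
                        try:
                            model = train_model(
                                spec,
                                [inst_of[lm.mmp.key] for lm in train_b],
                                [lm.label for lm in train_b],
                            )
                            metrics = _evaluate(
                                model, test, [inst_of[lm.mmp.key] for lm in test]
                            )
                        except Exception as exc:
                            failures.append(
                                {
                                    "class": cls.class_id,
                                    "stage": f"train:{method}:{mode}:{balance}",
                                    "error": str(exc),
                                }
                            )
                            continue
                        reports.append(
                            MetricsReport(
                                class_id=cls.class_id,
                                method=method,
                                split_mode=mode,
                                balance_mode=balance,
                                seed=trial_seed,
                                metrics=metrics,
                                n_test=len(test),
                                n_train=len(train_b),
                            )
                        )
        logger.info("%s done in %.1fs", cls.class_id, time.perf_counter() - t0)

    trials_df = pd.DataFrame([r.as_row() for r in reports])
    cells = {}
    for r in reports:
        cells.setdefault(r.key(), []).append(r)
    agg_df = pd.DataFrame(
        [aggregate_trials(rs).as_row() for rs in cells.values()]
    )
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        trials_df.to_csv(out / "results_trials.csv", index=False)
        agg_df.to_csv(out / "results_aggregated.csv", index=False)
        (out / "manifests").mkdir(exist_ok=True)
        for (cid, mode, trial), split in manifests.items():
            split.save(out / "manifests" / f"{cid}_{mode}_t{trial}.json")
        with open(out / "failures.json", "w") as fh:
            json.dump(failures, fh, indent=1)
        with open(out / "config.json", "w") as fh:
            json.dump(_config_to_jsonable(config), fh, indent=1, default=str)
    if failures:
        logger.warning("%d stage failures (see failures.json)", len(failures))
    return trials_df, agg_df


def _config_to_jsonable(config: ExperimentConfig) -> dict:
    d = asdict(config)
    return d


# --- built-in experiment recipes ---------------------------------------


def leakage_study_config(seed: int = 0, **overrides) -> ExperimentConfig:
    """Random vs AXV splits for the kernel SVM and 1NN control."""
    return ExperimentConfig(
        split_modes=(RANDOM, AXV),
        methods=("svm_mmp", "knn1"),
        seed=seed,
        **overrides,
    )


def balance_study_config(seed: int = 0, **overrides) -> ExperimentConfig:
    """Balanced vs imbalanced training for SVM (10 AC-richest classes)."""
    return ExperimentConfig(
        split_modes=(RANDOM, AXV),
        balance_modes=(IMBALANCED, BALANCED),
        methods=("svm_mmp",),
        seed=seed,
        **overrides,
    )


def restrict_to_ac_richest(
    config: ExperimentConfig, n_keep: int = 10
) -> ExperimentConfig:
    """Keep only the n classes with most ACs (re-generates to count)."""
    classes = load_classes(config)
    scored = []
    for cls in classes:
        mmps = build_mmps(cls)
        threshold = lab.compute_class_threshold(cls, mmps, config.threshold_policy)
        counts = lab.label_counts(lab.label_mmps(mmps, threshold))
        scored.append((counts[lab.AC], cls.class_id))
    scored.sort(reverse=True)
    keep = tuple(sorted(cid for _, cid in scored[:n_keep]))
    logger.info("AC-richest classes kept: %s", keep)
    return replace(config, keep_classes=keep)
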