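# mmpcliff

Activity-cliff prediction from matched molecular pairs, as a tested,
reusable pipeline.

An **activity cliff (AC)** is a pair of structurally analogous compounds
with a large potency difference against the same target — the sharpest
form of SAR discontinuity and a notoriously hard prediction target,
because the unit of prediction is a *pair* of molecules rather than a
single one. `mmpcliff` is aimed at computational chemists who want to
benchmark pair-based AC classifiers under controlled conditions,
including the data-leakage regime that inflates most published accuracy
numbers.

The pipeline:

1. **Compound tables → MMPs.** Structural analogy is formalized as the
   matched molecular pair (MMP): two compounds sharing a core and
   differing by one substituent at a single site, enumerated by
   single-cut fragmentation over acyclic single bonds with size
   constraints (substituents ≤ 13 heavy atoms, core ≥ 10 heavy atoms and
   ≥ 2× either substituent, substituent size difference ≤ 8).
2. **Class-dependent cliff labeling.** For each activity class a
   threshold T is derived from the class's ΔpKi distribution
   (mean + 2·SD by default; the classical fixed 100-fold criterion,
   T = 2, is also available). An MMP is an AC when ΔpKi ≥ T, a nonAC
   when ΔpKi < 1 (less than tenfold), and excluded in between.
3. **Pair representations.** (a) A class-specific three-block binary
   fingerprint — core features, substituent-unique features (symmetric
   difference), substituent-common features (intersection) — built from
   collision-free sorted circular-environment identifiers; (b) a
   condensed-graph-of-reaction (CGR) pseudo-molecule joining the core to
   the weak-compound substituent by an order-1 bond and to the potent
   one by a hypothetical order-0 bond.
4. **Leakage-aware splits.** Random 80/20 MMP splits (compound overlap
   between train and test possible) versus advanced cross-validation
   (AXV): hold out compounds *before* pairing so train and test MMPs
   share no compound. Optional training-set balancing by nonAC
   undersampling.
5. **Nine classifiers.** SVM with the MMP kernel
   K(x, y) = Tanimoto(core) × Tanimoto(substituents), 1NN/5NN controls
   over the same kernel, random forest, XGBoost, two fully connected
   networks (single fingerprint vs. per-block branches) and two message
   passing networks (single CGR vs. per-fragment subgraphs), each with
   seeded trial-based hyperparameter search under stratified internal
   cross-validation.
6. **Evaluation.** Balanced accuracy, Matthews correlation coefficient,
   recall and precision (AC positive), averaged over independent trials
   and emitted as tidy CSV/JSON.

Because public bioactivity extracts cannot ship with the package, a
first-class **synthetic generator** builds congeneric series
(scaffold ⊕ substituent assemblies with one variable site) with planted
cliff substituents, class-specific potency distributions, and
context-dependent SAR — so every stage runs and is testable at desk
scale, with known ground truth.

## Worked example

```python
from mmpcliff import (
    SyntheticClassConfig, ThresholdPolicy, build_mmps,
    compute_class_threshold, label_mmps, ModelSpec, train_model,
)
from mmpcliff.labeling import EXCLUDED, label_counts
from mmpcliff.metrics import compute_metrics, confusion
from mmpcliff.representations import build_vocabularies, encode_mmp_fingerprint
from mmpcliff.splits import random_split
from mmpcliff.synthetic import generate_class

cls, truth = generate_class(SyntheticClassConfig(seed=7))
mmps = build_mmps(cls)
threshold = compute_class_threshold(cls, mmps, ThresholdPolicy())
labeled = [lm for lm in label_mmps(mmps, threshold) if lm.label != EXCLUDED]
print(f"{len(cls)} compounds -> {len(mmps)} MMPs, threshold {threshold:.2f}")
print("labels:", label_counts(label_mmps(mmps, threshold)))

split = random_split([lm.mmp for lm in labeled], test_fraction=0.2, seed=0)
train = [lm for lm in labeled if lm.mmp.key in split.train_ids]
test = [lm for lm in labeled if lm.mmp.key in split.test_ids]
vocab = build_vocabularies([lm.mmp for lm in train])
fp = {lm.mmp.key: encode_mmp_fingerprint(lm.mmp, vocab) for lm in labeled}

model = train_model(
    ModelSpec.default("svm_mmp", seed=0),
    [fp[lm.mmp.key] for lm in train], [lm.label for lm in train],
)
pred, _ = model.predict([fp[lm.mmp.key] for lm in test])
m = compute_metrics(confusion([lm.label for lm in test], pred))
print(f"SVM (MMP kernel) test BA={m['ba']:.3f} MCC={m['mcc']:.3f} "
      f"recall={m['recall']:.3f} precision={m['precision']:.3f}")
```

Output:

```
252 compounds -> 1638 MMPs, threshold 3.21
labels: {'AC': 123, 'nonAC': 1018, 'excluded': 497}
SVM (MMP kernel) test BA=0.884 MCC=0.780 recall=0.793 precision=0.821
```

Reading: a 252-compound class yields 1638 MMPs; the adaptive threshold
(3.21 log units, about 1600-fold) labels 123 pairs as cliffs. Under a
random split — where test pairs share compounds with training pairs —
the MMP-kernel SVM looks excellent (MCC 0.78). Re-running the same class
under an AXV split (`mmpcliff.splits.axv_split`) drops the MCC to near
0.2: most of the apparent skill was compound memorization, the central
caution this pipeline is built to expose.

A `mmpcliff` console command exposes the stages
(`generate`, `mmp`, `label`, `split`, `featurize`, `audit`, `run`); see
`mmpcliff --help`. `run` executes a YAML-configured experiment grid and
writes per-trial results, aggregates, and split manifests that make any
row exactly re-runnable.

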