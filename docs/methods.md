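# Methods

This note documents the models, conventions, and numerical choices
behind `mmpcliff`, and what the synthetic benchmark does and does not
establish.

## Problem setting

Given an activity class — compounds with measured potency (pKi, the
negative decadic logarithm of a molar Ki/Kd) against one target — the
task is binary classification of compound *pairs*: does a matched
molecular pair (MMP) form an activity cliff (AC)? Pair-level prediction
has a failure mode that molecule-level QSAR does not: when pairs are
split randomly into train and test sets, the same compound can appear
on both sides, and a model can score well by memorizing compounds
rather than learning what makes a transformation a cliff. Quantifying
that gap is the pipeline's main purpose.

## Input curation

Potencies are converted to pKi (`pKi = −log10(value in mol/L)`; nM
inputs are scaled by 1e−9). Replicates of a compound are combined by
arithmetic mean when their range is ≤ 1.0 log unit; otherwise the
compound is discarded as unreliable. This is a conservative standard
convention — assay-level reconciliation is out of scope. Disconnected
structures (salts, mixtures) are rejected rather than desalted so that
no silent structure editing occurs. A molecular-mass filter
(default < 1000 Da) drops non-drug-like entries. Upstream
database-specific filters (assay confidence, relationship type) are
treated as extraction concerns and are not re-implemented.

## MMP enumeration

Every acyclic single bond between two heavy atoms is a cut candidate;
cutting yields a (core, substituent) pair with the core the larger
side (both orientations on ties). Hydrogen is not a substituent: each
substituent has ≥ 1 heavy atom. Fragmentations are indexed by canonical
fragment SMILES (attachment point as a generic `*` atom; attachment
position is part of the key, so positional isomers have distinct
cores). Two compounds sharing a core with different substituents form
an MMP when the size rules hold: substituents ≤ 13 heavy atoms, core
≥ 10 heavy atoms and ≥ 2× the larger substituent, substituent size
difference ≤ 8. If a pair qualifies through several cores, the largest
core (most specific transformation) wins; ties break on the
lexicographically smallest core string. Pairs are oriented weak-potency
first, and output is sorted by compound ids, so enumeration is
deterministic and independent of input order.

## Cliff labeling

The class threshold T is, by default, mean + 2 sample standard
deviations (n−1) of the class's MMP ΔpKi distribution
(`diffdist_mean_plus_2sd`). Two alternatives are selectable: the same
statistic over the compound potency values themselves
(`potency_mean_plus_2sd`) — a literal potency-distribution reading that
typically lands far above any observable ΔpKi and yields very few or
zero ACs — and a fixed threshold (`fixed`, e.g. 2.0 for the classical
100-fold criterion). Labels: AC when ΔpKi ≥ T (inclusive), nonAC when
ΔpKi < 1 (exclusive at exactly tenfold), excluded otherwise. The buffer
zone guards against potency-measurement boundary effects and is removed
before model training. Note a deliberate consequence of the adaptive
threshold: in degenerate classes whose ΔpKi distribution is a sharp
mixture (e.g. noise-free data where cliff pairs all sit at exactly the
cliff effect), mean + 2·SD can exceed the largest observed ΔpKi and
label zero ACs; the fixed policy is the right tool for such data.

## Representations

**Fingerprints.** Circular atom environments (radii 1 and 2, i.e. bond
diameters 2 and 4) are computed per fragment with the attachment point
as a distinct atom type; the smallest-environment tier (single atoms,
radius 0) is omitted to de-emphasize trivial features. The radius set is
configurable. Observed environment identifiers are sorted ascending and
mapped bijectively to bits — no hashing, hence no collisions — giving a
class-specific fingerprint length. An MMP fingerprint is the
concatenation of three blocks: core features, the symmetric difference
of the two substituents' feature sets (what the transformation
changes), and their intersection (what it preserves). One shared
substituent vocabulary backs both substituent blocks. Vocabularies are
built from training MMPs only; feature ids unseen in training are
dropped at encoding time. Building the vocabulary on the full class
would leak test-set features into the representation.

**CGR graphs.** The core and both substituents form one connected
pseudo-molecule: substituent attachment atoms bond to the core
attachment atom — the weak compound's substituent through an order-1
edge, the potent one through a hypothetical order-0 edge — and the
marker atoms are removed. Atom features: element one-hot (+other),
heavy degree (counting the attachment edge), formal charge, aromatic
and ring flags, attached-H count. Bond features: order one-hot
{0, 1, 1.5, 2, 3}, conjugation, ring flag. Node order is core, weak
substituent, potent substituent, each canonically ranked, so graphs are
deterministic functions of the MMP.

## Splits

Random splits partition MMPs uniformly (test size = round(n·fraction),
at least 1). AXV holds out round(n·fraction) compounds *before*
pairing: MMPs with no hold-out compound train, with two hold-out
compounds test, and mixed pairs are discarded — approximately
2f(1−f) of MMPs at hold-out fraction f. Train/test compound
disjointness is guaranteed by construction and asserted by
`audit_leakage`. A fresh hold-out is drawn per trial seed. Balancing
undersamples training nonACs (without replacement) to the AC count;
test sets always keep their natural imbalance, matching the realistic
deployment scenario where cliffs are rare.

## Models

All nine classifiers share one contract: train on labeled instances,
predict labels and an AC score.

* **svm_mmp** — SVC with a precomputed MMP-kernel Gram,
  K(x, y) = Tanimoto(core blocks) × Tanimoto(concatenated substituent
  blocks); balanced class weights; C chosen over the grid
  10^{−2, −1.6, …, 2} (exponent range −2…2 in 10 equal intervals). The
  kernel is a product of Tanimoto kernels and therefore positive
  semidefinite; Tanimoto(∅, ∅) = 1 by convention (identical empty
  feature sets; configurable to 0). Reported AC scores are a logistic
  transform of the SVM decision value — a monotone ranking score, not a
  calibrated probability.
* **knn1 / knn5** — nearest-neighbor controls under the same kernel;
  similarity ties break to the lower training index, vote ties to
  nonAC.
* **rf / xgb** — random forest (balanced class weights) and XGBoost on
  the concatenated fingerprint.
* **fcnn / fcnn_sep** — fully connected networks (NumPy
  implementation): ReLU hidden layers with monotonically non-increasing
  widths, two-unit softmax output, cross-entropy weighted on the AC
  class by the nonAC:AC ratio, Adam, step learning-rate schedule
  (multiplier 0.1 every `step_size` epochs; a multiplier of 0 — which
  would freeze training after the first step — is available but not the
  default), batch size min(128, n_train), dropout optional. fcnn_sep
  feeds the three fingerprint blocks through separate branches before a
  shared head.
* **mpnn / mpnn_sep** — message passing networks on CGR graphs: node
  states initialized from atom features, then T steps of
  H ← ReLU(H + A·(H·Wm) + B) where B aggregates edge-feature
  projections per node (the order-0 edge therefore enters every
  message-passing step); mean readout over node states; fully connected
  head with softmax. The mean (rather than sum) readout keeps the graph
  vector on a size-independent scale — summed ReLU activations over
  ~30-atom graphs saturate the softmax at initialization and stall
  training. mpnn_sep runs the same encoder on the three role subgraphs
  (attachment edges removed) and concatenates the readouts. Gradients
  are implemented analytically and verified against central differences
  in the test suite.

**Hyperparameter search** draws `n_trials` parameter samples from the
method's space (uniform over choices, log-uniform over rates) and
scores each by mean MCC over stratified k-fold cross-validation within
the training set (k = 3), refitting the best sample on the full
training set; everything is seeded. Networks train 50 epochs during the
search and 100 for the final fit. The search spaces (trees 100–500,
depths 3–12, XGB learning rate 10^−3–0.3, FCNN widths from
{512…64} monotone, MPNN 2–4 steps at hidden dim 64–256) are this
package's defaults, chosen as conventional ranges for these model
families at desk scale.

## Evaluation

AC is the positive class. BA = mean of the two per-class recalls; MCC
with the 0-convention for vanishing denominators; precision is reported
as an explicit undefined marker (not 0) when no positive prediction was
made, and trial averages skip undefined values with a logged count.
Default experiment design: 3 independent trials (fresh split, search,
and fit seeds), aggregated by arithmetic mean.

## The synthetic benchmark

`generate_class` assembles compounds as scaffold ⊕ substituent with one
variable site, from shipped libraries of 24 fused-ring scaffolds
(13–16 heavy atoms, all internal bonds in rings, so the only cuttable
scaffold bond is the attachment) and 28 substituents (1–6 heavy atoms).
Every same-scaffold pair passes the MMP size filters by construction
(scaffolds are ≥ 2× the largest substituent). The potency model is

    pKi(s, r) = baseline(s) + beta(s, r) + N(0, noise_sd²)

with scaffold baselines N(6.5, 1.0²) (a typical class-mean pKi and
between-series spread for Ki-based classes), measurement noise
SD 0.3 log units (typical inter-assay reproducibility), and a planted
cliff effect of 3.0 log units against non-cliff effects N(0, 0.5²).

Two mechanisms make the SAR context-dependent, i.e. make part of a
compound's activity a property of the individual compound rather than
of its substituent: a designated cliff substituent (15% of the library
by default) expresses its effect on a given scaffold only with
probability 0.5 (`cliff_penetrance`), and non-cliff effects carry a
per-(scaffold, substituent) interaction term N(0, 0.35²). Both are
fixed compound properties: under a random pair split they are
memorizable through shared compounds, under AXV they are invisible for
held-out compounds. Without them, substituent identity alone would
transfer across scaffolds and leakage-free prediction would be nearly
as easy as leaky prediction — unlike real congeneric-series data, where
potency is notoriously context-sensitive. With them, the benchmark
reproduces the qualitative leakage phenomenology: high random-split
scores, a sharp drop under AXV, and per-class random ≥ AXV ordering for
both the kernel SVM and the 1NN control (the 1NN ordering is the
noisiest of these quantities and can dip below a 8/10 class majority at
some suite seeds).

Default class size is 18 scaffolds × 14 substituents ≈ 250 compounds
(~1600 MMPs), inside the 200–400 compound range the benchmark targets;
the 10-class suite jitters scaffold counts, substituent counts, and
cliff fractions per class and derives per-class seeds from one master
seed. The deterministic `fixture_class` (2 scaffolds × 6 substituents,
noise-free, one cliff substituent) has a fully hand-enumerable MMP list
(22 MMPs; 10 AC / 6 nonAC / 6 excluded at the fixed 2.0 threshold) and
anchors exact-value tests, including a deliberately oversized
benzyloxy substituent that can only pair through an extended ether
core.

**What the benchmark does not show.** Synthetic classes have a single
variable site, small substituents, no stereochemistry, no correlated
assay artifacts, and an additive potency model; real SAR contains
multi-site variation, nonadditivity beyond the planted interaction
term, and heavy-tailed noise. Passing results demonstrate that the
machinery is correct and that the leakage effect is detected where it
is planted — not that any model's absolute accuracy transfers to real
bioactivity data.

## Problem sizes and determinism

The shipped experiment recipes run 10 classes × 2 split modes × 3
trials with 10 search trials per model — about half a minute for the
SVM/1NN benchmark on one CPU. All randomness flows from explicit seeds
(NumPy `default_rng`; per-trial seeds derived from the master seed), so
every results row is exactly reproducible from its config and split
manifest.

## Known limitations

* Attachment-point symmetry is not merged: equivalent ring positions
  with different canonical strings count as different cores.
* SVM scores are uncalibrated; if calibrated probabilities are needed,
  Platt scaling should be fitted on held-out folds.
* The per-fold hyperparameter search reuses the outer training
  vocabulary rather than rebuilding one per inner fold; features from
  inner validation folds are therefore visible during the search
  (training-set internal only — the test set never contributes
  features).
* XGBoost uses its library defaults for class imbalance (no
  `scale_pos_weight`), mirroring how the decision-tree baselines are
  typically run in this setting.
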