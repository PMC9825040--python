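"""The nine AC classifier configurations behind one train/predict API.

Fingerprint methods: MMP-kernel SVM (``svm_mmp``), 1NN/5NN controls over
the same kernel, random forest, XGBoost, and the two fully connected
networks. Graph methods: MPNN and MPNN_sep over CGR inputs.

Hyperparameters are chosen by a seeded trial-based search: ``n_trials``
parameter samples are drawn from the method's space and scored by mean
objective (MCC by default) over stratified internal cross-validation
folds; the best sample is refit on the full training set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from xgboost import XGBClassifier

from ..labeling import AC, NONAC
from ..metrics import compute_metrics, confusion
from ..representations import MMPFingerprint
from .fcnn import FCNNClassifier, FCNNSepClassifier
from .kernels import mmp_gram
from .mpnn import MPNNClassifier

logger = logging.getLogger(__name__)

FINGERPRINT_METHODS = ("svm_mmp", "knn1", "knn5", "rf", "xgb", "fcnn", "fcnn_sep")
GRAPH_METHODS = ("mpnn", "mpnn_sep")
METHODS = FINGERPRINT_METHODS + GRAPH_METHODS

#: C grid: exponents -2..2 in 10 equal intervals (11 points)
SVM_C_GRID = tuple(float(10.0**e) for e in np.linspace(-2.0, 2.0, 11))

DEFAULT_SPACES = {
    "svm_mmp": {"C": ("choice", SVM_C_GRID)},
    "knn1": {},
    "knn5": {},
    "rf": {"n_estimators": ("int", 100, 500), "max_depth": ("int", 3, 12)},
    "xgb": {
        "n_estimators": ("int", 100, 500),
        "max_depth": ("int", 3, 12),
        "learning_rate": ("loguniform", 1e-3, 0.3),
    },
    "fcnn": {
        "hidden": ("choice", ((256, 128), (128, 64), (256, 128, 64), (128,), (64,))),
        "dropout": ("uniform", 0.0, 0.5),
        "lr": ("loguniform", 1e-4, 1e-2),
        "step_size": ("int", 10, 50),
    },
    "fcnn_sep": {
        "branch_width": ("choice", (64, 128)),
        "hidden": ("choice", ((128, 64), (64,), (128,))),
        "dropout": ("uniform", 0.0, 0.5),
        "lr": ("loguniform", 1e-4, 1e-2),
        "step_size": ("int", 10, 50),
    },
    "mpnn": {
        "hidden_dim": ("choice", (64, 128, 256)),
        "n_steps": ("int", 2, 4),
        "head": ("choice", ((64,), (128, 64))),
        "lr": ("loguniform", 1e-4, 1e-2),
        "step_size": ("int", 10, 50),
    },
    "mpnn_sep": {
        "hidden_dim": ("choice", (64, 128, 256)),
        "n_steps": ("int", 2, 4),
        "head": ("choice", ((64,), (128, 64))),
        "lr": ("loguniform", 1e-4, 1e-2),
        "step_size": ("int", 10, 50),
    },
}


@dataclass(frozen=True)
class ModelSpec:
    method: str
    space: dict = field(default_factory=dict)
    hpo_trials: int = 10
    hpo_folds: int = 3
    objective: str = "mcc"
    epochs_search: int = 50
    epochs_final: int = 100
    batch_size: int = 128
    lr_gamma: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")

    @classmethod
    def default(cls, method: str, **overrides) -> "ModelSpec":
        return cls(method=method, space=dict(DEFAULT_SPACES[method]), **overrides)

    @property
    def representation(self) -> str:
        return "cgr" if self.method in GRAPH_METHODS else "fingerprint"


def sample_params(space: dict, rng: np.random.Generator) -> dict:
    out = {}
    for name, dist in space.items():
        kind = dist[0]
        if kind == "choice":
            options = dist[1]
            out[name] = options[int(rng.integers(len(options)))]
        elif kind == "int":
            out[name] = int(rng.integers(dist[1], dist[2] + 1))
        elif kind == "uniform":
            out[name] = float(rng.uniform(dist[1], dist[2]))
        elif kind == "loguniform":
            out[name] = float(
                np.exp(rng.uniform(np.log(dist[1]), np.log(dist[2])))
            )
        else:
            raise ValueError(f"unknown distribution kind {kind!r}")
    return out


def _as_int_labels(labels) -> np.ndarray:
    return np.array([1 if l == AC else 0 for l in labels], dtype=int)


def _as_str_labels(y) -> list[str]:
    return [AC if v == 1 else NONAC for v in y]


def knn_predict(query_sims: np.ndarray, train_y: np.ndarray, k: int):
    """Majority label over the k most similar training MMPs.

    ``query_sims``: (n_query, n_train) kernel matrix. Similarity ties are
    broken toward the lower training index (stable sort); an exact vote
    tie goes to the negative class.
    """
    if k < 1 or k > query_sims.shape[1]:
        raise ValueError(f"k={k} outside 1..{query_sims.shape[1]}")
    order = np.argsort(-query_sims, axis=1, kind="stable")[:, :k]
    votes = train_y[order].mean(axis=1)
    return (votes > 0.5).astype(int), votes


class TrainedModel:
    """Fitted state plus a uniform predict contract and provenance."""

    def __init__(self, spec, params, impl, train_fps=None, train_y=None, block_dims=None):
        self.spec = spec
        self.params = params
        self._impl = impl
        self._train_fps = train_fps
        self._train_y = train_y
        self._block_dims = block_dims

    @property
    def provenance(self) -> dict:
        return {
            "method": self.spec.method,
            "seed": self.spec.seed,
            "params": {k: str(v) for k, v in self.params.items()},
        }

    def predict(self, instances):
        """Return (labels, P(AC)) for a list of instances, order-preserving."""
        if len(instances) == 0:
            return [], np.zeros(0)
        method = self.spec.method
        if method in ("knn1", "knn5"):
            k = 1 if method == "knn1" else 5
            sims = mmp_gram(instances, self._train_fps)
            y, votes = knn_predict(sims, self._train_y, k)
            return _as_str_labels(y), votes
        if method == "svm_mmp":
            gram = mmp_gram(instances, self._train_fps)
            decision = self._impl.decision_function(gram)
            prob = 1.0 / (1.0 + np.exp(-decision))  # monotone score, not calibrated
            return _as_str_labels((decision > 0).astype(int)), prob
        if method in ("rf", "xgb"):
            X = np.stack([fp.full for fp in instances])
            prob = self._impl.predict_proba(X)[:, 1]
            return _as_str_labels((prob >= 0.5).astype(int)), prob
        if method in ("fcnn", "fcnn_sep"):
            X = np.stack([fp.full for fp in instances])
            prob = self._impl.predict_proba(X)[:, 1]
            return _as_str_labels((prob >= 0.5).astype(int)), prob
        # graph methods
        prob = self._impl.predict_proba(instances)[:, 1]
        return _as_str_labels((prob >= 0.5).astype(int)), prob


def _fit_impl(spec: ModelSpec, params: dict, instances, y, epochs: int):
    method = spec.method
    seed = spec.seed % (2**31)
    if method == "svm_mmp":
        gram = mmp_gram(instances)
        impl = SVC(
            kernel="precomputed",
            C=params.get("C", 1.0),
            class_weight="balanced",
            random_state=seed,
        )
        impl.fit(gram, y)
        return impl
    if method in ("knn1", "knn5"):
        return None  # lazy learner: training set is the model
    if method == "rf":
        impl = RandomForestClassifier(
            n_estimators=params.get("n_estimators", 200),
            max_depth=params.get("max_depth"),
            class_weight="balanced",
            random_state=seed,
            n_jobs=1,
        )
        impl.fit(np.stack([fp.full for fp in instances]), y)
        return impl
    if method == "xgb":
        impl = XGBClassifier(
            n_estimators=params.get("n_estimators", 200),
            max_depth=params.get("max_depth", 6),
            learning_rate=params.get("learning_rate", 0.1),
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
        )
        impl.fit(np.stack([fp.full for fp in instances]), y)
        return impl
    common = dict(
        dropout=params.get("dropout", 0.0),
        lr=params.get("lr", 1e-3),
        step_size=params.get("step_size", 30),
        lr_gamma=spec.lr_gamma,
        epochs=epochs,
        batch_size=spec.batch_size,
        seed=seed,
    )
    if method == "fcnn":
        impl = FCNNClassifier(hidden=params.get("hidden", (128, 64)), **common)
        impl.fit(np.stack([fp.full for fp in instances]), y)
        return impl
    if method == "fcnn_sep":
        fp0 = instances[0]
        impl = FCNNSepClassifier(
            block_dims=(
                len(fp0.core_bits),
                len(fp0.unique_bits),
                len(fp0.common_bits),
            ),
            branch_width=params.get("branch_width", 64),
            hidden=params.get("hidden", (64,)),
            **common,
        )
        impl.fit(np.stack([fp.full for fp in instances]), y)
        return impl
    impl = MPNNClassifier(
        hidden_dim=params.get("hidden_dim", 64),
        n_steps=params.get("n_steps", 3),
        head=params.get("head", (64,)),
        separate=method == "mpnn_sep",
        **common,
    )
    impl.fit(instances, y)
    return impl


def _metric_or_neginf(spec, y_true, y_pred) -> float:
    c = confusion(_as_str_labels(y_true), _as_str_labels(y_pred))
    value = compute_metrics(c)[spec.objective]
    return -np.inf if value is None else value


def _score(spec, params, instances, y, train_idx, val_idx, gram=None) -> float:
    if gram is not None and spec.method == "svm_mmp":
        impl = SVC(
            kernel="precomputed",
            C=params.get("C", 1.0),
            class_weight="balanced",
            random_state=spec.seed % (2**31),
        )
        impl.fit(gram[np.ix_(train_idx, train_idx)], y[train_idx])
        pred = (impl.decision_function(gram[np.ix_(val_idx, train_idx)]) > 0).astype(int)
        return _metric_or_neginf(spec, y[val_idx], pred)
    if gram is not None and spec.method in ("knn1", "knn5"):
        k = 1 if spec.method == "knn1" else 5
        pred, _ = knn_predict(gram[np.ix_(val_idx, train_idx)], y[train_idx], k)
        return _metric_or_neginf(spec, y[val_idx], pred)
    train_inst = [instances[i] for i in train_idx]
    impl = _fit_impl(spec, params, train_inst, y[train_idx], spec.epochs_search)
    model = TrainedModel(
        spec,
        params,
        impl,
        train_fps=train_inst if spec.representation == "fingerprint" else None,
        train_y=y[train_idx],
    )
    pred, _ = model.predict([instances[i] for i in val_idx])
    c = confusion(_as_str_labels(y[val_idx]), pred)
    value = compute_metrics(c)[spec.objective]
    return -np.inf if value is None else value


def hyperparameter_search(
    spec: ModelSpec,
    instances,
    labels,
    n_trials: int | None = None,
    n_folds: int | None = None,
    objective: str | None = None,
    seed: int | None = None,
) -> dict:
    """Best parameter sample under mean CV objective; deterministic in seed."""
    n_trials = n_trials if n_trials is not None else spec.hpo_trials
    n_folds = n_folds if n_folds is not None else spec.hpo_folds
    seed = seed if seed is not None else spec.seed
    if objective is not None:
        spec = replace(spec, objective=objective)
    if n_trials < 1 or n_folds < 2:
        raise ValueError("need n_trials >= 1 and n_folds >= 2")
    y = _as_int_labels(labels)
    if min(np.bincount(y, minlength=2)) < n_folds:
        raise ValueError("a class has fewer members than folds")
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31))
    folds = list(skf.split(np.zeros(len(y)), y))
    gram = (
        mmp_gram(instances)
        if spec.method in ("svm_mmp", "knn1", "knn5")
        else None
    )
    best_params, best_score = {}, -np.inf
    for trial in range(n_trials):
        params = sample_params(spec.space, rng)
        scores = [
            _score(spec, params, instances, y, tr, va, gram=gram) for tr, va in folds
        ]
        mean_score = float(np.mean(scores))
        logger.debug("trial %d %s -> %.4f", trial, params, mean_score)
        if mean_score > best_score:
            best_params, best_score = params, mean_score
    return best_params


def train_model(spec: ModelSpec, train_instances, train_labels) -> TrainedModel:
    """Fit one classifier, searching hyperparameters when a space is set."""
    y = _as_int_labels(train_labels)
    if len(set(y.tolist())) < 2:
        raise ValueError("training set must contain both labels")
    if spec.representation == "fingerprint" and not isinstance(
        train_instances[0], MMPFingerprint
    ):
        raise TypeError(f"{spec.method} expects MMPFingerprint instances")
    params = {}
    if spec.space and spec.hpo_trials > 0:
        params = hyperparameter_search(spec, train_instances, train_labels)
    impl = _fit_impl(spec, params, train_instances, y, spec.epochs_final)
    return TrainedModel(
        spec,
        params,
        impl,
        train_fps=list(train_instances)
        if spec.representation == "fingerprint"
        else None,
        train_y=y,
    )


def predict(model: TrainedModel, instances):
    return model.predict(instances)
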