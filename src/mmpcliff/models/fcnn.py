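"""Fully connected AC classifiers over MMP fingerprints.

``FCNNClassifier`` consumes the single concatenated MMP fingerprint;
``FCNNSepClassifier`` sends the core, substituent-unique and
substituent-common blocks through separate branches whose outputs are
concatenated and passed to a shared head.
"""

from __future__ import annotations

import numpy as np

from .nn import (
    Dense,
    Sequence,
    build_mlp,
    positive_class_weight,
    softmax,
    train_network,
    weighted_ce_grad,
)


class FCNNClassifier:
    def __init__(
        self,
        hidden=(128, 64),
        dropout=0.0,
        lr=1e-3,
        step_size=30,
        lr_gamma=0.1,
        epochs=100,
        batch_size=128,
        seed=0,
    ):
        self.hidden = tuple(hidden)
        self.dropout = dropout
        self.lr = lr
        self.step_size = step_size
        self.lr_gamma = lr_gamma
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=int)
        rng = np.random.default_rng(self.seed)
        self.net_ = build_mlp(X.shape[1], self.hidden, rng, self.dropout)
        pos_w = positive_class_weight(y)

        def forward_backward(idx):
            logits = self.net_.forward(X[idx], training=True)
            loss, grad = weighted_ce_grad(logits, y[idx], pos_w)
            self.net_.backward(grad)
            return loss

        train_network(
            forward_backward,
            self.net_.params(),
            len(y),
            self.epochs,
            self.lr,
            self.step_size,
            self.lr_gamma,
            self.batch_size,
            rng,
        )
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=np.float64)
        return softmax(self.net_.forward(X, training=False))


class FCNNSepClassifier:
    def __init__(
        self,
        block_dims=None,  # (core, unique, common) input widths, set at fit
        branch_width=64,
        hidden=(64,),
        dropout=0.0,
        lr=1e-3,
        step_size=30,
        lr_gamma=0.1,
        epochs=100,
        batch_size=128,
        seed=0,
    ):
        self.block_dims = block_dims
        self.branch_width = branch_width
        self.hidden = tuple(hidden)
        self.dropout = dropout
        self.lr = lr
        self.step_size = step_size
        self.lr_gamma = lr_gamma
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed

    def _split(self, X):
        d1, d2, _ = self.block_dims
        return X[:, :d1], X[:, d1 : d1 + d2], X[:, d1 + d2 :]

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=int)
        if self.block_dims is None or sum(self.block_dims) != X.shape[1]:
            raise ValueError("block_dims must partition the fingerprint")
        rng = np.random.default_rng(self.seed)
        self.branches_ = [
            Sequence([Dense(d, self.branch_width, rng)]) for d in self.block_dims
        ]
        self.head_ = build_mlp(
            3 * self.branch_width, self.hidden, rng, self.dropout
        )
        pos_w = positive_class_weight(y)
        params = [p for b in self.branches_ for p in b.params()] + self.head_.params()

        def forward_backward(idx):
            blocks = self._split(X[idx])
            outs = [b.forward(x) for b, x in zip(self.branches_, blocks)]
            merged = np.concatenate(outs, axis=1)
            logits = self.head_.forward(merged, training=True)
            loss, grad = weighted_ce_grad(logits, y[idx], pos_w)
            gmerged = self.head_.backward(grad)
            for i, b in enumerate(self.branches_):
                w = self.branch_width
                b.backward(gmerged[:, i * w : (i + 1) * w])
            return loss

        train_network(
            forward_backward,
            params,
            len(y),
            self.epochs,
            self.lr,
            self.step_size,
            self.lr_gamma,
            self.batch_size,
            rng,
        )
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=np.float64)
        outs = [b.forward(x) for b, x in zip(self.branches_, self._split(X))]
        return softmax(self.head_.forward(np.concatenate(outs, axis=1)))
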