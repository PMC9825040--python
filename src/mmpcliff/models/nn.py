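"""Minimal feed-forward network machinery in NumPy.

Two-unit softmax output read as P(nonAC), P(AC); binary cross-entropy
weighted on the positive class by the negative-to-positive sample
ratio; Adam optimizer with a step learning-rate schedule (the rate is
multiplied by ``lr_gamma`` every ``step_size`` epochs). Batch size is
128 or the training-set size, whichever is smaller. Hidden widths are
monotonically non-increasing.
"""

from __future__ import annotations

import numpy as np


class TrainingFailure(RuntimeError):
    pass


def relu(x):
    return np.maximum(x, 0.0)


def softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Dense:
    def __init__(self, n_in, n_out, rng, activation="relu"):
        # He initialization for ReLU layers
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.activation = activation

    def forward(self, x):
        self._x = x
        z = x @ self.W + self.b
        self._z = z
        return relu(z) if self.activation == "relu" else z

    def backward(self, grad):
        if self.activation == "relu":
            grad = grad * (self._z > 0)
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [("W", self), ("b", self)]


class Dropout:
    def __init__(self, rate, rng):
        self.rate = rate
        self.rng = rng
        self.training = False

    def forward(self, x):
        if not self.training or self.rate <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask

    def params(self):
        return []


class Sequence:
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, training=False):
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.training = training
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(obj, name)) for name, obj in params]
        self.v = [np.zeros_like(getattr(obj, name)) for name, obj in params]

    def step(self):
        self.t += 1
        for i, (name, obj) in enumerate(self.params):
            g = getattr(obj, "d" + name)
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            value = getattr(obj, name)
            setattr(
                obj, name, value - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            )


def weighted_ce_grad(logits, y, pos_weight):
    """Loss and d(loss)/d(logits) for class-weighted cross-entropy."""
    p = softmax(logits)
    n = len(y)
    w = np.where(y == 1, pos_weight, 1.0)
    eps = 1e-12
    loss = -np.mean(w * np.log(p[np.arange(n), y] + eps))
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    grad *= (w / n)[:, None]
    return loss, grad


def positive_class_weight(y) -> float:
    """Ratio of negative to positive training samples."""
    n_pos = int(np.sum(y == 1))
    n_neg = len(y) - n_pos
    if n_pos == 0:
        raise TrainingFailure("no positive samples")
    return n_neg / n_pos


def _lr_at(base_lr, epoch, step_size, gamma):
    return base_lr * (gamma ** (epoch // max(1, step_size)))


def train_network(
    forward_backward,
    param_list,
    n_samples,
    epochs,
    base_lr,
    step_size,
    lr_gamma,
    batch_size,
    rng,
):
    """Generic minibatch training loop.

    ``forward_backward(indices) -> loss`` must compute gradients into the
    layers' ``dW``/``db`` slots for the given sample indices.
    """
    opt = Adam(param_list, lr=base_lr)
    bs = min(batch_size, n_samples)
    for epoch in range(epochs):
        opt.lr = _lr_at(base_lr, epoch, step_size, lr_gamma)
        order = rng.permutation(n_samples)
        for start in range(0, n_samples, bs):
            idx = order[start : start + bs]
            loss = forward_backward(idx)
            if not np.isfinite(loss):
                raise TrainingFailure(f"non-finite loss at epoch {epoch}")
            opt.step()


def monotone_widths(widths) -> tuple[int, ...]:
    widths = tuple(int(w) for w in widths)
    if any(a < b for a, b in zip(widths, widths[1:])):
        raise ValueError(f"hidden widths must be non-increasing: {widths}")
    return widths


def build_mlp(n_in, hidden, rng, dropout=0.0, n_out=2):
    """Dense stack with ReLU hidden layers and a linear 2-unit head."""
    layers = []
    prev = n_in
    for w in monotone_widths(hidden):
        layers.append(Dense(prev, w, rng))
        if dropout > 0:
            layers.append(Dropout(dropout, rng))
        prev = w
    layers.append(Dense(prev, n_out, rng, activation="linear"))
    return Sequence(layers)
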