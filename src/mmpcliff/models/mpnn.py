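"""Message passing neural network over CGR pseudo-molecule graphs.

Node states are initialized from atom features, then refined for a
fixed number of steps: each node adds a ReLU-gated sum of linearly
transformed neighbor states plus an edge-feature term, with a residual
connection. A mean readout over node states feeds a fully connected
head ending in a two-unit softmax.

``separate=True`` (the MPNN_sep variant) runs the same encoder on the
three role subgraphs (core, weak substituent, potent substituent) with
the inter-fragment attachment edges removed and concatenates the three
readout vectors before the head.
"""

from __future__ import annotations

import numpy as np

from ..representations import CGRGraph, ROLE_CORE, ROLE_SUB_HIGH, ROLE_SUB_LOW
from .nn import (
    build_mlp,
    positive_class_weight,
    relu,
    softmax,
    train_network,
    weighted_ce_grad,
)


class _Params:
    """Named-attribute parameter holder compatible with the Adam loop."""


def _prepare(graph_nodes, graph_edges, graph_edge_feats):
    """Dense adjacency and directed edge arrays for one (sub)graph."""
    n = len(graph_nodes)
    A = np.zeros((n, n))
    src, dst, feats = [], [], []
    for (i, j), f in zip(graph_edges, graph_edge_feats):
        A[i, j] = 1.0
        A[j, i] = 1.0
        src += [i, j]
        dst += [j, i]
        feats += [f, f]
    E = np.array(feats, dtype=np.float64) if feats else np.zeros((0, 1))
    return {
        "X": np.asarray(graph_nodes, dtype=np.float64),
        "A": A,
        "dst": np.array(dst, dtype=int),
        "E": E,
    }


def _subgraphs(graph: CGRGraph):
    parts = []
    for role in (ROLE_CORE, ROLE_SUB_LOW, ROLE_SUB_HIGH):
        idx = [i for i, r in enumerate(graph.roles) if r == role]
        remap = {g: l for l, g in enumerate(idx)}
        edges, feats = [], []
        for (i, j), f in zip(graph.edges, graph.edge_features):
            if i in remap and j in remap:
                edges.append((remap[i], remap[j]))
                feats.append(f)
        parts.append(_prepare(graph.node_features[idx], edges, feats))
    return parts


class MPNNClassifier:
    def __init__(
        self,
        hidden_dim=64,
        n_steps=3,
        head=(64,),
        dropout=0.0,
        lr=1e-3,
        step_size=30,
        lr_gamma=0.1,
        epochs=100,
        batch_size=128,
        seed=0,
        separate=False,
    ):
        self.hidden_dim = hidden_dim
        self.n_steps = n_steps
        self.head = tuple(head)
        self.dropout = dropout
        self.lr = lr
        self.step_size = step_size
        self.lr_gamma = lr_gamma
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.separate = separate

    # --- encoder ---------------------------------------------------------

    def _encode(self, g):
        p = self.p_
        Z0 = g["X"] @ p.Wi + p.bi
        H = relu(Z0)
        if len(g["E"]):
            B = np.zeros_like(H)
            np.add.at(B, g["dst"], g["E"] @ p.We)
        else:
            B = 0.0
        cache = {"Z0": Z0, "H": [H], "Z": [], "g": g, "B": B}
        for _ in range(self.n_steps):
            Z = H + g["A"] @ (H @ p.Wm) + B
            H = relu(Z)
            cache["Z"].append(Z)
            cache["H"].append(H)
        # mean readout keeps the graph vector on a size-independent scale
        return H.mean(axis=0), cache

    def _encode_backward(self, d_readout, cache):
        p = self.p_
        g = cache["g"]
        n_nodes = cache["H"][-1].shape[0]
        dH = np.broadcast_to(d_readout / n_nodes, cache["H"][-1].shape).copy()
        dB = np.zeros_like(dH) if len(g["E"]) else None
        for t in range(self.n_steps - 1, -1, -1):
            dZ = dH * (cache["Z"][t] > 0)
            H_t = cache["H"][t]
            dP = g["A"].T @ dZ
            p.dWm += H_t.T @ dP
            if dB is not None:
                dB += dZ
            dH = dZ + dP @ p.Wm.T
        dZ0 = dH * (cache["Z0"] > 0)
        p.dWi += g["X"].T @ dZ0
        p.dbi += dZ0.sum(axis=0)
        if dB is not None and len(g["E"]):
            p.dWe += g["E"].T @ dB[g["dst"]]

    def _zero_grads(self):
        p = self.p_
        p.dWi = np.zeros_like(p.Wi)
        p.dbi = np.zeros_like(p.bi)
        p.dWm = np.zeros_like(p.Wm)
        p.dWe = np.zeros_like(p.We)

    def _readouts(self, prepared):
        """Forward all (sub)graphs of one instance; concat readouts."""
        vecs, caches = [], []
        for g in prepared:
            v, c = self._encode(g)
            vecs.append(v)
            caches.append(c)
        return np.concatenate(vecs), caches

    def _prepare_instances(self, graphs):
        out = []
        for graph in graphs:
            if self.separate:
                out.append(_subgraphs(graph))
            else:
                out.append(
                    [_prepare(graph.node_features, graph.edges, graph.edge_features)]
                )
        return out

    # --- scikit-learn style API ------------------------------------------

    def fit(self, graphs, y):
        y = np.asarray(y, dtype=int)
        rng = np.random.default_rng(self.seed)
        d_atom = graphs[0].node_features.shape[1]
        d_bond = graphs[0].edge_features.shape[1]
        H = self.hidden_dim
        p = _Params()
        p.Wi = rng.normal(0, np.sqrt(2.0 / d_atom), size=(d_atom, H))
        p.bi = np.zeros(H)
        p.Wm = rng.normal(0, np.sqrt(1.0 / H), size=(H, H)) / self.n_steps
        p.We = rng.normal(0, np.sqrt(2.0 / d_bond), size=(d_bond, H))
        self.p_ = p
        n_parts = 3 if self.separate else 1
        self.head_ = build_mlp(n_parts * H, self.head, rng, self.dropout)
        prepared = self._prepare_instances(graphs)
        pos_w = positive_class_weight(y)
        params = [("Wi", p), ("bi", p), ("Wm", p), ("We", p)] + self.head_.params()

        def forward_backward(idx):
            self._zero_grads()
            vecs, caches = [], []
            for i in idx:
                v, c = self._readouts(prepared[i])
                vecs.append(v)
                caches.append(c)
            G = np.stack(vecs)
            logits = self.head_.forward(G, training=True)
            loss, grad = weighted_ce_grad(logits, y[idx], pos_w)
            dG = self.head_.backward(grad)
            for row, cache_list in zip(dG, caches):
                for part, cache in enumerate(cache_list):
                    self._encode_backward(
                        row[part * H : (part + 1) * H], cache
                    )
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

    def predict_proba(self, graphs):
        vecs = [self._readouts(inst)[0] for inst in self._prepare_instances(graphs)]
        return softmax(self.head_.forward(np.stack(vecs), training=False))
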