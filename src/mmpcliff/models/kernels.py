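"""Tanimoto and MMP product kernels over binary MMP fingerprints.

The MMP kernel multiplies a core-similarity Tanimoto with a
substituent-similarity Tanimoto computed on the concatenated unique and
common substituent blocks. Two identical all-zero vectors (identical
empty feature sets) have similarity 1 by convention (configurable).
"""

from __future__ import annotations

import numpy as np

from ..representations import MMPFingerprint

#: value of Tanimoto(empty, empty); 1.0 treats identical empty sets as equal
EMPTY_EMPTY_SIMILARITY = 1.0


def tanimoto_kernel(a: np.ndarray, b: np.ndarray) -> float:
    """|a AND b| / |a OR b| for binary vectors of equal length."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("vectors differ in length")
    union = int(np.sum(a | b))
    if union == 0:
        return EMPTY_EMPTY_SIMILARITY
    return float(np.sum(a & b)) / union


def mmp_kernel(x: MMPFingerprint, y: MMPFingerprint) -> float:
    """Product of core and substituent Tanimoto similarities."""
    if len(x.core_bits) != len(y.core_bits) or len(x.unique_bits) != len(
        y.unique_bits
    ):
        raise ValueError("fingerprints come from different vocabularies")
    return tanimoto_kernel(x.core_bits, y.core_bits) * tanimoto_kernel(
        x.substituent_bits, y.substituent_bits
    )


def _stack(fps: list[MMPFingerprint]) -> tuple[np.ndarray, np.ndarray]:
    core = np.stack([fp.core_bits for fp in fps]).astype(np.float32)
    sub = np.stack([fp.substituent_bits for fp in fps]).astype(np.float32)
    return core, sub


def _tanimoto_gram_from_bits(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    inter = A @ B.T
    a = A.sum(axis=1, keepdims=True)
    b = B.sum(axis=1, keepdims=True)
    union = a + b.T - inter
    out = np.full(inter.shape, EMPTY_EMPTY_SIMILARITY, dtype=np.float64)
    np.divide(inter, union, out=out, where=union > 0)
    return out


def tanimoto_gram(X: list[np.ndarray] | np.ndarray, Y=None) -> np.ndarray:
    A = np.stack(X).astype(np.float32)
    B = A if Y is None else np.stack(Y).astype(np.float32)
    return _tanimoto_gram_from_bits(A, B)


def mmp_gram(
    X: list[MMPFingerprint], Y: list[MMPFingerprint] | None = None
) -> np.ndarray:
    """Dense Gram matrix of the MMP kernel, rows X by columns Y."""
    xc, xs = _stack(X)
    if Y is None:
        yc, ys = xc, xs
    else:
        yc, ys = _stack(Y)
    return _tanimoto_gram_from_bits(xc, yc) * _tanimoto_gram_from_bits(xs, ys)
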