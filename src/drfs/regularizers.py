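"""Regularization terms evaluated on a d x r feature-weight matrix.

Two penalties: a class-local term summing Laplacian quadratic forms of the
per-class weight columns over the class-specific feature graphs, and a
global redundancy term summing cross-column bilinear forms over the global
feature graph.  The expansion form of the global term is kept as an
independent oracle for testing.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import scipy.sparse as sp

from drfs.feature_graphs import FeatureGraph, GraphLaplacian


def _as_array(M: FeatureGraph | np.ndarray | sp.csr_array):
    if isinstance(M, FeatureGraph):
        return M.sim
    return M


def omega_local(W: np.ndarray, class_laps: Sequence[GraphLaplacian]) -> float:
    """Sum over classes l of w_l^T L^(l) w_l. Non-negative (each L is PSD)."""
    W = np.asarray(W, dtype=float)
    d, r = W.shape
    if len(class_laps) != r:
        raise ValueError(f"expected {r} Laplacians, got {len(class_laps)}")
    total = 0.0
    for l, L in enumerate(class_laps):
        if L.d != d:
            raise ValueError(f"Laplacian {l} has size {L.d}, expected {d}")
        total += L.quad(W[:, l])
    return float(total)


def omega_global(W: np.ndarray, M: FeatureGraph | np.ndarray) -> float:
    """Sum over ordered class pairs p != q of w_p^T M w_q.

    Computed as s^T M s - sum_p w_p^T M w_p with s the row-sum vector.
    """
    W = np.asarray(W, dtype=float)
    A = _as_array(M)
    if A.shape[0] != W.shape[0]:
        raise ValueError("graph size does not match weight rows")
    s = W.sum(axis=1)
    MW = A @ W
    return float(s @ (A @ s) - np.einsum("ij,ij->", W, MW))


def omega_global_expansion(W: np.ndarray, M: FeatureGraph | np.ndarray) -> float:
    """Explicit double-sum expansion of the redundancy term (test oracle).

    sum_ij |w_i||w_j| M_ij  -  sum_ij sum_p W_ip W_jp M_ij,
    with |w_i| the i-th row sum of W.  Deliberately written as plain loops
    over entries so it shares no code path with :func:`omega_global`.
    """
    W = np.asarray(W, dtype=float)
    A = _as_array(M)
    if sp.issparse(A):
        A = A.toarray()
    d, r = W.shape
    row_tot = [sum(W[i, p] for p in range(r)) for i in range(d)]
    first = 0.0
    second = 0.0
    for i in range(d):
        for j in range(d):
            first += row_tot[i] * row_tot[j] * A[i, j]
            for p in range(r):
                second += W[i, p] * W[j, p] * (-A[i, j])
    return first + second


def dual_regularizer(
    W: np.ndarray,
    class_laps: Sequence[GraphLaplacian],
    M: FeatureGraph | np.ndarray,
    lambda1: float,
    lambda2: float,
) -> float:
    """(lambda1 / r) * local + (lambda2 / (r (r-1))) * global.

    With a single class the global term is identically zero (no cross-class
    pairs), so its divisor is never applied.
    """
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("regularization weights must be non-negative")
    W = np.asarray(W, dtype=float)
    r = W.shape[1]
    value = (lambda1 / r) * omega_local(W, class_laps)
    if r > 1:
        value += (lambda2 / (r * (r - 1))) * omega_global(W, M)
    return float(value)
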