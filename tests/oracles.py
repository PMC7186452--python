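"""Independent dense reference implementations used only by the tests.

Everything here is written as literal triple loops over a dense
n x n x L array so it shares no code path with the sparse package
implementation it is used to check.
"""

from typing import Tuple

import numpy as np

from mon.network import MultiplexNetwork


def dense_tensor(net: MultiplexNetwork) -> np.ndarray:
    """Dense (n, n, L) array of layer weights."""
    n, L = net.n, net.L
    idx = net.universe.index
    A = np.zeros((n, n, L))
    for k, layer in enumerate(net.layers):
        for (a, b), w in layer.weights.items():
            A[idx[a], idx[b], k] = w
            A[idx[b], idx[a], k] = w
    return A


def dense_transition_tensors(A: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    n, _, L = A.shape
    T1 = np.zeros_like(A)
    for j in range(n):
        for k in range(L):
            s = sum(A[i, j, k] for i in range(n))
            for i in range(n):
                T1[i, j, k] = A[i, j, k] / s if s > 0 else 1.0 / n
    T2 = np.zeros_like(A)
    for i in range(n):
        for j in range(n):
            s = sum(A[i, j, k] for k in range(L))
            for k in range(L):
                T2[i, j, k] = A[i, j, k] / s if s > 0 else 1.0 / L
    return T1, T2


def dense_walk_step(T1: np.ndarray, T2: np.ndarray, x: np.ndarray,
                    y: np.ndarray, rv: np.ndarray, alpha: float
                    ) -> Tuple[np.ndarray, np.ndarray]:
    n, _, L = T1.shape
    new_x = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            for k in range(L):
                acc += T1[i, j, k] * x[j] * y[k]
        new_x[i] = alpha * acc + (1.0 - alpha) * rv[i]
    new_x = new_x / new_x.sum()  # analytic no-op; stops rounding feedback
    new_y = np.zeros(L)
    for k in range(L):
        acc = 0.0
        for i in range(n):
            for j in range(n):
                acc += T2[i, j, k] * new_x[i] * new_x[j]
        new_y[k] = acc
    return new_x, new_y


def dense_run(A: np.ndarray, rv: np.ndarray, alpha: float,
              threshold: float = 1e-9, max_iter: int = 1000
              ) -> Tuple[np.ndarray, np.ndarray]:
    n, _, L = A.shape
    T1, T2 = dense_transition_tensors(A)
    x = np.full(n, 1.0 / n)
    y = np.full(L, 1.0 / L)
    for _ in range(max_iter):
        nx, ny = dense_walk_step(T1, T2, x, y, rv, alpha)
        if np.abs(nx - x).sum() + np.abs(ny - y).sum() < threshold:
            return nx, ny
        x, y = nx, ny
    return x, y


def classical_rwr(P: np.ndarray, rv: np.ndarray, alpha: float,
                  threshold: float = 1e-12, max_iter: int = 10000) -> np.ndarray:
    """Plain power iteration x = alpha P x + (1 - alpha) rv on a
    column-stochastic matrix."""
    n = len(rv)
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        nx = alpha * (P @ x) + (1.0 - alpha) * rv
        if np.abs(nx - x).sum() < threshold:
            return nx
        x = nx
    return x


def column_stochastic(A: np.ndarray) -> np.ndarray:
    """Column-normalize with uniform columns where the sum is zero."""
    n = A.shape[0]
    P = np.zeros_like(A, dtype=float)
    for j in range(n):
        s = A[:, j].sum()
        P[:, j] = A[:, j] / s if s > 0 else 1.0 / n
    return P
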