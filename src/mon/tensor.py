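"""Third-order tensor representation and the coupled random walk with restart.

The multiplex network is viewed as a sparse n x n x L tensor of layer
weights. Two fiber-normalized transition tensors drive a coupled
iteration: a node-score vector ``x`` diffuses through layers weighted by
a layer-importance vector ``y``, which is in turn re-estimated from the
mass that node pairs carry in each layer.

The "uniform fallback" fibers (a node with no edges in a layer; a node
pair adjacent in no layer) make the transition tensors logically dense.
They are never materialized: their contribution is a rank-one correction
computed in closed form, so memory stays proportional to the edge count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy import sparse

from mon.network import MultiplexNetwork

_MASS_TOL = 1e-9


@dataclass(frozen=True)
class AdjacencyTensor:
    """Sparse n x n x L tensor stacking symmetric layer matrices.

    ``layers[k]`` is the CSR adjacency of layer k; entry (i, j, k) is
    ``layers[k][i, j]``. No diagonal entries; values in (0, 1].
    """

    n: int
    L: int
    layers: Tuple[sparse.csr_matrix, ...]

    def entry(self, i: int, j: int, k: int) -> float:
        return float(self.layers[k][i, j])

    @property
    def nnz(self) -> int:
        return sum(int(m.nnz) for m in self.layers)


@dataclass(frozen=True)
class TransitionTensorPair:
    """The two fiber-normalized transition tensors in factored form.

    T1 (node transitions, per layer): entry (i, j, k) is
    ``adj[k][i, j] / col_sums[k][j]`` when column j of layer k has mass,
    and 1/n otherwise (``dangling[k][j]`` flags those columns).

    T2 (layer selection, per node pair): entry (i, j, k) is
    ``norm_layers[k][i, j]`` — the layer weight divided by the pair's
    total weight across layers — when the pair is adjacent somewhere
    (``pattern[i, j] == 1``), and 1/L otherwise. Fallback fibers are
    implicit; only flags are stored.
    """

    n: int
    L: int
    adj: Tuple[sparse.csr_matrix, ...]
    col_sums: np.ndarray  # (L, n)
    dangling: np.ndarray  # (L, n) bool
    norm_layers: Tuple[sparse.csr_matrix, ...]
    pattern: sparse.csr_matrix  # indicator of pairs adjacent in >= 1 layer

    def t1(self, i: int, j: int, k: int) -> float:
        if self.dangling[k, j]:
            return 1.0 / self.n
        return float(self.adj[k][i, j]) / float(self.col_sums[k, j])

    def t2(self, i: int, j: int, k: int) -> float:
        if self.pattern[i, j] == 0:
            return 1.0 / self.L
        return float(self.norm_layers[k][i, j])


@dataclass(frozen=True)
class WalkState:
    """Node scores ``x`` (sum 1) and layer scores ``y`` (sum 1)."""

    x: np.ndarray
    y: np.ndarray
    iteration: int = 0

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if (x < 0).any() or (y < 0).any():
            raise ValueError("walk state must be nonnegative")
        if abs(x.sum() - 1.0) > _MASS_TOL or abs(y.sum() - 1.0) > _MASS_TOL:
            raise ValueError("walk state vectors must each sum to 1")


@dataclass(frozen=True)
class WalkResult:
    """Converged (or truncated) walk outcome with a residual trace."""

    state: WalkState
    converged: bool
    residual_trace: Tuple[float, ...] = field(default=())

    @property
    def iterations(self) -> int:
        return len(self.residual_trace)


def build_adjacency_tensor(net: MultiplexNetwork) -> AdjacencyTensor:
    """Stack the layer weights into symmetric sparse matrices."""
    n = net.n
    idx = net.universe.index
    mats: List[sparse.csr_matrix] = []
    for layer in net.layers:
        rows, cols, data = [], [], []
        for (a, b), w in layer.weights.items():
            ia, ib = idx[a], idx[b]
            rows += [ia, ib]
            cols += [ib, ia]
            data += [w, w]
        m = sparse.csr_matrix(
            (np.asarray(data, dtype=float), (rows, cols)), shape=(n, n)
        )
        mats.append(m)
    return AdjacencyTensor(n=n, L=net.L, layers=tuple(mats))


def build_transition_tensors(T: AdjacencyTensor) -> TransitionTensorPair:
    """Normalize the tensor along its two fiber directions.

    T1 divides each (j, k) column by its node-sum; columns with zero sum
    are flagged for the uniform 1/n fallback. T2 divides each (i, j)
    fiber by its layer-sum; pairs adjacent in no layer get 1/L.
    """
    n, L = T.n, T.L
    col_sums = np.zeros((L, n))
    for k, m in enumerate(T.layers):
        col_sums[k] = np.asarray(m.sum(axis=0)).ravel()
    dangling = col_sums == 0.0

    total = sum((m for m in T.layers), sparse.csr_matrix((n, n)))
    total = total.tocsr()
    pattern = total.copy()
    pattern.data = np.ones_like(pattern.data)

    norm_layers: List[sparse.csr_matrix] = []
    for m in T.layers:
        if m.nnz == 0:
            norm_layers.append(sparse.csr_matrix((n, n)))
            continue
        mc = m.tocoo()
        denom = np.asarray(total[mc.row, mc.col]).ravel()
        nm = sparse.csr_matrix(
            (mc.data / denom, (mc.row, mc.col)), shape=(n, n)
        )
        norm_layers.append(nm)

    return TransitionTensorPair(
        n=n,
        L=L,
        adj=tuple(T.layers),
        col_sums=col_sums,
        dangling=dangling,
        norm_layers=tuple(norm_layers),
        pattern=pattern,
    )


def _check_restart_vector(rv: np.ndarray, n: int) -> np.ndarray:
    rv = np.asarray(rv, dtype=float)
    if rv.shape != (n,):
        raise ValueError(f"restart vector must have length {n}")
    if (rv < 0).any() or abs(rv.sum() - 1.0) > _MASS_TOL:
        raise ValueError("restart vector must be a probability vector")
    return rv


def walk_step(
    state: WalkState,
    tt: TransitionTensorPair,
    rv: np.ndarray,
    alpha: float,
) -> WalkState:
    """One coupled update: diffuse x through T1, then re-score layers.

    new_x[i] = alpha * sum_jk T1[i,j,k] x[j] y[k] + (1 - alpha) rv[i];
    new_y[k] = sum_ij T2[i,j,k] new_x[i] new_x[j]   (uses the NEW x).

    Fallback fibers contribute in closed form: dangling columns of a
    layer spread their mass uniformly (1/n), and pairs adjacent in no
    layer select layers uniformly, with total pair mass
    (sum x)^2 - sum_adjacent x_i x_j.
    """
    rv = _check_restart_vector(rv, tt.n)
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    x, y = state.x, state.y

    new_x = np.zeros(tt.n)
    for k in range(tt.L):
        cs = tt.col_sums[k]
        live = ~tt.dangling[k]
        xn = np.where(live, x, 0.0) / np.where(live, cs, 1.0)
        diffused = tt.adj[k] @ xn
        dangling_mass = float(x[tt.dangling[k]].sum())
        new_x += y[k] * (diffused + dangling_mass / tt.n)
    new_x = alpha * new_x + (1.0 - alpha) * rv
    # exact identity (the sum is 1 analytically); without it, rounding in
    # the x-sum feeds back through sum(y) = sum(x)^2 and compounds
    # geometrically for alpha > 1/3
    new_x /= new_x.sum()

    adjacent_mass = float(new_x @ (tt.pattern @ new_x))
    fallback_mass = float(new_x.sum()) ** 2 - adjacent_mass
    new_y = np.empty(tt.L)
    for k in range(tt.L):
        new_y[k] = float(new_x @ (tt.norm_layers[k] @ new_x)) + fallback_mass / tt.L

    return WalkState(x=new_x, y=new_y, iteration=state.iteration + 1)


def run_rwr(
    net: MultiplexNetwork,
    rv: np.ndarray,
    alpha: float = 0.3,
    threshold: float = 1e-9,
    max_iter: int = 1000,
) -> WalkResult:
    """Iterate the coupled walk from uniform x, y to the L1 fixed point.

    Stops when ``||dx||_1 + ||dy||_1 < threshold``; non-convergence
    within ``max_iter`` is reported via the flag, not raised, since a
    truncated ranking is still usable downstream.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    T = build_adjacency_tensor(net)
    tt = build_transition_tensors(T)
    rv = _check_restart_vector(rv, net.n)

    state = WalkState(
        x=np.full(net.n, 1.0 / net.n), y=np.full(net.L, 1.0 / net.L)
    )
    trace: List[float] = []
    converged = False
    for _ in range(max_iter):
        nxt = walk_step(state, tt, rv, alpha)
        residual = float(
            np.abs(nxt.x - state.x).sum() + np.abs(nxt.y - state.y).sum()
        )
        trace.append(residual)
        state = nxt
        if residual < threshold:
            converged = True
            break
    return WalkResult(state=state, converged=converged, residual_trace=tuple(trace))
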