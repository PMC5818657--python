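"""Multiresolution modularity and the iterated Louvain optimizer.

The quality function is

    Q(g, gamma) = sum_{i,j} (A_ij - gamma * P_ij) * delta(g_i, g_j),

a double sum over ordered node pairs including ``i = j`` (the diagonal adds a
partition-independent constant when self-loops are absent, so optimization is
unaffected).  ``P`` is either the configuration null ``P_ij = k_i k_j / 2m``
— kept in its rank-one form and never materialized during optimization — or
an externally supplied null matrix, as used for consensus matrices.

The optimizer is a Louvain-style two-phase algorithm with *weighted random
moves*: during phase 1 single nodes move between communities, sampling among
the strictly improving moves with probability proportional to the resulting
modularity increase; phase 2 aggregates communities into supernodes.  The
whole algorithm is restarted from its own output until the quality stops
increasing ("iterated" variant).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from ._kernels import sweep_dense, sweep_sparse_config
from .network import Network, Partition

__all__ = [
    "QualityModel",
    "configuration_null",
    "modularity",
    "louvain",
    "iterated_louvain",
]

#: a move/restart counts as improving only if dQ exceeds this times the
#: total interaction weight (the paper's algorithm gives no tolerance)
REL_TOL = 1e-10

_MAX_SWEEPS = 1000
_DENSE_AGG_LIMIT = 4096  # aggregated levels above this size stay sparse


class QualityModel:
    """Adjacency + null-model pair defining a modularity quality function."""

    def __init__(self, adjacency, null, gamma: float = 1.0):
        self.gamma = float(gamma)
        if self.gamma < 0:
            raise ValueError("resolution gamma must be >= 0")
        if isinstance(null, tuple) and null[0] == "configuration":
            self.adjacency = sp.csr_matrix(adjacency, dtype=np.float64)
            _, self.degrees, self.twom = null
            self.kind = "configuration"
        else:
            self.adjacency = np.asarray(adjacency, dtype=np.float64)
            self.null_matrix = np.asarray(null, dtype=np.float64)
            if self.null_matrix.shape != self.adjacency.shape:
                raise ValueError("null matrix shape must match adjacency")
            if not np.allclose(self.null_matrix, self.null_matrix.T, atol=1e-12):
                raise ValueError("null matrix must be symmetric")
            if self.null_matrix.min() < 0:
                raise ValueError("null matrix entries must be >= 0")
            self.kind = "dense"
        self._interaction = None

    @classmethod
    def configuration(cls, network: Network, gamma: float = 1.0) -> "QualityModel":
        """Configuration-null model ``P_ij = k_i k_j / 2m`` on a network."""
        if network.total <= 0:
            raise ValueError("empty network: configuration null undefined (2m = 0)")
        return cls(
            network.adjacency,
            ("configuration", network.degrees, network.total),
            gamma=gamma,
        )

    @classmethod
    def from_matrices(cls, adjacency, null, gamma: float = 1.0) -> "QualityModel":
        """Quality model from explicit adjacency and null matrices."""
        return cls(adjacency, null, gamma=gamma)

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def scale(self) -> float:
        """Total interaction weight used for relative improvement tolerances."""
        if self.kind == "configuration":
            return float(self.twom)
        return float(np.abs(self.adjacency).sum())

    def interaction_matrix(self) -> np.ndarray:
        """Dense ``A - gamma*P`` with zeroed diagonal (optimizer's view)."""
        if self._interaction is None:
            if self.kind == "configuration":
                a = self.adjacency.toarray()
                b = a - self.gamma * np.outer(self.degrees, self.degrees) / self.twom
            else:
                b = self.adjacency - self.gamma * self.null_matrix
            np.fill_diagonal(b, 0.0)
            self._interaction = np.ascontiguousarray(b)
        return self._interaction

    def modularity(self, partition: Partition) -> float:
        """Evaluate Q(g, gamma) as the full ordered double sum incl. i = j."""
        if partition.n != self.n:
            raise ValueError("partition length does not match model size")
        lab = partition.labels - 1
        k = partition.n_clusters
        onehot = sp.csr_matrix(
            (np.ones(self.n), (np.arange(self.n), lab)), shape=(self.n, k)
        )
        if self.kind == "configuration":
            a_in = float((onehot.T @ self.adjacency @ onehot).diagonal().sum())
            kc = np.bincount(lab, weights=self.degrees, minlength=k)
            return a_in - self.gamma * float((kc**2).sum() / self.twom)
        grouped = onehot.T @ (self.adjacency - self.gamma * self.null_matrix) @ onehot
        return float(grouped.diagonal().sum())


def configuration_null(network: Network) -> np.ndarray:
    """Dense configuration null matrix ``P_ij = k_i k_j / 2m`` (Newman null)."""
    if network.total <= 0:
        raise ValueError("empty network: configuration null undefined (2m = 0)")
    k = network.degrees
    return np.outer(k, k) / network.total


def modularity(model: QualityModel, partition: Partition) -> float:
    """Multiresolution modularity of a partition under a quality model."""
    return model.modularity(partition)


def _aggregate(matrix, labels: np.ndarray, degrees=None):
    """Sum rows/columns of ``matrix`` by community label (0-based, compact)."""
    n = labels.size
    k = int(labels.max()) + 1
    onehot = sp.csr_matrix((np.ones(n), (np.arange(n), labels)), shape=(n, k))
    agg = onehot.T @ matrix @ onehot
    if degrees is not None:
        return agg, np.bincount(labels, weights=degrees, minlength=k)
    return agg


def _compact(labels: np.ndarray) -> np.ndarray:
    _, compact = np.unique(labels, return_inverse=True)
    return compact.astype(np.int64)


def louvain(
    model: QualityModel,
    seed: int,
    initial: Partition | None = None,
) -> Partition:
    """One pass of the weighted-random-move Louvain algorithm.

    Returns a partition that is a local optimum under single-node moves and
    community aggregation.  On a model where no move improves (e.g., all
    interactions antiferromagnetic) the all-singletons partition (or the
    ``initial`` partition, if given) is returned unchanged.
    """
    rng = np.random.default_rng(seed)
    n = model.n
    tol = REL_TOL * model.scale

    level_sparse = model.kind == "configuration"
    if level_sparse:
        adj = model.adjacency.tocsr()
        degrees = model.degrees.astype(np.float64)
        twom = float(model.twom)
        b = None
    else:
        b = model.interaction_matrix().copy()

    mapping = np.arange(n, dtype=np.int64)  # original node -> current supernode
    if initial is not None:
        if initial.n != n:
            raise ValueError("initial partition length does not match model")
        level_init = _compact(initial.labels.astype(np.int64) - 1)
    else:
        level_init = np.arange(n, dtype=np.int64)

    first = True
    while True:
        labels = level_init.copy()
        kernel_seed = int(rng.integers(0, 2**31 - 1))
        if level_sparse:
            moves = sweep_sparse_config(
                adj.indptr,
                adj.indices,
                adj.data.astype(np.float64),
                degrees,
                twom,
                model.gamma,
                labels,
                kernel_seed,
                tol,
                _MAX_SWEEPS,
            )
        else:
            moves = sweep_dense(b, labels, kernel_seed, tol, _MAX_SWEEPS)
        labels = _compact(labels)
        mapping = labels[mapping]
        k = int(labels.max()) + 1
        if moves == 0 and not first:
            break
        if k == labels.size:
            # no aggregation possible; phase 1 is the fixed point
            break
        # phase 2: aggregate communities into supernodes
        if level_sparse:
            adj, degrees = _aggregate(adj, labels, degrees)
            adj = sp.csr_matrix(adj)
            if k <= _DENSE_AGG_LIMIT:
                b = adj.toarray() - model.gamma * np.outer(degrees, degrees) / twom
                np.fill_diagonal(b, 0.0)
                b = np.ascontiguousarray(b)
                level_sparse = False
        else:
            tmp = np.zeros((k, labels.size))
            np.add.at(tmp, labels, b)
            agg = np.zeros((k, k))
            np.add.at(agg, labels, tmp.T)
            b = np.ascontiguousarray(agg.T)
            np.fill_diagonal(b, 0.0)
        level_init = np.arange(k, dtype=np.int64)
        first = False
    return Partition(mapping + 1)


def iterated_louvain(
    model: QualityModel,
    seed: int,
    max_restarts: int = 100,
    initial: Partition | None = None,
) -> Partition:
    """Louvain restarted from its own output until Q stops increasing."""
    if max_restarts < 1:
        raise ValueError("max_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    tol = REL_TOL * model.scale
    best = louvain(model, int(rng.integers(0, 2**31 - 1)), initial=initial)
    best_q = model.modularity(best)
    for _ in range(max_restarts - 1):
        nxt = louvain(model, int(rng.integers(0, 2**31 - 1)), initial=best)
        q = model.modularity(nxt)
        if q > best_q + tol:
            best, best_q = nxt, q
        else:
            break
    return best
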