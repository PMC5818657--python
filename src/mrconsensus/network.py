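"""Graph and partition data model, file I/O, and deterministic fixture networks.

A :class:`Network` is an undirected, weighted graph stored as a symmetric
sparse adjacency matrix together with node strengths ``k_i = sum_j A_ij`` and
the total weight ``2m = sum_i k_i`` — the quantities entering the modularity
quality function.  Nodes carry arbitrary string labels externally and dense
0-based integer indices internally.

A :class:`Partition` is a cluster-assignment vector over ``n`` nodes with
integer labels canonicalized to ``1..#clusters`` in order of first appearance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "Network",
    "Partition",
    "PartitionEnsemble",
    "read_edge_list",
    "read_gml",
    "read_partition",
    "write_partition",
    "read_ensemble",
    "write_ensemble",
    "make_fixture",
]

_SYMMETRY_TOL = 1e-12


def canonicalize_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters to contiguous 1-based labels in first-appearance order.

    Idempotent and invariant under any bijective relabeling of the input.
    """
    labels = np.asarray(labels)
    _, first_idx, inverse = np.unique(labels, return_index=True, return_inverse=True)
    # np.unique sorts by value; reorder so that label 1 is the cluster of the
    # first node, label 2 the next new cluster encountered, and so on.
    order = np.argsort(first_idx, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    return (rank[inverse] + 1).astype(np.int64)


@dataclass(frozen=True)
class Partition:
    """Cluster assignment vector ``g`` with canonical labels ``1..n_clusters``."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        canon = canonicalize_labels(self.labels)
        object.__setattr__(self, "labels", canon)
        self.labels.setflags(write=False)

    @property
    def n(self) -> int:
        return int(self.labels.size)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) if self.labels.size else 0

    @property
    def cluster_sizes(self) -> np.ndarray:
        """Array of cluster sizes ``#[g=c]`` for ``c = 1..n_clusters``."""
        return np.bincount(self.labels, minlength=self.n_clusters + 1)[1:]

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)

    def clusters(self) -> list[np.ndarray]:
        return [self.members(c) for c in range(1, self.n_clusters + 1)]

    def restrict(self, nodes: np.ndarray) -> "Partition":
        """Induced partition on a subset of node indices (re-canonicalized)."""
        return Partition(self.labels[np.asarray(nodes)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return np.array_equal(self.labels, other.labels)

    def __hash__(self) -> int:
        return hash(self.labels.tobytes())


@dataclass
class PartitionEnsemble:
    """Ordered collection of partitions over a shared node set."""

    partitions: list[Partition]
    gamma_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.partitions:
            raise ValueError("ensemble must contain at least one partition")
        n = self.partitions[0].n
        if any(p.n != n for p in self.partitions):
            raise ValueError("all partitions in an ensemble must have the same length")
        if self.gamma_values is not None:
            self.gamma_values = np.asarray(self.gamma_values, dtype=float)
            if self.gamma_values.size != len(self.partitions):
                raise ValueError("gamma_values length must match ensemble size")

    @property
    def size(self) -> int:
        return len(self.partitions)

    @property
    def n(self) -> int:
        return self.partitions[0].n

    def labels_matrix(self) -> np.ndarray:
        """(size, n) matrix of 1-based labels, one row per partition."""
        return np.vstack([p.labels for p in self.partitions])

    def restrict(self, nodes: np.ndarray) -> "PartitionEnsemble":
        """Ensemble induced on a node subset; labels re-canonicalized."""
        return PartitionEnsemble(
            [p.restrict(nodes) for p in self.partitions], gamma_values=self.gamma_values
        )

    def __iter__(self):
        return iter(self.partitions)

    def __len__(self) -> int:
        return len(self.partitions)


class Network:
    """Undirected weighted network with symmetric nonnegative adjacency."""

    def __init__(self, node_ids: Sequence[str], adjacency) -> None:
        adjacency = sp.csr_matrix(adjacency, dtype=np.float64)
        n = adjacency.shape[0]
        if adjacency.shape != (n, n):
            raise ValueError("adjacency must be square")
        if len(node_ids) != n:
            raise ValueError("node_ids length must match adjacency size")
        asym = abs(adjacency - adjacency.T)
        if asym.nnz and asym.max() > _SYMMETRY_TOL:
            raise ValueError("adjacency must be symmetric (tolerance 1e-12)")
        if adjacency.nnz and adjacency.data.min() < 0:
            raise ValueError("adjacency weights must be nonnegative")
        self.node_ids: list[str] = [str(v) for v in node_ids]
        self.adjacency: sp.csr_matrix = adjacency
        self.degrees: np.ndarray = np.asarray(adjacency.sum(axis=1)).ravel()
        self.total: float = float(self.degrees.sum())  # 2m

    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        a = sp.triu(self.adjacency)
        return int(a.nnz)

    def dense(self) -> np.ndarray:
        return self.adjacency.toarray()

    def index_of(self, node_id: str) -> int:
        try:
            return self.node_ids.index(str(node_id))
        except ValueError as exc:
            raise KeyError(f"unknown node {node_id!r}") from exc

    def subnetwork(self, nodes: np.ndarray) -> "Network":
        nodes = np.asarray(nodes)
        sub = self.adjacency[nodes][:, nodes]
        return Network([self.node_ids[i] for i in nodes], sub)


def _build_network(
    sources: list[str], targets: list[str], weights: list[float], directed_policy: str
) -> Network:
    order: dict[str, int] = {}
    for name in itertools.chain.from_iterable(zip(sources, targets)):
        if name not in order:
            order[name] = len(order)
    n = len(order)
    rows = np.fromiter((order[s] for s in sources), dtype=np.int64, count=len(sources))
    cols = np.fromiter((order[t] for t in targets), dtype=np.int64, count=len(targets))
    w = np.asarray(weights, dtype=np.float64)
    if directed_policy not in ("reject", "symmetrize_mean", "symmetrize_max"):
        raise ValueError(f"unknown directed_policy {directed_policy!r}")
    directed = sp.coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    directed.sum_duplicates()
    node_ids = list(order)
    # An edge listed in one direction is an ordinary undirected edge; the
    # directed policy only concerns pairs listed in BOTH directions.
    fwd = directed.copy()
    fwd.data = np.ones_like(fwd.data)
    both = fwd.multiply(fwd.T).astype(bool)
    asym = (directed - directed.T).multiply(both)
    if abs(asym).nnz and abs(asym).max() > _SYMMETRY_TOL:
        if directed_policy == "reject":
            i, j = np.unravel_index(np.argmax(abs(asym).toarray()), (n, n))
            raise ValueError(
                "directed input under policy 'reject': first asymmetric pair "
                f"({node_ids[i]!r}, {node_ids[j]!r})"
            )
        if directed_policy == "symmetrize_mean":
            adjacency = directed.maximum(directed.T) - abs(asym) * 0.5
        else:  # symmetrize_max
            adjacency = directed.maximum(directed.T)
    else:
        adjacency = directed.maximum(directed.T)
    return Network(node_ids, adjacency)


def read_edge_list(path, directed_policy: str = "symmetrize_mean") -> Network:
    """Read a whitespace/tab-delimited edge list (source, target[, weight]).

    A missing weight column defaults to weight 1; duplicate edges (same
    direction) are summed; asymmetric input is handled per ``directed_policy``
    (``reject``, ``symmetrize_mean`` or ``symmetrize_max``).
    """
    df = pd.read_csv(
        path, sep=r"\s+", header=None, comment="#", dtype=str, skip_blank_lines=True
    )
    if df.shape[1] < 2:
        raise ValueError(f"{path}: edge list needs at least 2 columns")
    sources = df.iloc[:, 0].astype(str).tolist()
    targets = df.iloc[:, 1].astype(str).tolist()
    if df.shape[1] >= 3:
        weights = df.iloc[:, 2].astype(float).to_numpy()
    else:
        weights = np.ones(len(sources))
    neg = np.flatnonzero(weights < 0)
    if neg.size:
        raise ValueError(f"{path}: negative weight on line {neg[0] + 1}")
    return _build_network(sources, targets, list(weights), directed_policy)


def read_gml(path, directed_policy: str = "symmetrize_mean") -> Network:
    """Read a GML file (node ``id``/``label``, edge ``source/target/weight``)."""
    import networkx as nx

    g = nx.read_gml(path, label="label")
    sources, targets, weights = [], [], []
    for u, v, data in g.edges(data=True):
        sources.append(str(u))
        targets.append(str(v))
        weights.append(float(data.get("weight", 1.0)))
    if min(weights, default=0.0) < 0:
        raise ValueError(f"{path}: negative edge weight in GML input")
    policy = "reject" if not g.is_directed() else directed_policy
    return _build_network(sources, targets, weights, policy)


def write_partition(partition: Partition, node_ids: Sequence[str], path) -> None:
    """Write a two-column TSV (node, canonical cluster label)."""
    if partition.n != len(node_ids):
        raise ValueError("partition length does not match node_ids")
    with open(path, "w") as fh:
        for name, lab in zip(node_ids, partition.labels):
            fh.write(f"{name}\t{lab}\n")


def read_partition(path, node_ids: Sequence[str] | None = None) -> Partition:
    """Read a two-column TSV partition; rows reordered to ``node_ids`` if given."""
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype={0: str})
    names = df.iloc[:, 0].astype(str).tolist()
    labels = df.iloc[:, 1].astype(np.int64).to_numpy()
    if node_ids is not None:
        index = {name: i for i, name in enumerate(names)}
        labels = labels[[index[str(v)] for v in node_ids]]
    return Partition(labels)


def write_ensemble(
    ensemble: PartitionEnsemble, node_ids: Sequence[str], path
) -> None:
    """Write an ensemble as TSV: one row per node, one column per partition."""
    if ensemble.n != len(node_ids):
        raise ValueError("ensemble length does not match node_ids")
    labels = ensemble.labels_matrix().T  # (n, T)
    with open(path, "w") as fh:
        for name, row in zip(node_ids, labels):
            fh.write(str(name) + "\t" + "\t".join(str(v) for v in row) + "\n")


def read_ensemble(path, node_ids: Sequence[str] | None = None) -> PartitionEnsemble:
    """Read an ensemble TSV written by :func:`write_ensemble`."""
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype={0: str})
    names = df.iloc[:, 0].astype(str).tolist()
    labels = df.iloc[:, 1:].to_numpy(dtype=np.int64)
    if node_ids is not None:
        index = {name: i for i, name in enumerate(names)}
        labels = labels[[index[str(v)] for v in node_ids]]
    return PartitionEnsemble([Partition(labels[:, t]) for t in range(labels.shape[1])])


def _ring(n: int) -> Network:
    if n < 3:
        raise ValueError("ring fixture requires n >= 3")
    i = np.arange(n)
    rows = np.concatenate([i, (i + 1) % n])
    cols = np.concatenate([(i + 1) % n, i])
    adj = sp.coo_matrix((np.ones(2 * n), (rows, cols)), shape=(n, n))
    return Network([str(v) for v in range(n)], adj)


def _cliques(s: int, c: int, bridges: int = 0) -> tuple[Network, Partition]:
    if s < 2 or c < 1:
        raise ValueError("cliques fixture requires clique size >= 2 and count >= 1")
    if bridges < 0 or bridges > s:
        raise ValueError("bridges must be between 0 and the clique size")
    n = s * c
    r, cl = [], []
    for q in range(c):
        base = q * s
        for i in range(s):
            for j in range(i + 1, s):
                r.append(base + i)
                cl.append(base + j)
    for q in range(c - 1):
        for b in range(bridges):
            r.append(q * s + b)
            cl.append((q + 1) * s + b)
    r, cl = np.array(r), np.array(cl)
    adj = sp.coo_matrix(
        (np.ones(2 * r.size), (np.concatenate([r, cl]), np.concatenate([cl, r]))),
        shape=(n, n),
    )
    planted = Partition(np.repeat(np.arange(1, c + 1), s))
    return Network([str(v) for v in range(n)], adj), planted


def _er(n: int, p: float, seed: int) -> Network:
    if n < 2 or not (0 <= p <= 1):
        raise ValueError("er fixture requires n >= 2 and p in [0, 1]")
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.size) < p
    r, cl = iu[mask], ju[mask]
    adj = sp.coo_matrix(
        (np.ones(2 * r.size), (np.concatenate([r, cl]), np.concatenate([cl, r]))),
        shape=(n, n),
    )
    return Network([str(v) for v in range(n)], adj)


def make_fixture(name: str, **params):
    """Deterministic fixture networks: ``ring``, ``cliques`` or ``er``.

    ``cliques`` returns ``(Network, planted Partition)``; the others return a
    ``Network``.
    """
    if name == "ring":
        return _ring(int(params["n"]))
    if name == "cliques":
        return _cliques(
            int(params["s"]), int(params["c"]), int(params.get("bridges", 0))
        )
    if name == "er":
        return _er(int(params["n"]), float(params["p"]), int(params["seed"]))
    raise ValueError(f"unknown fixture {name!r}")
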