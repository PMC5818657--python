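"""Recursive hierarchical consensus trees, dendrogram cuts, and tree I/O.

The hierarchical consensus (HC) procedure starts from the all-nodes cluster
and applies significance-based consensus clustering to the ensemble induced
on each cluster's nodes (labels re-canonicalized and null probabilities
recomputed with n = cluster size), recursing into every newly created
cluster until no cluster has statistically significant sub-structure.

Each tree vertex carries the cluster strength <C>: the mean of the ORIGINAL
ensemble's co-classification matrix over the cluster's distinct node pairs
(diagonal excluded; singletons have strength 1 by convention).  Cuts of the
dendrogram at a strength threshold turn the tree into flat partitions:
a split is performed iff it was created at strength above the threshold,
with the root's split always performed, so threshold 1 yields the coarsest
partition below the root and threshold 0 the leaf partition.  The strength
at which a split was created is the minimum of its children's strengths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .consensus import NullModelSpec, _consensus_loop, coclassification
from .network import Partition, PartitionEnsemble

__all__ = [
    "TreeVertex",
    "ConsensusTree",
    "hierarchical_consensus",
    "cut_tree",
    "all_cuts",
    "write_tree",
    "read_tree",
]


@dataclass
class TreeVertex:
    """A cluster in the consensus hierarchy."""

    members: np.ndarray
    strength: float
    children: list["TreeVertex"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def size(self) -> int:
        return int(self.members.size)

    @property
    def split_strength(self) -> float:
        """Strength at which this vertex's split was created (min child <C>)."""
        if self.is_leaf:
            raise ValueError("leaf vertices have no split")
        return min(c.strength for c in self.children)


@dataclass
class ConsensusTree:
    """Rooted cluster tree over ``n`` nodes with per-vertex <C> strengths."""

    root: TreeVertex
    node_ids: list[str]

    @property
    def n(self) -> int:
        return len(self.node_ids)

    def vertices(self):
        """Preorder iteration over all vertices."""
        stack = [self.root]
        while stack:
            v = stack.pop()
            yield v
            stack.extend(reversed(v.children))

    def leaves(self) -> list[TreeVertex]:
        return [v for v in self.vertices() if v.is_leaf]

    def leaf_partition(self) -> Partition:
        labels = np.empty(self.n, dtype=np.int64)
        for c, leaf in enumerate(self.leaves(), start=1):
            labels[leaf.members] = c
        return Partition(labels)

    def validate(self) -> None:
        """Check the partition-of-members tree invariants."""
        for v in self.vertices():
            if not (0.0 <= v.strength <= 1.0):
                raise AssertionError("vertex strength outside [0, 1]")
            if v.children:
                merged = np.sort(np.concatenate([c.members for c in v.children]))
                if not np.array_equal(merged, np.sort(v.members)):
                    raise AssertionError("children do not partition their parent")
        seen = np.sort(np.concatenate([l.members for l in self.leaves()]))
        if not np.array_equal(seen, np.arange(self.n)):
            raise AssertionError("leaves do not partition the node set")


def _mean_coclassification(c: np.ndarray, members: np.ndarray) -> float:
    """Mean off-diagonal co-classification over a cluster's pairs (<C>)."""
    m = members.size
    if m < 2:
        return 1.0
    sub = c[np.ix_(members, members)]
    return float((sub.sum() - np.trace(sub)) / (m * (m - 1)))


def _child_seed(parent_seed: int, index: int) -> int:
    return int(np.random.default_rng([parent_seed, index]).integers(0, 2**31 - 1))


def hierarchical_consensus(
    ensemble: PartitionEnsemble,
    spec: NullModelSpec | None = None,
    optimizer=None,
    seed: int = 0,
    max_iter: int = 50,
    node_ids: list[str] | None = None,
    recurse_on: str = "original",
) -> ConsensusTree:
    """Build the hierarchical consensus tree of a partition ensemble.

    ``recurse_on`` selects which ensemble is restricted when descending into
    a cluster: the ``"original"`` input ensemble (default) or the
    ``"working"`` ensemble that the parent's consensus step converged to.
    """
    if ensemble.size < 2:
        raise ValueError("hierarchical consensus needs an ensemble of size >= 2")
    if recurse_on not in ("original", "working"):
        raise ValueError("recurse_on must be 'original' or 'working'")
    spec = spec or NullModelSpec()
    c_orig = coclassification(ensemble).C
    n = ensemble.n

    def build(
        members: np.ndarray, sub: PartitionEnsemble, vertex_seed: int
    ) -> TreeVertex:
        """``sub`` is the ensemble already restricted to ``members`` (same order)."""
        vertex = TreeVertex(
            members=members, strength=_mean_coclassification(c_orig, members)
        )
        if members.size < 2:
            return vertex
        part, work = _consensus_loop(sub, spec, optimizer, vertex_seed, max_iter)
        if part.n_clusters <= 1:
            return vertex
        for idx, cluster in enumerate(part.clusters()):
            child_members = members[cluster]
            if recurse_on == "original":
                child_sub = ensemble.restrict(child_members)
            else:
                child_sub = work.restrict(cluster)
            vertex.children.append(
                build(child_members, child_sub, _child_seed(vertex_seed, idx))
            )
        return vertex

    root = build(np.arange(n), ensemble, seed)
    if node_ids is None:
        node_ids = [str(v) for v in range(n)]
    elif len(node_ids) != n:
        raise ValueError("node_ids length does not match ensemble")
    return ConsensusTree(root=root, node_ids=list(node_ids))


def _cut(vertex: TreeVertex, threshold: float, is_root: bool, strict: bool) -> list[np.ndarray]:
    if vertex.is_leaf:
        return [vertex.members]
    s = vertex.split_strength
    perform = is_root or (s > threshold if strict else s >= threshold)
    if not perform:
        return [vertex.members]
    out: list[np.ndarray] = []
    for child in vertex.children:
        out.extend(_cut(child, threshold, False, strict))
    return out


def _clusters_to_partition(clusters: list[np.ndarray], n: int) -> Partition:
    labels = np.empty(n, dtype=np.int64)
    for c, members in enumerate(clusters, start=1):
        labels[members] = c
    return Partition(labels)


def cut_tree(tree: ConsensusTree, threshold: float) -> Partition:
    """Flat partition from the dendrogram at a strength threshold.

    Splits created at strength strictly above ``threshold`` are performed
    (the root's split always is), so cuts are nested: a lower threshold
    refines a higher one.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    return _clusters_to_partition(_cut(tree.root, threshold, True, True), tree.n)


def all_cuts(tree: ConsensusTree) -> list[tuple[float, Partition]]:
    """One cut per distinct split strength, sorted by descending threshold.

    The final entry is always the leaf partition.  Used for best-cut
    evaluation against reference partitions (the HC_max statistic).
    """
    strengths = sorted(
        {v.split_strength for v in tree.vertices() if not v.is_leaf}, reverse=True
    )
    if not strengths:
        return [(1.0, tree.leaf_partition())]
    return [
        (s, _clusters_to_partition(_cut(tree.root, s, True, False), tree.n))
        for s in strengths
    ]


# ---------------------------------------------------------------------------
# serialization


def _vertex_to_json(vertex: TreeVertex, node_ids: list[str]) -> dict:
    return {
        "members": [node_ids[i] for i in vertex.members],
        "strength": vertex.strength,
        "children": [_vertex_to_json(c, node_ids) for c in vertex.children],
    }


def _vertex_from_json(obj: dict, index: dict[str, int]) -> TreeVertex:
    members = np.sort(np.array([index[m] for m in obj["members"]], dtype=np.int64))
    return TreeVertex(
        members=members,
        strength=float(obj["strength"]),
        children=[_vertex_from_json(c, index) for c in obj["children"]],
    )


def _vertex_to_newick(vertex: TreeVertex, node_ids: list[str]) -> str:
    def quote(name: str) -> str:
        if any(ch in name for ch in "()[]{}:;,='\" \t\n"):
            return "'" + name.replace("'", "''") + "'"
        return name

    label = quote(f"C={vertex.strength:.9g}" + ("|leaf" if vertex.is_leaf else ""))
    length = f":{1.0 - vertex.strength:.9g}"
    if vertex.is_leaf:
        inner = ",".join(quote(node_ids[i]) for i in vertex.members)
        if vertex.size == 1:
            return quote(node_ids[vertex.members[0]])
        return f"({inner}){label}{length}"
    inner = ",".join(_vertex_to_newick(c, node_ids) for c in vertex.children)
    return f"({inner}){label}{length}"


def _newick_to_tree(text: str) -> ConsensusTree:
    import dendropy

    dtree = dendropy.Tree.get(data=text, schema="newick", suppress_internal_node_taxa=True)

    names: list[str] = []

    def convert(node) -> TreeVertex:
        if node.is_leaf():
            name = node.taxon.label if node.taxon else node.label
            idx = len(names)
            names.append(str(name))
            return TreeVertex(members=np.array([idx]), strength=1.0)
        label = node.label or ""
        strength = 1.0
        is_leaf_cluster = label.endswith("|leaf")
        if label.startswith("C="):
            strength = float(label[2:].split("|")[0])
        kids = [convert(ch) for ch in node.child_nodes()]
        members = np.sort(np.concatenate([k.members for k in kids]))
        if is_leaf_cluster:
            return TreeVertex(members=members, strength=strength)
        return TreeVertex(members=members, strength=strength, children=kids)

    root = convert(dtree.seed_node)
    return ConsensusTree(root=root, node_ids=names)


def write_tree(tree: ConsensusTree, path, format: str = "json") -> None:
    """Serialize a consensus tree as annotated Newick or JSON."""
    if format == "json":
        with open(path, "w") as fh:
            json.dump(
                {
                    "node_ids": tree.node_ids,
                    "root": _vertex_to_json(tree.root, tree.node_ids),
                },
                fh,
                indent=1,
            )
    elif format == "newick":
        with open(path, "w") as fh:
            fh.write(_vertex_to_newick(tree.root, tree.node_ids) + ";\n")
    else:
        raise ValueError(f"unknown tree format {format!r}")


def read_tree(path, format: str = "json") -> ConsensusTree:
    """Read a tree written by :func:`write_tree` (topology and strengths)."""
    if format == "json":
        with open(path) as fh:
            obj = json.load(fh)
        node_ids = [str(v) for v in obj["node_ids"]]
        index = {v: i for i, v in enumerate(node_ids)}
        return ConsensusTree(root=_vertex_from_json(obj["root"], index), node_ids=node_ids)
    if format == "newick":
        with open(path) as fh:
            return _newick_to_tree(fh.read())
    raise ValueError(f"unknown tree format {format!r}")
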