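"""Two-level hierarchical degree-corrected SBM benchmark generator.

Networks have a planted two-level hierarchy: the single root community is
split into first-level communities, each of which is split again into
second-level communities.  Every split draws its number of children from a
Poisson distribution with mean 4 truncated to a minimum of 2 (resampling
until >= 2, so each community is actually split), child proportions from a
symmetric Dirichlet with concentration 1.5, and assigns nodes to children
multinomially.

Node degrees follow a discrete power law with exponent 2 on [5, 70].  Each
of ``m = round(sum k / 2)`` edges is assigned a category with probabilities
``(p0, p1, p2)``: category-0 edges join two degree-proportional stubs drawn
globally, category-1 edges are constrained to a first-level community, and
category-2 edges to a second-level community (in each case the first stub is
drawn globally and the second degree-proportionally within the first stub's
block).  Self-loops and duplicate edges are rejected and resampled; after
repeated failures the edge is dropped and recorded as a deficit, so the
realized graph is always simple.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .network import Network, Partition

__all__ = [
    "HierBenchmarkSpec",
    "HierBenchmarkResult",
    "generate_hier_benchmark",
    "truncated_poisson_mean",
]


@dataclass(frozen=True)
class HierBenchmarkSpec:
    """Parameters of the two-level hierarchical benchmark."""

    n: int = 1000
    p: tuple[float, float, float] = (0.2, 0.2, 0.6)
    degree_exponent: float = 2.0
    k_min: int = 5
    k_max: int = 70
    split_mean: float = 4.0
    split_min: int = 2
    dirichlet_conc: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.p) - 1.0) > 1e-12:
            raise ValueError("edge fractions p0 + p1 + p2 must sum to 1")
        if any(x < 0 for x in self.p):
            raise ValueError("edge fractions must be nonnegative")
        if not (2 <= self.k_min <= self.k_max):
            raise ValueError("need 2 <= k_min <= k_max")
        if self.n < 4:
            raise ValueError("benchmark needs at least 4 nodes")


@dataclass
class HierBenchmarkResult:
    """Generated network with its two planted partition levels."""

    network: Network
    level1: Partition
    level2: Partition
    edge_categories: np.ndarray
    edges: np.ndarray  # (m, 2) node-index pairs aligned with edge_categories
    degree_sequence: np.ndarray
    edge_deficit: int = 0


def truncated_poisson_mean(lam: float, minimum: int) -> float:
    """Mean of a Poisson(lam) conditioned on being >= minimum (closed form)."""
    from scipy.stats import poisson

    below = np.arange(minimum)
    p_below = poisson.pmf(below, lam)
    mass = 1.0 - p_below.sum()
    partial_mean = lam - (below * p_below).sum()
    return float(partial_mean / mass)


def _sample_split_count(rng: np.random.Generator, lam: float, minimum: int) -> int:
    while True:
        c = int(rng.poisson(lam))
        if c >= minimum:
            return c


def _split_community(
    rng: np.random.Generator, nodes: np.ndarray, spec: HierBenchmarkSpec
) -> list[np.ndarray]:
    c = _sample_split_count(rng, spec.split_mean, spec.split_min)
    probs = rng.dirichlet(np.full(c, spec.dirichlet_conc))
    assignment = rng.choice(c, size=nodes.size, p=probs)
    groups = [nodes[assignment == j] for j in range(c)]
    return [g for g in groups if g.size]  # multinomial draws may leave a child empty


def _power_law_degrees(rng: np.random.Generator, spec: HierBenchmarkSpec) -> np.ndarray:
    ks = np.arange(spec.k_min, spec.k_max + 1)
    w = ks.astype(float) ** (-spec.degree_exponent)
    w /= w.sum()
    return rng.choice(ks, size=spec.n, p=w)


def generate_hier_benchmark(spec: HierBenchmarkSpec) -> HierBenchmarkResult:
    """Generate one realization of the hierarchical benchmark."""
    rng = np.random.default_rng(spec.seed)
    nodes = np.arange(spec.n)

    level1_groups = _split_community(rng, nodes, spec)
    level2_groups: list[np.ndarray] = []
    lab1 = np.empty(spec.n, dtype=np.int64)
    lab2 = np.empty(spec.n, dtype=np.int64)
    for i, grp in enumerate(level1_groups, start=1):
        lab1[grp] = i
        for sub in _split_community(rng, grp, spec):
            level2_groups.append(sub)
            lab2[sub] = len(level2_groups)

    degrees = _power_law_degrees(rng, spec)
    m = int(round(degrees.sum() / 2.0))
    block1 = lab1 - 1
    block2 = lab2 - 1
    # per-block degree-proportional samplers
    global_p = degrees / degrees.sum()

    def block_sampler(block_labels: np.ndarray):
        tables = []
        for b in range(block_labels.max() + 1):
            members = np.flatnonzero(block_labels == b)
            w = degrees[members].astype(float)
            tables.append((members, w / w.sum()))
        return tables

    tab1 = block_sampler(block1)
    tab2 = block_sampler(block2)

    categories = rng.choice(3, size=m, p=np.asarray(spec.p))
    existing: set[tuple[int, int]] = set()
    rows, cols, cats = [], [], []
    deficit = 0
    for cat in categories:
        placed = False
        for _ in range(100):
            i = int(rng.choice(spec.n, p=global_p))
            if cat == 0:
                members, w = nodes, global_p
            elif cat == 1:
                members, w = tab1[block1[i]]
            else:
                members, w = tab2[block2[i]]
            j = int(members[rng.choice(members.size, p=w)])
            if i == j:
                continue
            key = (min(i, j), max(i, j))
            if key in existing:
                continue
            existing.add(key)
            rows.append(key[0])
            cols.append(key[1])
            cats.append(int(cat))
            placed = True
            break
        if not placed:
            deficit += 1
    r = np.array(rows)
    c = np.array(cols)
    adj = sp.coo_matrix(
        (np.ones(2 * r.size), (np.concatenate([r, c]), np.concatenate([c, r]))),
        shape=(spec.n, spec.n),
    )
    net = Network([str(v) for v in range(spec.n)], adj)
    return HierBenchmarkResult(
        network=net,
        level1=Partition(lab1),
        level2=Partition(lab2),
        edge_categories=np.array(cats, dtype=np.int64),
        edges=np.column_stack([r, c]).astype(np.int64),
        degree_sequence=degrees,
        edge_deficit=deficit,
    )
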