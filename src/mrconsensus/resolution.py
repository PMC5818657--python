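"""Resolution-parameter range estimation and gamma sampling strategies.

Multiresolution modularity interpolates between a single cluster (small
``gamma``) and all singletons (large ``gamma``).  The informative range
``[gamma_min, gamma_max]`` is bounded above by the smallest ``gamma`` at
which every pairwise interaction ``A_ij - gamma*P_ij`` is nonpositive
(computed exactly as ``max_ij A_ij / P_ij``), and below by the largest
``gamma`` at which the optimal partition is still the single cluster
(estimated iteratively from the linearity of Q in ``gamma``).

*Event sampling* places gamma values at equally spaced quantiles of

    beta(gamma) = sum_{(i,j) in E^-} |A_ij - gamma*P_ij|
                  / sum_{i != j} |A_ij - gamma*P_ij|,

the relative magnitude of antiferromagnetic (negative) interactions, which is
0 at gamma <= 0, 1 at gamma_max, and monotonically increasing in between.
Because ``E^+``/``E^-`` only change at the discrete "events"
``gamma = A_ij / P_ij``, ``beta`` is piecewise smooth and can be inverted in
closed form on each inter-event interval.  This avoids flooding the sample
with near-singleton partitions from the long high-gamma plateau that linear
(and, less severely, exponential) spacing produce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .modularity import QualityModel, iterated_louvain
from .network import Network, Partition, PartitionEnsemble

__all__ = [
    "InteractionEventTable",
    "GammaRange",
    "gamma_max",
    "beta",
    "gamma_of_beta",
    "estimate_gamma_min",
    "gamma_range",
    "sample_gammas",
    "build_ensemble",
]


class InteractionEventTable:
    """Sorted critical values ``gamma = A_ij/P_ij`` with interval aggregates.

    Built over unordered node pairs ``i < j`` with ``P_ij > 0`` under the
    configuration null; pairs with ``A_ij = 0`` collapse into a single event
    at 0.  Within any open interval between consecutive events the
    ferromagnetic set ``E+`` and antiferromagnetic set ``E-`` are constant.
    """

    def __init__(self, network: Network):
        if network.total <= 0:
            raise ValueError("network has no edges; no community structure possible")
        adj = sp.triu(network.adjacency, k=1).tocoo()
        if adj.nnz == 0:
            raise ValueError("network has no off-diagonal edges")
        k = network.degrees
        twom = network.total
        p_edge = k[adj.row] * k[adj.col] / twom
        ratios = adj.data / p_edge
        # P-mass over all unordered pairs i<j, minus the edge pairs, gives the
        # aggregate event at ratio 0 contributed by non-adjacent pairs
        tot_p = (twom**2 - float((k**2).sum())) / (2.0 * twom)
        p_zero = tot_p - float(p_edge.sum())
        events, inverse = np.unique(ratios, return_inverse=True)
        ev_a = np.bincount(inverse, weights=adj.data, minlength=events.size)
        ev_p = np.bincount(inverse, weights=p_edge, minlength=events.size)
        if events[0] > 0:
            events = np.concatenate([[0.0], events])
            ev_a = np.concatenate([[0.0], ev_a])
            ev_p = np.concatenate([[p_zero], ev_p])
        else:  # a zero-weight stored edge produced a ratio-0 event
            ev_p[0] += p_zero
        self.events = events
        self.cum_a = np.cumsum(ev_a)
        self.cum_p = np.cumsum(ev_p)
        self.tot_a = float(self.cum_a[-1])
        self.tot_p = float(self.cum_p[-1])
        self._event_betas = None

    @property
    def gamma_max(self) -> float:
        return float(self.events[-1])

    def _sums_below(self, idx: int) -> tuple[float, float]:
        if idx <= 0:
            return 0.0, 0.0
        return float(self.cum_a[idx - 1]), float(self.cum_p[idx - 1])

    def beta(self, gamma: float) -> float:
        """Relative magnitude of antiferromagnetic interactions at ``gamma``."""
        if gamma <= 0:
            return 0.0
        if gamma >= self.gamma_max:
            return 1.0
        i_lt = int(np.searchsorted(self.events, gamma, side="left"))
        i_le = int(np.searchsorted(self.events, gamma, side="right"))
        sa_neg, sp_neg = self._sums_below(i_lt)
        sa_le, sp_le = self._sums_below(i_le)
        sa_pos = self.tot_a - sa_le
        sp_pos = self.tot_p - sp_le
        neg = gamma * sp_neg - sa_neg
        pos = sa_pos - gamma * sp_pos
        denom = neg + pos
        if denom <= 0:
            raise ValueError("beta undefined: all interactions vanish")
        return float(neg / denom)

    def event_betas(self) -> np.ndarray:
        if self._event_betas is None:
            self._event_betas = np.array([self.beta(g) for g in self.events])
        return self._event_betas

    def gamma_of_beta(self, target: float) -> float:
        """Invert ``beta`` via binary search over events + per-interval closed form."""
        betas = self.event_betas()
        if not (betas[0] - 1e-12 <= target <= 1.0 + 1e-12):
            raise ValueError(f"beta target {target} outside [{betas[0]}, 1]")
        target = min(max(target, 0.0), 1.0)
        if target >= 1.0:
            return self.gamma_max
        hi = int(np.searchsorted(betas, target, side="left"))
        if hi == 0:
            return float(self.events[0])
        # gamma lies in [events[hi-1], events[hi]]; on the open interval
        # E- = ratios <= events[hi-1], E+ = ratios >= events[hi]
        sa_neg, sp_neg = self._sums_below(hi)
        sa_pos = self.tot_a - sa_neg
        sp_pos = self.tot_p - sp_neg
        num = sa_neg + target * (sa_pos - sa_neg)
        den = sp_neg + target * (sp_pos - sp_neg)
        return float(num / den)


@dataclass(frozen=True)
class GammaRange:
    """Resolution range with the beta values of its endpoints."""

    gamma_min: float
    gamma_max: float
    beta_min: float
    beta_max: float


def gamma_max(network: Network) -> float:
    """Smallest gamma with ``A_ij - gamma*P_ij <= 0`` for all pairs."""
    return InteractionEventTable(network).gamma_max


def beta(network: Network, gamma: float) -> float:
    """Evaluate the antiferromagnetic-magnitude response function."""
    return InteractionEventTable(network).beta(gamma)


def gamma_of_beta(network: Network, beta_target: float) -> float:
    """Gamma value at which ``beta(gamma) = beta_target``."""
    return InteractionEventTable(network).gamma_of_beta(beta_target)


def _partition_gamma_bound(network: Network, partition: Partition) -> float:
    """Smallest gamma at which ``partition`` beats the single-cluster partition.

    Q is linear in gamma for a fixed partition, so the crossover is
    ``(T_A - sum_in A) / (T_P - sum_in P)`` with sums over ordered pairs.
    """
    lab = partition.labels - 1
    k = partition.n_clusters
    n = network.n
    onehot = sp.csr_matrix((np.ones(n), (np.arange(n), lab)), shape=(n, k))
    a_in = float((onehot.T @ network.adjacency @ onehot).diagonal().sum())
    kc = np.bincount(lab, weights=network.degrees, minlength=k)
    p_in = float((kc**2).sum()) / network.total
    tot_a = float(network.adjacency.sum())
    tot_p = network.total
    if tot_p - p_in <= 0:
        return np.inf
    return (tot_a - a_in) / (tot_p - p_in)


def estimate_gamma_min(
    network: Network,
    optimizer=None,
    sample_size: int = 10,
    epsilon: float = 1e-3,
    seed: int = 0,
    max_iter: int = 50,
) -> float:
    """Iteratively estimate the largest gamma whose optimum is one cluster.

    Samples ``sample_size`` partitions at gamma = 1; every non-trivial
    partition bounds gamma_min from above through the linearity of Q in
    gamma; re-samples at ``gamma_min * (1 - epsilon)`` until only the
    trivial partition appears.  If the initial sample is entirely trivial the
    search first moves geometrically toward gamma_max.
    """
    if sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    optimizer = optimizer or (lambda model, s: iterated_louvain(model, s))
    rng = np.random.default_rng(seed)
    g_max = gamma_max(network)
    gamma = min(1.0, g_max)
    gmin: float | None = None
    trace: list[tuple[float, int]] = []
    for _ in range(max_iter):
        model = QualityModel.configuration(network, gamma)
        sample = [
            optimizer(model, int(rng.integers(0, 2**31 - 1)))
            for _ in range(sample_size)
        ]
        nontrivial = [p for p in sample if p.n_clusters > 1]
        trace.append((gamma, len(nontrivial)))
        if not nontrivial:
            if gmin is not None:
                return gmin
            # trivial regime extends upward; move toward gamma_max
            if gamma >= g_max * (1 - 1e-9):
                return g_max
            gamma = float(np.sqrt(gamma * g_max))
            continue
        bounds = [_partition_gamma_bound(network, p) for p in nontrivial]
        cand = min(bounds)
        gmin = cand if gmin is None else min(gmin, cand)
        next_gamma = gmin * (1.0 - epsilon)
        if next_gamma == gamma:  # no progress possible (e.g. gamma_min = 0)
            return gmin
        gamma = next_gamma
    raise RuntimeError(
        f"gamma_min estimation did not converge after {max_iter} iterations; "
        f"trace (gamma, #nontrivial): {trace}"
    )


def gamma_range(
    network: Network,
    optimizer=None,
    sample_size: int = 10,
    epsilon: float = 1e-3,
    seed: int = 0,
) -> GammaRange:
    """Estimate the full resolution range and its beta endpoints."""
    table = InteractionEventTable(network)
    gmin = estimate_gamma_min(
        network, optimizer=optimizer, sample_size=sample_size, epsilon=epsilon, seed=seed
    )
    return GammaRange(
        gamma_min=gmin,
        gamma_max=table.gamma_max,
        beta_min=table.beta(gmin),
        beta_max=1.0,
    )


def sample_gammas(
    network: Network, strategy: str, count: int, grange: GammaRange
) -> np.ndarray:
    """Draw ``count`` gamma values by event, linear, or exponential spacing."""
    if count < 2:
        raise ValueError("count must be >= 2")
    if strategy == "linear":
        return np.linspace(grange.gamma_min, grange.gamma_max, count)
    if strategy == "exponential":
        if grange.gamma_min <= 0:
            raise ValueError("exponential sampling requires gamma_min > 0")
        return np.geomspace(grange.gamma_min, grange.gamma_max, count)
    if strategy == "event":
        table = InteractionEventTable(network)
        betas = np.linspace(grange.beta_min, grange.beta_max, count)
        return np.array([table.gamma_of_beta(b) for b in betas])
    raise ValueError(f"unknown sampling strategy {strategy!r}")


def build_ensemble(
    network: Network, gammas, optimizer=None, seed: int = 0
) -> PartitionEnsemble:
    """One iterated-Louvain partition per gamma, with independent derived seeds."""
    gammas = np.asarray(gammas, dtype=float)
    if gammas.size == 0:
        raise ValueError("gammas must be nonempty")
    optimizer = optimizer or (lambda model, s: iterated_louvain(model, s))
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=gammas.size)
    partitions = [
        optimizer(QualityModel.configuration(network, g), int(s))
        for g, s in zip(gammas, seeds)
    ]
    return PartitionEnsemble(partitions, gamma_values=gammas)
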