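"""Co-classification, ensemble null models, and consensus modularity.

Given a partition ensemble ``g = {g(t)}``, the co-classification matrix

    C_ij = (1/|g|) * sum_t delta(g_i(t), g_j(t))

defines a weighted network.  Under a null model in which each partition's
labels are randomized (cluster counts and sizes fixed), ``C0_ij`` is a
rescaled Poisson-Binomial variable with per-partition success probabilities

    permutation:        p_ij(t) = sum_c  (s_c/n) * ((s_c - 1)/(n - 1))
    local permutation:  p_ij(t) = (s_{g_i(t)} - 1)/(n - 1)

whose mean ``mu_ij`` and variance ``sigma2_ij`` follow from the Bernoulli
sums.  The consensus quality function

    Q_C(g, alpha) = sum_{i,j} (C_ij - P_ij(alpha)) * delta(g_i, g_j)

uses as null matrix the alpha-quantile of the null co-classification
distribution (symmetrized so that ``max(Pr[C_ij <= p], Pr[C_ji <= p]) =
alpha``), so the only negative contributions come from pairs co-classified
statistically significantly *less* often than the null explains.  Repeatedly
re-clustering the resulting ensemble until it is unanimous yields the
consensus partition; no thresholding of C is ever applied.

The thresholded Lancichinetti-Fortunato (LF) consensus procedure is provided
as a baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .modularity import QualityModel, iterated_louvain
from .network import Network, Partition, PartitionEnsemble

__all__ = [
    "CoclassificationMatrix",
    "NullModelSpec",
    "coclassification",
    "null_probability",
    "null_moments",
    "significance_null_matrix",
    "consensus_modularity",
    "consensus_partition",
    "lf_consensus",
]


@dataclass(frozen=True)
class NullModelSpec:
    """Choice of ensemble null model and how its tail quantile is computed."""

    kind: str = "local_permutation"
    alpha: float = 0.05
    tail_method: str = "normal_approx"
    mc_reps: int = 10_000

    def __post_init__(self) -> None:
        if self.kind not in ("permutation", "local_permutation"):
            raise ValueError(f"unknown null model kind {self.kind!r}")
        if not (0 < self.alpha <= 0.5):
            raise ValueError("alpha must lie in (0, 0.5]")
        if self.tail_method not in ("normal_approx", "monte_carlo"):
            raise ValueError(f"unknown tail_method {self.tail_method!r}")


@dataclass
class CoclassificationMatrix:
    """Co-classification frequencies with their Poisson-Binomial null moments."""

    C: np.ndarray
    ensemble_size: int
    null_mean: np.ndarray
    null_var: np.ndarray

    @property
    def n(self) -> int:
        return self.C.shape[0]


def _null_probability_table(ensemble: PartitionEnsemble, kind: str) -> np.ndarray:
    """Per-partition success probabilities ``p0_ij(t)``.

    Returns shape ``(T,)`` for the pair-independent permutation model and
    ``(T, n)`` for the local permutation model, where entry ``(t, i)`` is
    ``p_ij(t)`` for any ``j != i``.
    """
    n = ensemble.n
    if n < 2:
        raise ValueError("null models need at least two nodes")
    if kind == "permutation":
        out = np.empty(ensemble.size)
        for t, part in enumerate(ensemble):
            s = part.cluster_sizes.astype(float)
            out[t] = float((s * (s - 1)).sum()) / (n * (n - 1))
        return out
    if kind == "local_permutation":
        out = np.empty((ensemble.size, n))
        for t, part in enumerate(ensemble):
            s = part.cluster_sizes.astype(float)
            out[t] = (s[part.labels - 1] - 1.0) / (n - 1.0)
        return out
    raise ValueError(f"unknown null model kind {kind!r}")


def null_probability(
    ensemble: PartitionEnsemble, kind: str, i: int, j: int, t: int
) -> float:
    """Null co-classification probability ``p0_ij(t)`` for one pair."""
    if i == j:
        raise ValueError("p0_ii = 1 trivially; null probability defined for i != j")
    table = _null_probability_table(ensemble, kind)
    if kind == "permutation":
        return float(table[t])
    return float(table[t, i])


def null_moments(
    ensemble: PartitionEnsemble, kind: str = "local_permutation"
) -> tuple[np.ndarray, np.ndarray]:
    """Null mean and variance matrices of the co-classification entries.

    ``mu_ij`` is the mean of ``p0_ij(t)`` over partitions and ``sigma2_ij``
    is ``(1/T^2) * sum_t p(1-p)``; both are returned as dense ``n x n``
    matrices with the trivial diagonal (``mu = 1``, ``sigma2 = 0``).
    """
    n = ensemble.n
    table = _null_probability_table(ensemble, kind)
    if kind == "permutation":
        mu_val = float(table.mean())
        var_val = float((table * (1 - table)).sum()) / ensemble.size**2
        mu = np.full((n, n), mu_val)
        var = np.full((n, n), var_val)
    else:
        mu_vec = table.mean(axis=0)
        var_vec = (table * (1 - table)).sum(axis=0) / ensemble.size**2
        mu = np.tile(mu_vec[:, None], (1, n))
        var = np.tile(var_vec[:, None], (1, n))
    np.fill_diagonal(mu, 1.0)
    np.fill_diagonal(var, 0.0)
    return mu, var


def coclassification(ensemble: PartitionEnsemble) -> CoclassificationMatrix:
    """Co-classification matrix with local-permutation null moments attached."""
    import scipy.sparse as sp

    labels = ensemble.labels_matrix()
    t_count, n = labels.shape
    offsets = np.concatenate([[0], np.cumsum(labels.max(axis=1))])[:-1]
    flat = (labels - 1 + offsets[:, None]).ravel()
    cols = np.tile(np.arange(n), t_count)
    g = sp.csr_matrix(
        (np.ones(flat.size), (cols, flat)), shape=(n, int(flat.max()) + 1)
    )
    c = (g @ g.T).toarray() / t_count
    np.fill_diagonal(c, 1.0)
    mu, var = null_moments(ensemble, "local_permutation")
    return CoclassificationMatrix(
        C=c, ensemble_size=t_count, null_mean=mu, null_var=var
    )


def _mc_quantiles(table: np.ndarray, alpha: float, reps: int, seed: int) -> np.ndarray:
    """Largest support value with empirical CDF <= alpha, per node (lperm).

    Simulates the Bernoulli scheme for ``C0``; for the local permutation
    model the distribution of ``C0_ij`` depends only on ``i``.
    """
    t_count, n = table.shape
    rng = np.random.default_rng(seed)
    quantiles = np.empty(n)
    for i in range(n):
        draws = (rng.random((reps, t_count)) < table[:, i]).mean(axis=1)
        support, counts = np.unique(draws, return_counts=True)
        cdf = np.cumsum(counts) / reps
        ok = np.flatnonzero(cdf <= alpha)
        quantiles[i] = support[ok[-1]] if ok.size else 0.0
    return quantiles


def significance_null_matrix(
    ensemble: PartitionEnsemble, spec: NullModelSpec, seed: int = 0
) -> np.ndarray:
    """Alpha-quantile null matrix ``P(alpha)`` for consensus modularity.

    For each pair the lower-tail alpha-quantile of the null co-classification
    distribution, symmetrized as ``min(q_ij, q_ji)`` so that the condition
    ``max(Pr[C_ij <= p], Pr[C_ji <= p]) = alpha`` holds; clipped to [0, 1]
    with diagonal 1.  With ``normal_approx`` a degenerate pair
    (``sigma = 0``) gets the quantile ``mu`` itself.
    """
    n = ensemble.n
    table = _null_probability_table(ensemble, spec.kind)
    z = float(norm.ppf(spec.alpha))
    if spec.kind == "permutation":
        if spec.tail_method == "normal_approx":
            mu = float(table.mean())
            sigma = float(np.sqrt((table * (1 - table)).sum())) / ensemble.size
            q = mu + sigma * z
        else:
            q = float(
                _mc_quantiles(table[:, None], spec.alpha, spec.mc_reps, seed)[0]
            )
        p = np.full((n, n), np.clip(q, 0.0, 1.0))
    else:
        if spec.tail_method == "normal_approx":
            mu = table.mean(axis=0)
            sigma = np.sqrt((table * (1 - table)).sum(axis=0)) / ensemble.size
            q = mu + sigma * z
        else:
            q = _mc_quantiles(table, spec.alpha, spec.mc_reps, seed)
        q = np.clip(q, 0.0, 1.0)
        p = np.minimum(q[:, None], q[None, :])
    np.fill_diagonal(p, 1.0)
    return p


def consensus_modularity(
    cmatrix: CoclassificationMatrix,
    ensemble: PartitionEnsemble,
    spec: NullModelSpec,
    seed: int = 0,
) -> QualityModel:
    """Quality model ``Q_C`` with ``A := C`` and ``P := P(alpha)`` at gamma 1."""
    p = significance_null_matrix(ensemble, spec, seed=seed)
    return QualityModel.from_matrices(cmatrix.C, p, gamma=1.0)


def _ensemble_identical(ensemble: PartitionEnsemble) -> bool:
    first = ensemble.partitions[0]
    return all(p == first for p in ensemble.partitions[1:])


def _agreement(ensemble: PartitionEnsemble) -> float:
    """Fraction of identical partition pairs in the working ensemble."""
    from collections import Counter

    counts = Counter(ensemble.partitions)
    t = ensemble.size
    if t < 2:
        return 1.0
    same = sum(c * (c - 1) for c in counts.values())
    return same / (t * (t - 1))


def _consensus_loop(
    ensemble: PartitionEnsemble,
    spec: NullModelSpec,
    optimizer,
    seed: int,
    max_iter: int,
) -> tuple[Partition, PartitionEnsemble]:
    optimizer = optimizer or (lambda model, s: iterated_louvain(model, s))
    rng = np.random.default_rng(seed)
    work = ensemble
    for _ in range(max_iter):
        if _ensemble_identical(work):
            return work.partitions[0], work
        cmat = coclassification(work)
        model = consensus_modularity(
            cmat, work, spec, seed=int(rng.integers(0, 2**31 - 1))
        )
        work = PartitionEnsemble(
            [
                optimizer(model, int(rng.integers(0, 2**31 - 1)))
                for _ in range(ensemble.size)
            ]
        )
    if _ensemble_identical(work):
        return work.partitions[0], work
    raise RuntimeError(
        f"consensus did not converge after {max_iter} iterations; "
        f"final ensemble agreement {_agreement(work):.3f}"
    )


def consensus_partition(
    ensemble: PartitionEnsemble,
    spec: NullModelSpec | None = None,
    optimizer=None,
    seed: int = 0,
    max_iter: int = 50,
) -> Partition:
    """Iterative significance-based consensus of a partition ensemble.

    Repeatedly optimizes ``Q_C`` of the working ensemble (same ensemble size
    each round, null model recomputed each round) until all partitions are
    identical — typically after one or two iterations.  The co-classification
    matrix is never thresholded.
    """
    part, _ = _consensus_loop(ensemble, spec or NullModelSpec(), optimizer, seed, max_iter)
    return part


def lf_consensus(
    ensemble: PartitionEnsemble,
    tau: float,
    base_optimizer=None,
    seed: int = 0,
    max_iter: int = 50,
) -> Partition:
    """Thresholded consensus baseline (Lancichinetti-Fortunato procedure).

    Zeroes co-classification entries below ``tau``, clusters the thresholded
    matrix as a weighted network with the same base community-detection
    configuration (configuration-null modularity at gamma = 1), rebuilds the
    ensemble, and iterates until unanimous.
    """
    if not (0.0 <= tau <= 1.0):
        raise ValueError("tau must lie in [0, 1]")
    base_optimizer = base_optimizer or (lambda model, s: iterated_louvain(model, s))
    rng = np.random.default_rng(seed)
    work = ensemble
    for _ in range(max_iter):
        if _ensemble_identical(work):
            return work.partitions[0]
        c = coclassification(work).C.copy()
        c[c < tau] = 0.0
        np.fill_diagonal(c, 0.0)
        if c.sum() == 0:
            raise RuntimeError("thresholded co-classification matrix is empty")
        net = Network([str(v) for v in range(c.shape[0])], c)
        model = QualityModel.configuration(net, gamma=1.0)
        work = PartitionEnsemble(
            [
                base_optimizer(model, int(rng.integers(0, 2**31 - 1)))
                for _ in range(ensemble.size)
            ]
        )
    if _ensemble_identical(work):
        return work.partitions[0]
    raise RuntimeError(
        f"LF consensus did not converge after {max_iter} iterations; "
        f"final ensemble agreement {_agreement(work):.3f}"
    )
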