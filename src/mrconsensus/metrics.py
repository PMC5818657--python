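"""Partition-comparison metrics: entropy, mutual information, NMI and AMI.

All quantities use natural logarithms (the normalizations cancel the units).
``ami_max`` adjusts the mutual information for chance under the permutation
model (fixed marginals; hypergeometric cell counts) and normalizes by the
larger entropy:

    AMI_max = (I - E[I]) / (max{H(g), H(h)} - E[I]).

Unlike NMI, which tends to overstate the similarity of partitions with many
small clusters, AMI is centered at 0 for independent partitions.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import gammaln

from .network import Partition

__all__ = [
    "entropy",
    "mutual_information",
    "nmi_max",
    "ami_max",
    "expected_mutual_information",
    "compare_hierarchy",
]


def _contingency(g: Partition, h: Partition) -> np.ndarray:
    if g.n != h.n:
        raise ValueError("partitions must have equal length")
    table = np.zeros((g.n_clusters, h.n_clusters), dtype=np.int64)
    np.add.at(table, (g.labels - 1, h.labels - 1), 1)
    return table


def entropy(g: Partition) -> float:
    """Plug-in entropy of the cluster-size distribution, in nats."""
    p = g.cluster_sizes / g.n
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def mutual_information(g: Partition, h: Partition) -> float:
    """Plug-in mutual information of two labelings, in nats."""
    table = _contingency(g, h)
    n = g.n
    pij = table / n
    pr = pij.sum(axis=1, keepdims=True)
    pc = pij.sum(axis=0, keepdims=True)
    mask = pij > 0
    ratio = np.where(mask, pij / (pr @ pc), 1.0)
    return float((pij[mask] * np.log(ratio[mask])).sum())


def expected_mutual_information(g: Partition, h: Partition) -> float:
    """E[I] under the permutation model (fixed marginals, hypergeometric cells)."""
    table = _contingency(g, h)
    n = g.n
    a = table.sum(axis=1)
    b = table.sum(axis=0)
    log_n_fact = gammaln(n + 1)
    emi = 0.0
    for ai in a:
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            if hi < lo:
                continue
            nij = np.arange(lo, hi + 1)
            term1 = (nij / n) * np.log(n * nij / (ai * bj))
            log_prob = (
                gammaln(ai + 1)
                + gammaln(bj + 1)
                + gammaln(n - ai + 1)
                + gammaln(n - bj + 1)
                - log_n_fact
                - gammaln(nij + 1)
                - gammaln(ai - nij + 1)
                - gammaln(bj - nij + 1)
                - gammaln(n - ai - bj + nij + 1)
            )
            emi += float((term1 * np.exp(log_prob)).sum())
    return emi


def nmi_max(g: Partition, h: Partition) -> float:
    """Mutual information normalized by the larger entropy."""
    hg, hh = entropy(g), entropy(h)
    denom = max(hg, hh)
    if denom == 0:
        if g == h:
            return 1.0
        raise ValueError("NMI undefined: both partitions have zero entropy")
    return mutual_information(g, h) / denom


def ami_max(g: Partition, h: Partition) -> float:
    """Adjusted mutual information, max-entropy normalization.

    Equals 1 for identical partitions; hovers around 0 (possibly negative)
    for independent ones.  Returns 0 with a warning when the denominator is
    non-positive (degenerate pair).
    """
    hg, hh = entropy(g), entropy(h)
    if max(hg, hh) == 0:
        if g == h:
            return 1.0
        raise ValueError("AMI undefined: both partitions have zero entropy")
    mi = mutual_information(g, h)
    emi = expected_mutual_information(g, h)
    denom = max(hg, hh) - emi
    if denom <= 0:
        warnings.warn("AMI denominator <= 0 (degenerate pair); returning 0")
        return 0.0
    return (mi - emi) / denom


def compare_hierarchy(tree, reference: Partition) -> tuple[float, float]:
    """Best cut of a consensus tree against a reference partition.

    Evaluates ``ami_max`` for every dendrogram cut and returns
    ``(best_threshold, best_ami)`` — the HC_max statistic.
    """
    from .hierarchy import all_cuts

    if tree.n != reference.n:
        raise ValueError("tree and reference cover different node sets")
    best_t, best_a = None, -np.inf
    for threshold, part in all_cuts(tree):
        a = ami_max(reference, part)
        if a > best_a:
            best_t, best_a = threshold, a
    return float(best_t), float(best_a)
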