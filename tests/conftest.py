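"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mrconsensus import (
    NullModelSpec,
    Partition,
    PartitionEnsemble,
    build_ensemble,
    gamma_range,
    make_fixture,
    sample_gammas,
)


@pytest.fixture(scope="session")
def ring6():
    return make_fixture("ring", n=6)


@pytest.fixture(scope="session")
def two_k3():
    """Two disconnected triangles with the planted 2-clique partition."""
    return make_fixture("cliques", s=3, c=2, bridges=0)


@pytest.fixture(scope="session")
def two_k5():
    """Two K5 cliques joined by one bridge edge, with the planted partition."""
    return make_fixture("cliques", s=5, c=2, bridges=1)


@pytest.fixture(scope="session")
def two_k5_range(two_k5):
    net, _ = two_k5
    return gamma_range(net, seed=11)


@pytest.fixture(scope="session")
def two_k5_ensemble(two_k5, two_k5_range):
    """250-partition event-sampled ensemble on the bridged two-K5 fixture."""
    net, _ = two_k5
    gammas = sample_gammas(net, "event", 250, two_k5_range)
    return build_ensemble(net, gammas, seed=21)


@pytest.fixture(scope="session")
def random_ensemble_small():
    """Random 10-node, 20-partition ensemble for null-model oracles."""
    rng = np.random.default_rng(7)
    parts = [Partition(rng.integers(1, 5, size=10)) for _ in range(20)]
    return PartitionEnsemble(parts)


# ---------------------------------------------------------------------------
# exhaustive enumeration oracle


def set_partitions(n: int) -> np.ndarray:
    """All set partitions of ``n`` items as restricted-growth label rows."""
    rows = [[0]]
    for _ in range(n - 1):
        new = []
        for row in rows:
            top = max(row)
            for lab in range(top + 2):
                new.append(row + [lab])
        rows = new
    return np.array(rows, dtype=np.int8)


def exhaustive_best_q(weight: np.ndarray, chunk: int = 20000):
    """Maximum of ``sum_ij W_ij delta(g_i,g_j)`` over all set partitions.

    ``weight`` is the full interaction matrix (A - gamma*P) including the
    diagonal.  Returns (best Q, best label row).
    """
    n = weight.shape[0]
    rows = set_partitions(n)
    best_q, best_row = -np.inf, None
    for start in range(0, rows.shape[0], chunk):
        block = rows[start : start + chunk]
        delta = block[:, :, None] == block[:, None, :]
        q = np.einsum("kij,ij->k", delta, weight)
        idx = int(np.argmax(q))
        if q[idx] > best_q:
            best_q = float(q[idx])
            best_row = block[idx]
    return best_q, best_row


@pytest.fixture(scope="session")
def null_spec():
    return NullModelSpec(alpha=0.05)
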