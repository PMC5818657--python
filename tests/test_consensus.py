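"""Co-classification, null models, consensus modularity, and the LF baseline."""

import numpy as np
import pytest
from scipy.stats import norm

from mrconsensus import (
    NullModelSpec,
    Partition,
    PartitionEnsemble,
    QualityModel,
    coclassification,
    consensus_modularity,
    consensus_partition,
    iterated_louvain,
    lf_consensus,
    null_moments,
    null_probability,
    significance_null_matrix,
)
from .conftest import exhaustive_best_q


class TestCoclassification:
    def test_identical_partitions_block_matrix(self):
        p = Partition(np.array([1, 1, 2, 2, 2]))
        cm = coclassification(PartitionEnsemble([p] * 4))
        expected = (p.labels[:, None] == p.labels[None, :]).astype(float)
        np.testing.assert_allclose(cm.C, expected)

    def test_half_agreement(self):
        a = Partition(np.array([1, 1, 2]))
        b = Partition(np.array([1, 2, 2]))
        cm = coclassification(PartitionEnsemble([a, b]))
        assert cm.C[0, 1] == pytest.approx(0.5)  # together only in a
        assert cm.C[1, 2] == pytest.approx(0.5)  # together only in b
        assert cm.C[0, 2] == pytest.approx(0.0)

    def test_diagonal_always_one(self, random_ensemble_small):
        cm = coclassification(random_ensemble_small)
        np.testing.assert_allclose(np.diag(cm.C), 1.0)

    def test_values_are_multiples_of_inverse_size(self, random_ensemble_small):
        cm = coclassification(random_ensemble_small)
        scaled = cm.C * random_ensemble_small.size
        np.testing.assert_allclose(scaled, np.round(scaled), atol=1e-9)


def mc_permutation_coclass(part: Partition, i: int, j: int, reps: int, seed: int):
    """Co-classification frequency of (i, j) under uniform label permutation."""
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(part.labels, (reps, 1)), axis=1)
    return float((perms[:, i] == perms[:, j]).mean())


def mc_local_permutation_coclass(part: Partition, i: int, j: int, reps: int, seed: int):
    """Frequency that j joins i's cluster when only j's label is random."""
    rng = np.random.default_rng(seed)
    others = np.delete(part.labels, i)
    draws = rng.choice(others, size=reps)
    return float((draws == part.labels[i]).mean())


class TestNullProbability:
    def test_permutation_closed_form(self):
        ens = PartitionEnsemble([Partition(np.array([1, 1, 2, 2]))])
        assert null_probability(ens, "permutation", 0, 2, 0) == pytest.approx(1 / 3)

    def test_local_permutation_closed_form(self):
        ens = PartitionEnsemble([Partition(np.array([1, 1, 2, 2]))])
        assert null_probability(ens, "local_permutation", 0, 2, 0) == pytest.approx(1 / 3)

    def test_single_cluster_gives_one(self):
        ens = PartitionEnsemble([Partition(np.ones(6, dtype=int))])
        for kind in ("permutation", "local_permutation"):
            assert null_probability(ens, kind, 1, 4, 0) == 1.0

    def test_diagonal_rejected(self):
        ens = PartitionEnsemble([Partition(np.array([1, 2]))])
        with pytest.raises(ValueError):
            null_probability(ens, "permutation", 1, 1, 0)

    @pytest.mark.parametrize("kind", ["permutation", "local_permutation"])
    def test_against_monte_carlo_permutation_oracle(self, kind):
        """Closed forms match direct simulation of the permutation scheme."""
        rng = np.random.default_rng(0)
        part = Partition(rng.integers(1, 4, size=10))
        ens = PartitionEnsemble([part])
        reps = 100_000
        for i, j in [(0, 1), (2, 7), (4, 9)]:
            if kind == "permutation":
                est = mc_permutation_coclass(part, i, j, reps, seed=i * 10 + j)
            else:
                est = mc_local_permutation_coclass(part, i, j, reps, seed=i * 10 + j)
            p = null_probability(ens, kind, i, j, 0)
            se = np.sqrt(max(p * (1 - p), 1e-6) / reps)
            assert abs(est - p) < 3 * se

    def test_local_permutation_asymmetric(self):
        part = Partition(np.array([1, 1, 1, 2, 3]))
        ens = PartitionEnsemble([part])
        pij = null_probability(ens, "local_permutation", 0, 3, 0)
        pji = null_probability(ens, "local_permutation", 3, 0, 0)
        assert pij != pji


class TestNullMoments:
    def test_identical_single_cluster(self):
        ens = PartitionEnsemble([Partition(np.ones(5, dtype=int))] * 8)
        mu, var = null_moments(ens, "local_permutation")
        np.testing.assert_allclose(mu, 1.0)
        np.testing.assert_allclose(var, 0.0)

    @pytest.mark.parametrize("kind", ["permutation", "local_permutation"])
    def test_against_bernoulli_scheme_oracle(self, random_ensemble_small, kind):
        """Moment formulas match Monte-Carlo simulation of the Bernoulli sums."""
        from mrconsensus.consensus import _null_probability_table

        ens = random_ensemble_small
        table = _null_probability_table(ens, kind)
        mu, var = null_moments(ens, kind)
        rng = np.random.default_rng(11)
        reps = 10_000
        for i in (0, 3, 8):
            p = table if kind == "permutation" else table[:, i]
            sims = (rng.random((reps, ens.size)) < p).mean(axis=1)
            se_mean = sims.std(ddof=1) / np.sqrt(reps)
            assert abs(sims.mean() - mu[i, (i + 1) % ens.n]) < 3 * se_mean + 1e-12
            v = sims.var(ddof=1)
            se_var = np.sqrt(
                max(((sims - sims.mean()) ** 4).mean() - v**2, 0.0) / reps
            )
            assert abs(v - var[i, (i + 1) % ens.n]) < 3 * se_var + 1e-6

    def test_variance_bound(self, random_ensemble_small):
        _, var = null_moments(random_ensemble_small, "local_permutation")
        assert var.max() <= 1.0 / (4 * random_ensemble_small.size) + 1e-12


class TestSignificanceNullMatrix:
    def test_alpha_half_returns_mean(self, random_ensemble_small):
        spec = NullModelSpec(kind="permutation", alpha=0.5)
        p = significance_null_matrix(random_ensemble_small, spec)
        mu, _ = null_moments(random_ensemble_small, "permutation")
        off = ~np.eye(random_ensemble_small.n, dtype=bool)
        np.testing.assert_allclose(p[off], mu[off], atol=1e-12)

    def test_normal_quantile_value(self, random_ensemble_small):
        spec = NullModelSpec(kind="local_permutation", alpha=0.05)
        p = significance_null_matrix(random_ensemble_small, spec)
        mu, var = null_moments(random_ensemble_small, "local_permutation")
        z = norm.ppf(0.05)
        assert z == pytest.approx(-1.6449, abs=1e-4)
        q = np.clip(mu + np.sqrt(var) * z, 0, 1)
        expected = np.minimum(q, q.T)
        off = ~np.eye(random_ensemble_small.n, dtype=bool)
        np.testing.assert_allclose(p[off], expected[off], atol=1e-12)

    def test_permutation_model_pair_independent(self, two_k5_ensemble):
        spec = NullModelSpec(kind="permutation", alpha=0.05)
        p = significance_null_matrix(two_k5_ensemble, spec)
        off = p[~np.eye(p.shape[0], dtype=bool)]
        assert np.ptp(off) == 0.0

    def test_monte_carlo_close_to_normal_on_large_ensemble(self):
        rng = np.random.default_rng(2)
        parts = [Partition(rng.integers(1, 4, size=10)) for _ in range(250)]
        ens = PartitionEnsemble(parts)
        pn = significance_null_matrix(ens, NullModelSpec(alpha=0.05))
        pm = significance_null_matrix(
            ens,
            NullModelSpec(alpha=0.05, tail_method="monte_carlo", mc_reps=20000),
            seed=3,
        )
        assert np.abs(pn - pm).max() < 0.02

    def test_degenerate_sigma_returns_mean(self):
        ens = PartitionEnsemble([Partition(np.array([1, 1, 2, 2]))] * 5)
        p = significance_null_matrix(ens, NullModelSpec(alpha=0.05))
        # p = 1/3 for every pair/partition -> sigma > 0; build a truly
        # degenerate case from single-cluster partitions instead (p = 1)
        ens2 = PartitionEnsemble([Partition(np.ones(4, dtype=int))] * 5)
        p2 = significance_null_matrix(ens2, NullModelSpec(alpha=0.05))
        np.testing.assert_allclose(p2, 1.0)
        assert p.shape == (4, 4)


class TestConsensusModularity:
    def test_all_ferromagnetic_single_cluster_optimal(self):
        parts = [Partition(np.ones(6, dtype=int))] * 9 + [
            Partition(np.array([1, 1, 1, 2, 2, 2]))
        ]
        ens = PartitionEnsemble(parts)
        cm = coclassification(ens)
        model = consensus_modularity(cm, ens, NullModelSpec(alpha=0.05))
        b = cm.C - model.null_matrix
        assert (b[~np.eye(6, dtype=bool)] >= 0).all()  # no antiferromagnetic pair
        assert iterated_louvain(model, 0).n_clusters == 1

    def test_two_k5_ensemble_matches_enumeration(self, two_k5, two_k5_ensemble):
        """The consensus quality optimum is exactly the planted 2-clique split."""
        _, planted = two_k5
        cm = coclassification(two_k5_ensemble)
        model = consensus_modularity(cm, two_k5_ensemble, NullModelSpec(alpha=0.05))
        w = cm.C - model.null_matrix
        np.fill_diagonal(w, 0.0)
        _, best_row = exhaustive_best_q(w)
        assert Partition(best_row + 1) == planted
        assert iterated_louvain(model, 1) == planted


class TestConsensusPartition:
    def test_identical_ensemble_returned_immediately(self):
        p = Partition(np.array([1, 1, 2, 2, 3]))
        assert consensus_partition(PartitionEnsemble([p] * 6), seed=0) == p

    def test_two_k5_recovers_planted(self, two_k5, two_k5_ensemble):
        _, planted = two_k5
        out = consensus_partition(two_k5_ensemble, NullModelSpec(alpha=0.05), seed=5)
        assert out == planted

    def test_deterministic_given_seed(self, two_k5_ensemble):
        a = consensus_partition(two_k5_ensemble, seed=9)
        b = consensus_partition(two_k5_ensemble, seed=9)
        assert a == b

    def test_random_network_safety_at_scale(self):
        """Fixed-resolution ensembles on a 1000-node random graph yield one
        cluster: no communities are identified in random networks."""
        from mrconsensus import make_fixture

        er = make_fixture("er", n=1000, p=0.005, seed=0)
        model = QualityModel.configuration(er, 1.0)
        rng = np.random.default_rng(100)
        parts = [
            iterated_louvain(model, int(rng.integers(2**31 - 1))) for _ in range(250)
        ]
        out = consensus_partition(
            PartitionEnsemble(parts), NullModelSpec(alpha=0.05), seed=1
        )
        assert out.n_clusters == 1


class TestLFConsensus:
    def test_identical_ensemble_any_tau(self):
        p = Partition(np.array([1, 1, 2, 2]))
        for tau in (0.0, 0.5, 1.0):
            assert lf_consensus(PartitionEnsemble([p] * 5), tau, seed=0) == p

    def test_tau_zero_keeps_all_entries(self, two_k5_ensemble):
        out = lf_consensus(two_k5_ensemble, 0.0, seed=2)
        assert out.n_clusters >= 1  # converges without thresholding

    def test_tau_one_keeps_only_unanimous_pairs(self):
        a = Partition(np.array([1, 1, 1, 2, 2, 2]))
        b = Partition(np.array([1, 1, 2, 2, 3, 3]))
        ens = PartitionEnsemble([a, b] * 5)
        out = lf_consensus(ens, 1.0, seed=3)
        # unanimous pairs by direct inspection of a and b: (0,1) and (4,5)
        assert out.labels[0] == out.labels[1]
        assert out.labels[4] == out.labels[5]
        assert out.labels[2] != out.labels[0]
        assert out.labels[2] != out.labels[3]

    def test_invalid_tau(self, two_k5_ensemble):
        with pytest.raises(ValueError):
            lf_consensus(two_k5_ensemble, 1.5, seed=0)
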