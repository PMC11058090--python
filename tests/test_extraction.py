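"""Gaussian NMF: updates, averaging, rank selection, and R-squared."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from syngait import (
    SynergySpec,
    average_repetitions,
    cosine_similarity,
    nmf_factorize,
    r_squared,
    select_rank,
    synthesize_trial,
)


def match_to_truth(M_true, P_true, syn):
    """Min per-component cosine similarity to ground truth after optimal matching."""
    ref = M_true / np.linalg.norm(M_true, axis=0)
    cur = syn.M / np.linalg.norm(syn.M, axis=0)
    sim = ref.T @ cur
    _, cols = linear_sum_assignment(-sim)
    w = min(sim[i, cols[i]] for i in range(M_true.shape[1]))
    p = min(
        cosine_similarity(P_true[i], syn.P[cols[i]]) for i in range(M_true.shape[1])
    )
    return w, p


class TestRSquared:
    def test_perfect_reconstruction_gives_one(self, rng):
        V = rng.uniform(size=(4, 10))
        assert r_squared(V, V) == 1.0

    def test_grand_mean_reconstruction_gives_zero(self, rng):
        V = rng.uniform(size=(4, 10))
        assert r_squared(V, np.full_like(V, V.mean())) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_definition(self, rng):
        V = rng.uniform(size=(4, 10))
        V_R = rng.uniform(size=(4, 10))
        sse = sum(
            (V[i, j] - V_R[i, j]) ** 2 for i in range(4) for j in range(10)
        )
        sst = sum((V[i, j] - V.mean()) ** 2 for i in range(4) for j in range(10))
        assert r_squared(V, V_R) == pytest.approx(1 - sse / sst, abs=1e-12)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="SST"):
            r_squared(np.ones((3, 3)), np.ones((3, 3)))


class TestFactorize:
    def test_exact_rank2_product_recovered(self, rng):
        M = rng.uniform(0.1, 1.0, size=(6, 2))
        P = rng.uniform(0.1, 1.0, size=(2, 30))
        syn = nmf_factorize(M @ P, rank=2, seed=0)
        assert syn.r_squared >= 0.999

    def test_factors_always_non_negative(self, rng):
        V = rng.uniform(size=(5, 40))
        syn = nmf_factorize(V, rank=3, seed=1)
        assert np.min(syn.M) >= 0 and np.min(syn.P) >= 0

    def test_rank1_fit_worse_than_rank2_on_rank2_data(self, rng):
        M = rng.uniform(0.1, 1.0, size=(6, 2))
        P = rng.uniform(0.1, 1.0, size=(2, 30))
        V = M @ P
        assert (
            nmf_factorize(V, 1, seed=0).r_squared
            < nmf_factorize(V, 2, seed=0).r_squared
        )

    def test_error_history_monotone_non_increasing(self, rng):
        V = rng.uniform(size=(8, 50))
        _, hist = nmf_factorize(V, rank=3, seed=2, return_history=True)
        assert np.all(np.diff(hist) <= 1e-10)

    def test_deterministic_for_fixed_seed(self, rng):
        V = rng.uniform(size=(5, 20))
        a = nmf_factorize(V, 2, seed=3)
        b = nmf_factorize(V, 2, seed=3)
        assert np.array_equal(a.M, b.M) and np.array_equal(a.P, b.P)

    def test_pattern_rows_max_normalized_scale_in_weights(self, rng):
        V = rng.uniform(size=(6, 30))
        syn = nmf_factorize(V, 3, seed=4)
        assert np.allclose(syn.P.max(axis=1), 1.0)
        assert r_squared(V, syn.M @ syn.P) == pytest.approx(syn.r_squared)

    def test_invalid_inputs_rejected(self, rng):
        V = rng.uniform(size=(5, 20))
        with pytest.raises(ValueError, match="non-negative"):
            nmf_factorize(V - 1.0, 2)
        with pytest.raises(ValueError, match="rank"):
            nmf_factorize(V, 6)

    def test_agrees_with_reference_solver_on_easy_data(self, rng):
        # independent cross-check: sklearn's MU solver on the same objective
        from sklearn.decomposition import NMF

        M = rng.uniform(0.1, 1.0, size=(8, 3))
        P = rng.uniform(0.1, 1.0, size=(3, 40))
        V = M @ P
        ours = nmf_factorize(V, 3, seed=0, max_iter=2000)
        ref = NMF(3, init="random", solver="mu", max_iter=2000, random_state=0)
        W = ref.fit_transform(V)
        assert r_squared(V, ours.M @ ours.P) == pytest.approx(
            r_squared(V, W @ ref.components_), abs=1e-3
        )


class TestAverageRepetitions:
    def test_single_repetition_equals_factorization(self, rng):
        V = rng.uniform(size=(5, 30))
        avg = average_repetitions(V, 2, n_rep=1, seed=5)
        seed0 = int(np.random.default_rng(5).integers(0, 2**31 - 1, size=1)[0])
        single = nmf_factorize(V, 2, seed=seed0)
        assert np.allclose(avg.M, single.M) and np.allclose(avg.P, single.P)

    def test_matching_restores_column_permutations(self, rng):
        # hand-build "repetitions" that are permutations of one factorization
        from syngait.extraction import _match_columns

        M = rng.uniform(0.1, 1.0, size=(6, 4))
        perm = np.array([2, 0, 3, 1])
        cols = _match_columns(M, M[:, perm])
        assert np.array_equal(M[:, perm][:, cols], M)

    def test_averaged_recovery_at_least_median_single(self, noiseless_trial):
        cycles, gt = noiseless_trial
        V = cycles[0]
        avg = average_repetitions(V, 4, n_rep=10, seed=6)
        w_avg, _ = match_to_truth(gt.M_true, gt.P_true, avg)
        singles = [
            match_to_truth(gt.M_true, gt.P_true, nmf_factorize(V, 4, seed=s))[0]
            for s in range(10)
        ]
        assert w_avg >= np.median(singles) - 1e-6

    def test_r_squared_non_decreasing_in_rank(self, noiseless_trial):
        cycles, _ = noiseless_trial
        r2 = [average_repetitions(cycles[0], r, n_rep=5, seed=7).r_squared
              for r in (1, 2, 3, 4)]
        assert all(b >= a - 0.01 for a, b in zip(r2, r2[1:]))


class TestSelectRank:
    def test_exact_rank1_input_selects_one(self, rng):
        V = np.outer(rng.uniform(0.1, 1, 6), rng.uniform(0.1, 1, 40))
        rank, curve = select_rank(V, max_rank=6, n_rep=3, seed=8)
        assert rank == 1

    def test_pure_noise_returns_valid_rank(self, rng):
        V = rng.uniform(size=(13, 200))
        rank, _ = select_rank(V, max_rank=6, n_rep=2, seed=9)
        assert 1 <= rank <= 6

    def test_recovers_planted_rank_on_low_noise_trial(self):
        spec = SynergySpec(noise_sd=0.02, seed=13)
        cycles, _ = synthesize_trial(spec)
        rank, curve = select_rank(cycles[0], seed=10)
        assert rank == 4
        assert len(curve) == 10


class TestParameterRecovery:
    def test_noiseless_components_match_truth(self, noiseless_trial):
        cycles, gt = noiseless_trial
        syn = average_repetitions(cycles[0], 4, n_rep=20, seed=11)
        w, p = match_to_truth(gt.M_true, gt.P_true, syn)
        assert w >= 0.99 and p >= 0.99

    def test_noisy_components_match_truth(self):
        spec = SynergySpec(noise_sd=0.05, seed=14)
        cycles, gt = synthesize_trial(spec)
        syn = average_repetitions(cycles[0], 4, n_rep=20, seed=12)
        w, p = match_to_truth(gt.M_true, gt.P_true, syn)
        assert w >= 0.90 and p >= 0.90
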