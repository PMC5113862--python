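import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from conftest import random_hmm, random_tree_emission
from oracles import all_words, hmm_best_path, hmm_sequence_loglik
from popmodes.hmm import (
    HMMParams,
    StationaryMixture,
    baum_welch_fit,
    forward_backward,
    refit_transition_matrix,
    sample_hmm,
    select_num_modes,
    static_log_likelihood,
    stationary_weights,
    viterbi,
)
from popmodes.raster import BinaryRaster, word_frequencies
from popmodes.synthetic import make_ground_truth_model
from popmodes.tree import TreeEmission, emission_logprob


def match_modes(true_means, fit_means):
    """Permutation of fitted modes best matching the true ones (L1 cost)."""
    cost = np.abs(true_means[:, None, :] - fit_means[None, :, :]).sum(axis=2)
    _, perm = linear_sum_assignment(cost)
    return perm


class TestForwardBackward:
    def test_single_mode_gamma_one(self, rng):
        model = random_hmm(4, 1, seed=2)
        data = (rng.random((4, 20)) < 0.3).astype(np.uint8)
        post = forward_backward(model, data)
        assert np.allclose(post.gamma, 1.0)
        expected = emission_logprob(model.emissions[0], data).sum()
        assert np.isclose(post.loglik, expected, atol=1e-10)

    def test_uniform_chain_factorizes(self, rng):
        m = 3
        model = random_hmm(3, m, seed=5)
        model.transition = np.full((m, m), 1 / m)
        model.initial = np.full(m, 1 / m)
        data = (rng.random((3, 10)) < 0.4).astype(np.uint8)
        post = forward_backward(model, data)
        logq = np.stack(
            [emission_logprob(e, data) for e in model.emissions]
        )  # (M, T)
        expected = np.exp(logq) / np.exp(logq).sum(axis=0, keepdims=True)
        assert np.allclose(post.gamma, expected.T, atol=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_loglik_matches_sequence_enumeration(self, seed):
        model = random_hmm(3, 2, seed=seed)
        rng = np.random.default_rng(seed + 100)
        data = (rng.random((3, 3)) < 0.5).astype(np.uint8)
        post = forward_backward(model, data)
        assert np.isclose(post.loglik, hmm_sequence_loglik(model, data), atol=1e-10)

    def test_posterior_consistency(self, rng):
        model = random_hmm(4, 3, seed=8)
        data = (rng.random((4, 30)) < 0.3).astype(np.uint8)
        post = forward_backward(model, data)
        assert np.allclose(post.gamma.sum(axis=1), 1.0, atol=1e-8)
        assert np.allclose(post.xi.sum(axis=(1, 2)), 1.0, atol=1e-8)
        # marginalizing xi reproduces adjacent gammas
        assert np.allclose(post.xi.sum(axis=1), post.gamma[:-1], atol=1e-8)
        assert np.allclose(post.xi.sum(axis=2), post.gamma[1:], atol=1e-8)

    def test_loglik_invariant_to_mode_relabeling(self, rng):
        model = random_hmm(3, 3, seed=4)
        data = (rng.random((3, 25)) < 0.4).astype(np.uint8)
        ll0 = forward_backward(model, data).loglik
        perm = np.array([2, 0, 1])
        permuted = HMMParams(
            n_modes=3,
            transition=model.transition[np.ix_(perm, perm)],
            initial=model.initial[perm],
            emissions=[model.emissions[p] for p in perm],
        )
        assert np.isclose(forward_backward(permuted, data).loglik, ll0, atol=1e-10)

    def test_bad_transition_matrix_rejected(self, rng):
        model = random_hmm(2, 2, seed=0)
        model.transition = np.array([[0.5, 0.5], [0.1, 0.5]])
        data = (rng.random((2, 5)) < 0.5).astype(np.uint8)
        with pytest.raises(ValueError):
            forward_backward(model, data)


class TestViterbi:
    def test_single_mode_constant(self, rng):
        model = random_hmm(3, 1, seed=1)
        data = (rng.random((3, 12)) < 0.4).astype(np.uint8)
        assert np.all(viterbi(model, data).path == 0)

    def test_identical_emissions_diagonal_dominant(self, rng):
        em = random_tree_emission(3, 0)
        model = HMMParams(
            n_modes=2,
            transition=np.array([[0.9, 0.1], [0.1, 0.9]]),
            initial=np.array([0.3, 0.7]),
            emissions=[em, em],
        )
        data = (rng.random((3, 15)) < 0.4).astype(np.uint8)
        path = viterbi(model, data).path
        assert np.all(path == path[0])
        assert path[0] == 1  # higher initial weight, same self-transition

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_search(self, seed):
        model = random_hmm(2, 3, seed=seed + 10)
        rng = np.random.default_rng(seed)
        data = (rng.random((2, 5)) < 0.5).astype(np.uint8)
        assert np.array_equal(viterbi(model, data).path, hmm_best_path(model, data))

    def test_beats_random_paths(self, rng):
        model = random_hmm(4, 3, seed=3)
        data = (rng.random((4, 40)) < 0.3).astype(np.uint8)
        path = viterbi(model, data).path

        def path_logprob(p):
            lp = np.log(model.initial[p[0]]) + emission_logprob(
                model.emissions[p[0]], data[:, 0]
            )
            for t in range(1, len(p)):
                lp += np.log(model.transition[p[t], p[t - 1]])
                lp += emission_logprob(model.emissions[p[t]], data[:, t])
            return lp

        best = path_logprob(path)
        for _ in range(1000):
            alt = rng.integers(0, 3, size=40)
            assert path_logprob(alt) <= best + 1e-10


class TestStationaryWeights:
    def test_uniform_transition_uniform_weights(self):
        model = random_hmm(2, 4, seed=0)
        model.transition = np.full((4, 4), 0.25)
        w = stationary_weights(model).weights
        assert np.allclose(w, 0.25, atol=1e-10)

    def test_identity_transition_errors(self):
        model = random_hmm(2, 3, seed=0)
        model.transition = np.eye(3)
        with pytest.raises(ValueError, match="stationary"):
            stationary_weights(model)

    def test_two_state_closed_form(self):
        model = random_hmm(2, 2, seed=0)
        model.transition = np.array([[0.9, 0.2], [0.1, 0.8]])
        w = stationary_weights(model).weights
        assert np.allclose(w, [2 / 3, 1 / 3], atol=1e-10)
        assert np.allclose(model.transition @ w, w, atol=1e-10)


class TestStaticLogLikelihood:
    def test_empirical_mixture_gives_negative_entropy(self, rng):
        # mixture that exactly reproduces the empirical word distribution:
        # one near-deterministic mode per observed word
        data = np.array(
            [[0, 0, 1, 1, 0, 0], [0, 1, 1, 1, 0, 1]], dtype=np.uint8
        )
        raster = BinaryRaster(data, 0.02)
        df = word_frequencies(raster)
        eps = 1e-12
        emissions = []
        for word in df["word"]:
            bits = np.array([eps if b == "0" else 1 - eps for b in word])
            emissions.append(TreeEmission(bits, [], np.empty((0, 2, 2))))
        mixture = StationaryMixture(
            weights=df["frequency"].to_numpy(), emissions=emissions
        )
        _, L = static_log_likelihood(mixture, raster)
        f = df["frequency"].to_numpy()
        assert np.isclose(L, (f * np.log(f)).sum(), atol=1e-6)

    def test_single_mode_independent_cells(self, rng):
        data = (rng.random((3, 200)) < 0.3).astype(np.uint8)
        m = np.clip(data.mean(axis=1), 1e-6, 1 - 1e-6)
        em = TreeEmission(m, [], np.empty((0, 2, 2)))
        mixture = StationaryMixture(weights=np.array([1.0]), emissions=[em])
        _, L = static_log_likelihood(mixture, BinaryRaster(data, 0.02))
        expected = np.mean(
            np.log(np.where(data == 1, m[:, None], 1 - m[:, None])).sum(axis=0)
        )
        assert np.isclose(L, expected, atol=1e-10)

    def test_hand_built_two_mode_mixture(self):
        rng = np.random.default_rng(0)
        data = (rng.random((3, 20)) < 0.5).astype(np.uint8)
        raster = BinaryRaster(data, 0.02)
        e1 = random_tree_emission(3, 1)
        e2 = random_tree_emission(3, 2)
        w = np.array([0.4, 0.6])
        mixture = StationaryMixture(weights=w, emissions=[e1, e2])
        table, L = static_log_likelihood(mixture, raster)
        # brute force
        expected = 0.0
        uniq, counts = np.unique(data, axis=1, return_counts=True)
        for k in range(uniq.shape[1]):
            word = uniq[:, k]
            p = w[0] * np.exp(emission_logprob(e1, word)) + w[1] * np.exp(
                emission_logprob(e2, word)
            )
            expected += counts[k] / 20 * np.log(p)
        assert np.isclose(L, expected, atol=1e-12)

    def test_min_count_truncation(self, rng):
        data = (rng.random((3, 50)) < 0.4).astype(np.uint8)
        raster = BinaryRaster(data, 0.02)
        e = random_tree_emission(3, 5)
        mixture = StationaryMixture(weights=np.array([1.0]), emissions=[e])
        table, L_full = static_log_likelihood(mixture, raster, min_count=1)
        _, L_trunc = static_log_likelihood(mixture, raster, min_count=2)
        keep = table["count"] >= 2
        expected = (table["frequency"][keep] * table["log_pmodel"][keep]).sum()
        assert np.isclose(L_trunc, expected, atol=1e-12)
        assert L_trunc >= L_full  # dropped terms are negative


class TestBaumWelch:
    def test_single_mode_recovers_empirical_marginals(self, rng):
        data = (rng.random((5, 400)) < 0.3).astype(np.uint8)
        model = baum_welch_fit(data, 1, seed=0, n_restarts=1, max_iter=20)
        emp = data.mean(axis=1)
        assert np.allclose(model.emissions[0].marginals, emp, atol=1e-9)

    def test_eta_one_collapses_to_global_tables(self, rng):
        data = (rng.random((4, 300)) < 0.3).astype(np.uint8)
        model = baum_welch_fit(
            data, 3, eta=1.0, seed=0, n_restarts=1, max_iter=3
        )
        g = np.clip(data.mean(axis=1), 1e-6, 1 - 1e-6)
        for em in model.emissions:
            assert np.allclose(em.marginals, g, atol=1e-12)

    def test_monotone_loglik(self, rng):
        data = (rng.random((6, 600)) < 0.2).astype(np.uint8)
        model = baum_welch_fit(data, 3, seed=2, n_restarts=2, max_iter=60)
        hist = np.array(model.meta["loglik_history"])
        assert np.all(np.diff(hist) >= -1e-8 * np.abs(hist[:-1]))

    def test_fitted_model_valid(self, rng):
        data = (rng.random((5, 500)) < 0.25).astype(np.uint8)
        model = baum_welch_fit(data, 2, seed=1, n_restarts=1, max_iter=30)
        model.validate(atol=1e-8)

    def test_parameter_recovery_small(self):
        truth = make_ground_truth_model(
            12, 3, separation=1.0, self_transition=0.8, seed=5
        )
        raster, _ = sample_hmm(truth, 15_000, seed=6)
        fit = baum_welch_fit(raster, 3, seed=3, n_restarts=3, max_iter=150)
        true_means = np.stack([e.marginals for e in truth.emissions])
        fit_means = np.stack([e.marginals for e in fit.emissions])
        perm = match_modes(true_means, fit_means)
        assert np.abs(true_means - fit_means[perm]).max() <= 0.05
        P_fit = fit.transition[np.ix_(perm, perm)]
        assert np.abs(truth.transition - P_fit).max() <= 0.08

    def test_too_few_bins_errors(self, rng):
        data = (rng.random((3, 2)) < 0.5).astype(np.uint8)
        with pytest.raises(ValueError):
            baum_welch_fit(data, 5)


class TestRefitTransitions:
    def test_emissions_frozen(self, rng):
        data = (rng.random((4, 300)) < 0.3).astype(np.uint8)
        model = baum_welch_fit(
            data, 2, seed=0, n_restarts=1, max_iter=10, tree=False
        )
        refit = refit_transition_matrix(model, data)
        for e0, e1 in zip(model.emissions, refit.emissions):
            assert np.array_equal(e0.marginals, e1.marginals)
        refit.validate(atol=1e-8)


class TestSelectNumModes:
    def test_single_candidate(self, rng):
        data = (rng.random((4, 200)) < 0.3).astype(np.uint8)
        _, chosen = select_num_modes(
            data, [1], n_folds=2, seed=0, n_restarts=1, max_iter=10
        )
        assert chosen == 1

    def test_tiny_fold_errors(self):
        data = np.zeros((2, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            select_num_modes(data, [1], n_folds=2)

    def test_recovers_true_mode_count(self):
        truth = make_ground_truth_model(
            15, 3, separation=1.0, self_transition=0.8, seed=11
        )
        raster, _ = sample_hmm(truth, 12_000, seed=12)
        table, chosen = select_num_modes(
            raster, [1, 2, 3, 5], n_folds=2, seed=1,
            n_restarts=2, max_iter=80,
        )
        assert chosen == 3


class TestSampleHmm:
    def test_single_mode_statistics(self):
        em = random_tree_emission(4, 0)
        model = HMMParams(
            n_modes=1,
            transition=np.array([[1.0]]),
            initial=np.array([1.0]),
            emissions=[em],
        )
        raster, path = sample_hmm(model, 20_000, seed=4)
        assert np.all(path.path == 0)
        assert np.allclose(raster.data.mean(axis=1), em.marginals, atol=0.02)

    def test_geometric_dwell(self):
        delta = 0.2
        em = random_tree_emission(3, 1)
        model = HMMParams(
            n_modes=2,
            transition=np.array([[1 - delta, delta], [delta, 1 - delta]]),
            initial=np.array([0.5, 0.5]),
            emissions=[em, random_tree_emission(3, 2)],
        )
        _, path = sample_hmm(model, 50_000, seed=8)
        runs = np.diff(np.concatenate([[0], np.nonzero(np.diff(path.path))[0] + 1,
                                       [len(path)]]))
        assert abs(runs.mean() - 1 / delta) < 0.3

    def test_occupancy_matches_stationary(self):
        model = random_hmm(3, 2, seed=9)
        model.transition = np.array([[0.9, 0.2], [0.1, 0.8]])
        _, path = sample_hmm(model, 200_000, seed=10)
        occ = np.bincount(path.path, minlength=2) / len(path)
        w = stationary_weights(model).weights
        assert np.abs(occ - w).max() < 0.02

    def test_bootstrap_closure(self):
        """Refit on data sampled from a fitted model; held-out likelihood of
        the refit is within sampling error of the generator's."""
        truth = make_ground_truth_model(10, 2, separation=1.0,
                                        self_transition=0.8, seed=20)
        raster, _ = sample_hmm(truth, 8_000, seed=21)
        fit = baum_welch_fit(raster, 2, seed=22, n_restarts=2, max_iter=80)
        boot, _ = sample_hmm(fit, 8_000, seed=23)
        refit = baum_welch_fit(boot, 2, seed=24, n_restarts=2, max_iter=80)
        held, _ = sample_hmm(fit, 4_000, seed=25)
        ll_gen = forward_backward(fit, held).loglik / 4_000
        ll_refit = forward_backward(refit, held).loglik / 4_000
        assert abs(ll_gen - ll_refit) < 0.05


class TestSerialization:
    def test_json_roundtrip(self, tmp_path):
        model = random_hmm(4, 3, seed=14)
        model.meta = {"train_loglik": -1.5}
        path = tmp_path / "model.json"
        model.to_json(path)
        back = HMMParams.from_json(path)
        assert back.n_modes == 3
        assert np.allclose(back.transition, model.transition)
        assert np.allclose(back.initial, model.initial)
        for e0, e1 in zip(model.emissions, back.emissions):
            assert np.allclose(e0.marginals, e1.marginals)
            assert e0.edges == e1.edges
            assert np.allclose(e0.edge_joints, e1.edge_joints)
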