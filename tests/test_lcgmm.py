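"""Label-conditional GMM: EM, BIC, joint model-order selection."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.stats import multivariate_normal

from emocat import lcgmm
from emocat.lcgmm import (
    LcGmmModel,
    bic,
    bstar_counts,
    em_fit,
    mixing_proportions,
    select_model_order,
)


def sample_lcgmm(mu, sigma_diag, gamma, labels, seed):
    """Draw scores from a known label-conditional GMM (generative oracle)."""
    rng = np.random.default_rng(seed)
    B, D = mu.shape
    scores = np.empty((len(labels), D))
    clusters = np.empty(len(labels), dtype=int)
    for t, l in enumerate(labels):
        b = rng.choice(B, p=gamma[:, l])
        clusters[t] = b
        scores[t] = rng.normal(mu[b], np.sqrt(sigma_diag))
    return scores, clusters


def two_cluster_scores(seed, n=100, sep=8.0, d=2):
    rng = np.random.default_rng(seed)
    centers = np.zeros((2, d))
    centers[1, 0] = sep
    assign = rng.integers(0, 2, size=n)
    return centers[assign] + rng.normal(size=(n, d)), assign


class TestEmFit:
    def test_single_component_closed_form(self, rng):
        X = rng.normal(size=(50, 3)) * [1.0, 2.0, 0.5]
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        model = em_fit(X, labels, B=1, seed=0)
        assert np.allclose(model.gamma, 1.0)
        assert np.allclose(model.mu[0], X.mean(axis=0), atol=1e-8)
        # closed-form single-Gaussian log-likelihood with ML diagonal variance
        var = X.var(axis=0)
        ll = np.sum(multivariate_normal.logpdf(X, X.mean(axis=0), np.diag(var)))
        assert model.log_likelihood == pytest.approx(ll, abs=1e-6)

    def test_loglik_nondecreasing_every_fit(self, rng):
        for seed in range(5):
            X, _ = two_cluster_scores(seed, sep=3.0)
            labels = np.random.default_rng(seed).integers(0, 3, size=len(X))
            labels[:3] = [0, 1, 2]
            model = em_fit(X, labels, B=3, seed=seed)
            assert np.all(np.diff(model.ll_history) >= -1e-7)

    def test_separated_clusters_label_blind(self):
        # labels assigned independently of cluster -> gamma columns ~ uniform
        X, assign = two_cluster_scores(seed=1, n=2000, sep=10.0)
        labels = np.random.default_rng(2).integers(0, 2, size=2000)
        model = em_fit(X, labels, B=2, seed=0)
        order = np.argsort(model.mu[:, 0])
        truth = np.array([[0.0, 0.0], [10.0, 0.0]])
        assert np.allclose(model.mu[order], truth, atol=0.1)
        assert np.allclose(model.gamma, 0.5, atol=0.1)

    def test_gamma_columns_sum_to_one(self, rng):
        X = rng.normal(size=(60, 2))
        labels = np.tile([0, 1, 2], 20)
        model = em_fit(X, labels, B=3, seed=1)
        assert np.allclose(model.gamma.sum(axis=0), 1.0, atol=1e-8)

    @pytest.mark.parametrize(
        "bad",
        [
            {"B": 0},
            {"B": 60},  # T <= B
            {"labels": np.ones(60, dtype=int)},  # class 0 absent
        ],
    )
    def test_invalid_inputs_rejected(self, rng, bad):
        X = rng.normal(size=(60, 2))
        labels = bad.get("labels", np.tile([0, 1], 30))
        with pytest.raises(ValueError):
            em_fit(X, labels, B=bad.get("B", 2), seed=0)

    def test_gamma_recovery_hungarian(self):
        # known generative gamma, well-separated clusters
        mu = np.array([[0.0, 0.0], [7.0, 0.0], [0.0, 7.0]])
        sigma = np.array([1.0, 1.0])
        gamma = np.array([[0.7, 0.2, 0.1], [0.2, 0.7, 0.2], [0.1, 0.1, 0.7]])
        labels = np.tile([0, 1, 2], 200)
        hits = 0
        for seed in range(20):
            X, _ = sample_lcgmm(mu, sigma, gamma, labels, seed)
            model = em_fit(X, labels, B=3, seed=seed)
            cost = np.linalg.norm(model.mu[:, None] - mu[None], axis=2)
            rows, cols = linear_sum_assignment(cost)
            aligned = np.empty_like(model.gamma)
            aligned[cols] = model.gamma[rows]
            if np.max(np.abs(aligned - gamma)) < 0.1:
                hits += 1
        assert hits >= 18


class TestBic:
    def test_direct_arithmetic(self):
        # p = B*D + D + (B-1)*L = 4 + 2 + 4 = 10 for B=2, D=2, L=4
        model = LcGmmModel(
            B=2, D=2, L=4,
            mu=np.zeros((2, 2)), sigma_diag=np.ones(2),
            gamma=np.full((2, 4), 0.5), log_likelihood=-100.0, n_trials=180,
        )
        assert bic(model) == pytest.approx(200 + 10 * np.log(180), abs=1e-6)

    def test_penalty_monotone_in_b(self):
        def make(B):
            return LcGmmModel(
                B=B, D=3, L=2,
                mu=np.zeros((B, 3)), sigma_diag=np.ones(3),
                gamma=np.full((B, 2), 1.0 / B), log_likelihood=-50.0, n_trials=100,
            )

        assert bic(make(3)) > bic(make(2)) > bic(make(1))

    def test_selects_two_clusters_on_two_cluster_data(self):
        hits = 0
        for seed in range(20):
            X, _ = two_cluster_scores(seed, n=150, sep=8.0)
            labels = np.tile([0, 1, 2], 50)
            bics = [bic(em_fit(X, labels, B=b, seed=seed)) for b in range(1, 5)]
            if int(np.argmin(bics)) + 1 == 2:
                hits += 1
        assert hits >= 18


class TestSelectModelOrder:
    def test_single_pair_grid(self, rng):
        X = rng.normal(size=(40, 5))
        labels = np.tile([0, 1], 20)
        trace, model = select_model_order(X, labels, d_grid=[3], b_grid=[2], seed=0)
        assert trace.selected == (3, 2)
        assert model.D == 3 and model.B == 2

    def test_selected_attains_minimum(self, rng):
        X = rng.normal(size=(60, 6))
        labels = np.tile([0, 1, 2], 20)
        trace, _ = select_model_order(
            X, labels, d_grid=[2, 4], b_grid=[1, 2], n_restarts=3, seed=1
        )
        i = trace.grid.index(trace.selected)
        assert trace.bic_values[i] == trace.bic_values.min()

    def test_bstar_histogram_bookkeeping(self):
        traces = [
            lcgmm.ModelSelectionTrace(grid=[(2, b)], bic_values=np.zeros(1), selected=(2, b))
            for b in [1, 1, 2, 3, 1]
        ]
        assert bstar_counts(traces) == {1: 3, 2: 1, 3: 1}


class TestMixingProportions:
    def test_single_cluster(self):
        model = LcGmmModel(
            B=1, D=2, L=3, mu=np.zeros((1, 2)), sigma_diag=np.ones(2),
            gamma=np.ones((1, 3)), log_likelihood=0.0, n_trials=10,
        )
        assert np.allclose(mixing_proportions(model, np.full(3, 1 / 3)), [1.0])

    def test_marginalisation_identity(self):
        gamma = np.tile(np.array([[0.7], [0.3]]), (1, 4))
        model = LcGmmModel(
            B=2, D=2, L=4, mu=np.zeros((2, 2)), sigma_diag=np.ones(2),
            gamma=gamma, log_likelihood=0.0, n_trials=10,
        )
        pi = mixing_proportions(model, np.full(4, 0.25))
        assert np.allclose(pi, [0.7, 0.3])

    def test_brute_force_trial_average_oracle(self, rng):
        gamma = rng.dirichlet(np.ones(3), size=4).T  # (B=3, L=4)
        model = LcGmmModel(
            B=3, D=2, L=4, mu=np.zeros((3, 2)), sigma_diag=np.ones(2),
            gamma=gamma, log_likelihood=0.0, n_trials=200,
        )
        labels = rng.integers(0, 4, size=200)
        freqs = np.bincount(labels, minlength=4) / 200
        pi = mixing_proportions(model, freqs)
        brute = np.mean([gamma[:, l] for l in labels], axis=0)
        assert np.allclose(pi, brute, atol=1e-10)
        assert pi.sum() == pytest.approx(1.0)

    def test_invalid_frequencies_rejected(self):
        model = LcGmmModel(
            B=1, D=1, L=2, mu=np.zeros((1, 1)), sigma_diag=np.ones(1),
            gamma=np.ones((1, 2)), log_likelihood=0.0, n_trials=5,
        )
        with pytest.raises(ValueError):
            mixing_proportions(model, np.array([0.7, 0.7]))


def test_model_json_round_trip(rng):
    X = rng.normal(size=(30, 2))
    labels = np.tile([0, 1], 15)
    model = em_fit(X, labels, B=2, seed=0)
    clone = LcGmmModel.from_json(model.to_json())
    assert np.allclose(clone.mu, model.mu)
    assert np.allclose(clone.gamma, model.gamma)
    assert clone.score(X, labels) == pytest.approx(model.log_likelihood, abs=1e-8)
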