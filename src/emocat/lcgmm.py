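"""Label-conditional Gaussian mixture model (LC-GMM).

The model clusters trial feature vectors alpha_t into B latent "brain
labels" while conditioning the mixing weights on the observed per-trial
emotion label Lambda_t:

    p(alpha_t | Lambda_t = l) = sum_b gamma_bl N(alpha_t; mu_b, Sigma)

with a diagonal covariance Sigma shared across components and gamma_bl the
probability of latent cluster b given emotion label l (columns of gamma are
distributions). With a single label class (L = 1) the model reduces exactly
to a standard shared-diagonal-covariance GMM.

Parameters are estimated by EM; the number of clusters B and the feature
dimension D (number of retained principal components) are selected jointly
by minimising BIC over a (D, B) grid.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

VARIANCE_FLOOR = 1e-6

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class LcGmmModel:
    """Fitted label-conditional GMM.

    ``gamma`` has shape (B, L); each column sums to 1. ``sigma_diag`` is the
    shared diagonal covariance (floored at ``VARIANCE_FLOOR``).
    """

    B: int
    D: int
    L: int
    mu: np.ndarray  # (B, D)
    sigma_diag: np.ndarray  # (D,)
    gamma: np.ndarray  # (B, L), columns sum to 1
    log_likelihood: float
    n_trials: int
    ll_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True

    def log_density(self, scores: np.ndarray) -> np.ndarray:
        """(T, B) log N(alpha_t; mu_b, Sigma) under the shared diagonal Sigma."""
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        diff = scores[:, None, :] - self.mu[None, :, :]
        quad = np.sum(diff**2 / self.sigma_diag, axis=2)
        log_det = float(np.sum(np.log(self.sigma_diag)))
        return -0.5 * (self.D * _LOG2PI + log_det + quad)

    def responsibilities(self, scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
        """(T, B) posterior probabilities of cluster membership."""
        log_joint = self.log_density(scores) + np.log(self.gamma).T[np.asarray(labels)]
        return np.exp(log_joint - logsumexp(log_joint, axis=1, keepdims=True))

    def score(self, scores: np.ndarray, labels: np.ndarray) -> float:
        """Total log-likelihood of data under the fitted model."""
        log_joint = self.log_density(scores) + np.log(self.gamma).T[np.asarray(labels)]
        return float(np.sum(logsumexp(log_joint, axis=1)))

    def predict(self, scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
        """Hard cluster assignment (argmax responsibility)."""
        return np.argmax(self.responsibilities(scores, labels), axis=1)

    def to_json(self, path=None) -> str:
        payload = {
            "B": self.B,
            "D": self.D,
            "L": self.L,
            "mu": self.mu.tolist(),
            "sigma_diag": self.sigma_diag.tolist(),
            "gamma": self.gamma.tolist(),
            "log_likelihood": self.log_likelihood,
            "n_trials": self.n_trials,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "LcGmmModel":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        return cls(
            B=payload["B"],
            D=payload["D"],
            L=payload["L"],
            mu=np.asarray(payload["mu"], dtype=float),
            sigma_diag=np.asarray(payload["sigma_diag"], dtype=float),
            gamma=np.asarray(payload["gamma"], dtype=float),
            log_likelihood=payload["log_likelihood"],
            n_trials=payload["n_trials"],
        )


@dataclass
class ModelSelectionTrace:
    """Record of a joint (D, B) BIC search."""

    grid: list  # list of (D, B) pairs
    bic_values: np.ndarray
    selected: tuple  # (D*, B*)


def _validate_inputs(scores: np.ndarray, labels: np.ndarray, B: int):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.ndim != 2:
        raise ValueError("scores must be a T x D table")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores contain non-finite values")
    if B <= 0:
        raise ValueError("B must be positive")
    T = scores.shape[0]
    if len(labels) != T:
        raise ValueError("labels length must equal number of trials")
    if T <= B:
        raise ValueError("need more trials than clusters")
    uniq = np.unique(labels)
    if not np.array_equal(uniq, np.arange(len(uniq))):
        raise ValueError("labels must be integers 0..L-1 with every class present")
    return scores, labels.astype(int), len(uniq)


def _single_em_run(scores, labels, onehot, B, L, tol, max_iter, random_state):
    T, D = scores.shape
    # k-means++-style seeding of means; gamma starts uniform
    mu, _ = kmeans_plusplus(scores, n_clusters=B, random_state=random_state)
    sigma = np.maximum(scores.var(axis=0), VARIANCE_FLOOR)
    gamma = np.full((B, L), 1.0 / B)
    counts = onehot.sum(axis=0)  # trials per label
    sum_sq = np.sum(scores**2, axis=0)

    history = []
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        # E-step
        diff = scores[:, None, :] - mu[None, :, :]
        quad = np.sum(diff**2 / sigma, axis=2)
        log_g = -0.5 * (D * _LOG2PI + np.sum(np.log(sigma)) + quad)
        log_joint = log_g + np.log(gamma).T[labels]
        log_norm = logsumexp(log_joint, axis=1, keepdims=True)
        ll = float(np.sum(log_norm))
        history.append(ll)
        resp = np.exp(log_joint - log_norm)

        if ll - prev_ll < tol and np.isfinite(prev_ll):
            converged = True
            break
        prev_ll = ll

        # M-step
        nb = resp.sum(axis=0)
        nb = np.maximum(nb, 1e-12)
        mu = (resp.T @ scores) / nb[:, None]
        sigma = (sum_sq - np.sum(nb[:, None] * mu**2, axis=0)) / T
        sigma = np.maximum(sigma, VARIANCE_FLOOR)
        gamma = (resp.T @ onehot) / counts
        gamma = np.maximum(gamma, 1e-12)
        gamma /= gamma.sum(axis=0, keepdims=True)

    history = np.asarray(history)
    # EM guarantee: the log-likelihood never decreases (beyond round-off)
    if np.any(np.diff(history) < -1e-8 * np.maximum(1.0, np.abs(history[:-1]))):
        raise AssertionError("EM log-likelihood decreased; numerical failure")
    return mu, sigma, gamma, history, converged


def em_fit(
    scores: np.ndarray,
    labels: np.ndarray,
    B: int,
    n_restarts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
) -> LcGmmModel:
    """Fit the LC-GMM by EM, keeping the best of ``n_restarts`` runs.

    Labels are integers 0..L-1 with every class present. Responsibilities
    use the label-specific prior gamma[:, Lambda_t]; the M-step re-estimates
    means, the shared diagonal covariance, and each label's gamma column from
    that label's trials only.
    """
    scores, labels, L = _validate_inputs(scores, labels, B)
    T, D = scores.shape
    onehot = np.zeros((T, L))
    onehot[np.arange(T), labels] = 1.0

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        rs = int(rng.integers(0, 2**31 - 1))
        mu, sigma, gamma, history, converged = _single_em_run(
            scores, labels, onehot, B, L, tol, max_iter, rs
        )
        if best is None or history[-1] > best[3][-1]:
            best = (mu, sigma, gamma, history, converged)

    mu, sigma, gamma, history, converged = best
    return LcGmmModel(
        B=B,
        D=D,
        L=L,
        mu=mu,
        sigma_diag=sigma,
        gamma=gamma,
        log_likelihood=float(history[-1]),
        n_trials=T,
        ll_history=history,
        converged=converged,
    )


def n_parameters(model: LcGmmModel) -> int:
    """Free parameters: B*D means + D shared variances + (B-1)*L mixing."""
    return model.B * model.D + model.D + (model.B - 1) * model.L


def bic(model: LcGmmModel) -> float:
    """Bayesian information criterion: -2 log L + p ln T (lower is better)."""
    return -2.0 * model.log_likelihood + n_parameters(model) * np.log(model.n_trials)


def select_model_order(
    scores_full: np.ndarray,
    labels: np.ndarray,
    d_grid=range(2, 13),
    b_grid=range(1, 7),
    n_restarts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
) -> tuple[ModelSelectionTrace, LcGmmModel]:
    """Joint (D, B) selection by BIC.

    Fits the LC-GMM at every (D, B) pair, using the first D columns of
    ``scores_full`` (assumed ordered by decreasing explained variance, as
    PCA scores are). Ties are broken toward smaller B, then smaller D.
    """
    scores_full = np.asarray(scores_full, dtype=float)
    d_grid = [int(d) for d in d_grid]
    b_grid = [int(b) for b in b_grid]
    if not d_grid or not b_grid:
        raise ValueError("grids must be nonempty")
    if max(d_grid) > scores_full.shape[1]:
        raise ValueError("max(d_grid) exceeds the available score dimension")

    grid, bics, models = [], [], []
    for D in d_grid:
        for B in b_grid:
            model = em_fit(
                scores_full[:, :D], labels, B,
                n_restarts=n_restarts, tol=tol, max_iter=max_iter, seed=seed,
            )
            grid.append((D, B))
            bics.append(bic(model))
            models.append(model)

    order = sorted(range(len(grid)), key=lambda i: (bics[i], grid[i][1], grid[i][0]))
    best_idx = order[0]
    trace = ModelSelectionTrace(
        grid=grid, bic_values=np.asarray(bics), selected=grid[best_idx]
    )
    return trace, models[best_idx]


def mixing_proportions(model: LcGmmModel, label_frequencies: np.ndarray) -> np.ndarray:
    """Label-marginalised prior cluster probabilities pi_k.

    pi_k = sum_l f_l * gamma_kl for a label distribution f. An alternative
    empirical summary (hard-assignment occupancy) is available via
    :func:`cluster_occupancy`.
    """
    f = np.asarray(label_frequencies, dtype=float)
    if f.shape != (model.L,) or np.any(f < 0) or not np.isclose(f.sum(), 1.0):
        raise ValueError("label_frequencies must be a distribution over the L labels")
    return model.gamma @ f


def cluster_occupancy(responsibilities: np.ndarray) -> np.ndarray:
    """Empirical cluster sizes: mean responsibility per cluster."""
    resp = np.asarray(responsibilities, dtype=float)
    return resp.mean(axis=0)


def bstar_counts(traces) -> dict[int, int]:
    """Histogram of selected cluster counts across participants (Fig.-style
    reporting: number of participants whose BIC-selected B* equals each value)."""
    counts: dict[int, int] = {}
    for trace in traces:
        b = trace.selected[1]
        counts[b] = counts.get(b, 0) + 1
    return dict(sorted(counts.items()))
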