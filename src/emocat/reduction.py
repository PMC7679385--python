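"""Principal-component feature extraction and parallel analysis.

PCA compresses trial-wise voxel maps into the low-dimensional trial scores
that the mixture models consume; parallel analysis gives a permutation-null
criterion for how many components carry systematic variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA


@dataclass
class PcaModel:
    """Fitted PCA basis.

    ``components`` rows are orthonormal; ``eigenvalues`` are the variances of
    the score columns, sorted nonincreasing. ``d_max`` is the largest
    dimension retained for downstream model-order searches.
    """

    mean_vector: np.ndarray  # (n_features,)
    components: np.ndarray  # (d_max, n_features), orthonormal rows
    eigenvalues: np.ndarray  # (d_max,), nonincreasing
    d_max: int

    def project(self, data: np.ndarray) -> np.ndarray:
        """Centered projection of samples x features data onto the basis."""
        data = np.asarray(data, dtype=float)
        return (data - self.mean_vector) @ self.components.T

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        """Map scores back to the (centered, then un-centered) feature space."""
        return np.asarray(scores, dtype=float) @ self.components + self.mean_vector


def _as_table(data) -> np.ndarray:
    if hasattr(data, "flattened"):  # TrialVolumeSet
        return data.flattened()
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a trials x features table, got shape {arr.shape}")
    return arr


def fit_project_pca(data, d_max: int) -> tuple[PcaModel, np.ndarray]:
    """Fit PCA on a trial table (or TrialVolumeSet) and return trial scores.

    Scores are centered projections; truncating them to any D <= d_max gives
    the best rank-D linear reconstruction of the centered data in squared
    error. Constant (zero-variance) input raises ``ValueError``.
    """
    table = _as_table(data)
    n, p = table.shape
    if n < 2:
        raise ValueError("need at least 2 trials for PCA")
    if d_max < 1 or d_max > min(n - 1, p):
        raise ValueError(f"d_max must be in [1, min(n_trials - 1, n_features)] = [1, {min(n - 1, p)}]")
    if np.allclose(table.var(axis=0), 0.0):
        raise ValueError("degenerate input: data has zero variance")

    pca = PCA(n_components=d_max, svd_solver="full")
    scores = pca.fit_transform(table)
    model = PcaModel(
        mean_vector=pca.mean_,
        components=pca.components_,
        eigenvalues=pca.explained_variance_,
        d_max=d_max,
    )
    return model, scores


def save_scores_tsv(scores: np.ndarray, path, trial_ids=None) -> None:
    """Write a trial x component score table as TSV with a trial_id column."""
    import pandas as pd

    scores = np.asarray(scores, dtype=float)
    if trial_ids is None:
        trial_ids = np.arange(scores.shape[0])
    table = pd.DataFrame(scores, columns=[f"pc{k + 1}" for k in range(scores.shape[1])])
    table.insert(0, "trial_id", trial_ids)
    table.to_csv(path, sep="\t", index=False)


def parallel_analysis(
    table: np.ndarray,
    n_draws: int = 500,
    quantile: float = 0.95,
    seed: int = 0,
) -> int:
    """Number of principal components exceeding a permutation null.

    Surrogates permute each column independently (destroying between-feature
    covariance while keeping marginals). The retained count is the number of
    *leading* observed eigenvalues strictly exceeding the pointwise
    ``quantile`` of the surrogate eigenvalue distribution of the same rank.
    """
    table = np.asarray(table, dtype=float)
    n, p = table.shape
    if p < 3:
        raise ValueError("parallel analysis needs at least 3 features")
    if n_draws < 100:
        raise ValueError("n_draws must be at least 100")
    rng = np.random.default_rng(seed)

    def _eigs(x):
        cov = np.cov(x, rowvar=False)
        return np.sort(np.linalg.eigvalsh(cov))[::-1]

    observed = _eigs(table)
    surrogate = np.empty((n_draws, p))
    for d in range(n_draws):
        shuffled = np.column_stack([rng.permutation(table[:, j]) for j in range(p)])
        surrogate[d] = _eigs(shuffled)
    threshold = np.quantile(surrogate, quantile, axis=0)

    retained = 0
    for k in range(p):
        if observed[k] > threshold[k]:
            retained += 1
        else:
            break
    return retained
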