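"""Synthetic generators for the three emotion-data modalities.

Three generators produce data with the statistical structure the downstream
analyses assume:

* :func:`generate_bold` — trial-wise 3D "beta maps": each emotion category is
  a weighted sum of isotropic Gaussian radial basis functions (RBFs) placed at
  random locations, with per-trial amplitude jitter and additive zero-mean
  Gaussian noise scaled to a requested signal-to-noise ratio (SNR, defined as
  signal variance over noise variance pooled across all voxels and trials).
* :func:`generate_ans_events` — six-feature cardiovascular change-score
  vectors drawn from a Gaussian mixture, with free-text emotion labels emitted
  through a many-to-many cluster-to-label channel and uniform valence/arousal
  ratings on a 100-point bipolar scale.
* :func:`generate_rating_corpus` — per-clip mean emotion-category ratings
  (yes/no means in [0, 1]) and mean affect ratings (Likert means in [1, 9])
  organised around latent topics.

Every generator records its generative truth (latent assignments, noiseless
signal, noise realisation) so recovery can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANS_FEATURES = ("IBI", "RSA", "PEP", "LVET", "SV", "CO")

VALENCE_AROUSAL_RANGE = (-50.0, 50.0)


# ---------------------------------------------------------------------------
# BOLD beta-map generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoldGeneratorConfig:
    """Configuration of the RBF beta-map generator.

    Parameters
    ----------
    grid_shape
        Voxel grid dimensions; every dimension must be >= 2.
    n_categories
        Number of emotion categories L.
    trials_per_category
        Trials generated per category (total T = L * trials_per_category).
    regions_per_category
        Number of RBF "active regions" per category.
    rbf_width_range
        Uniform sampling interval for RBF widths, in voxel units.
    weight_range
        Uniform sampling interval for per-trial, per-region amplitudes.
    snr
        Target dataset-level signal variance / noise variance; ``math.inf``
        requests noiseless data.
    n_runs
        Number of scanning runs; trials are assigned round-robin within each
        category so every run is label-balanced.
    seed
        Seed of the generator's private random stream.
    """

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    n_categories: int = 3
    trials_per_category: int = 60
    regions_per_category: int = 5
    rbf_width_range: tuple[float, float] = (2.0, 6.0)
    weight_range: tuple[float, float] = (0.5, 1.5)
    snr: float = 10.0
    n_runs: int = 6
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(g) < 2 for g in self.grid_shape):
            raise ValueError(f"degenerate grid {self.grid_shape}: every dimension must be >= 2")
        if self.n_categories < 1 or self.trials_per_category < 1:
            raise ValueError("n_categories and trials_per_category must be positive")
        if self.regions_per_category < 1:
            raise ValueError("regions_per_category must be positive")
        if not (self.snr > 0):
            raise ValueError(f"snr must be positive (or math.inf), got {self.snr}")
        for name, (lo, hi) in (
            ("rbf_width_range", self.rbf_width_range),
            ("weight_range", self.weight_range),
        ):
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a nonempty positive interval, got ({lo}, {hi})")
        if (self.trials_per_category * self.n_categories) % self.n_runs:
            raise ValueError("total trial count must be divisible by n_runs")


@dataclass
class BoldTruth:
    """Generative record of a synthetic beta-map dataset."""

    centers: np.ndarray  # (L, R, 3) RBF centers, voxel coords
    widths: np.ndarray  # (L, R) RBF widths
    weights: np.ndarray  # (T, R) per-trial region amplitudes
    noise_sd: float
    signal: np.ndarray  # (T, *grid) noiseless signal
    noise: np.ndarray  # (T, *grid) realised noise


@dataclass
class TrialVolumeSet:
    """Trial-indexed 3D beta maps with per-trial emotion labels and run ids."""

    volumes: np.ndarray  # (T, *grid_shape)
    labels: np.ndarray  # (T,) category index in 0..L-1
    run_ids: np.ndarray  # (T,) run index in 0..n_runs-1
    truth: BoldTruth | None = None

    def __post_init__(self) -> None:
        n = self.volumes.shape[0]
        if len(self.labels) != n or len(self.run_ids) != n:
            raise ValueError("labels and run_ids must have one entry per trial")

    @property
    def n_trials(self) -> int:
        return self.volumes.shape[0]

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.volumes.shape[1:]

    def flattened(self) -> np.ndarray:
        """Trials x voxels view of the volumes."""
        return self.volumes.reshape(self.n_trials, -1)

    def sidecar(self) -> pd.DataFrame:
        """Trial table (trial_id, label, run_id) matching the volume order."""
        return pd.DataFrame(
            {
                "trial_id": np.arange(self.n_trials),
                "label": self.labels,
                "run_id": self.run_ids,
            }
        )

    def save(self, directory, write_nifti: bool = False) -> None:
        """Write volumes (.npy) plus a TSV sidecar; optionally NIfTI per trial."""
        from pathlib import Path

        out = Path(directory)
        out.mkdir(parents=True, exist_ok=True)
        np.save(out / "volumes.npy", self.volumes)
        self.sidecar().to_csv(out / "trials.tsv", sep="\t", index=False)
        if write_nifti:
            import nibabel as nib

            for t in range(self.n_trials):
                img = nib.Nifti1Image(self.volumes[t].astype(np.float32), affine=np.eye(4))
                nib.save(img, out / f"trial_{t:04d}.nii")


def _rbf_image(grid_shape, center, width) -> np.ndarray:
    axes = np.ogrid[tuple(slice(0, g) for g in grid_shape)]
    sq = sum((ax - c) ** 2 for ax, c in zip(axes, center))
    return np.exp(-sq / (2.0 * width**2))


def generate_bold(config: BoldGeneratorConfig) -> TrialVolumeSet:
    """Simulate trial-wise beta maps with category-specific RBF patterns.

    Each category owns ``regions_per_category`` RBFs with centers uniform over
    the grid and widths uniform in ``rbf_width_range``. A trial's noiseless
    map is the sum of its category's RBF images, each scaled by an amplitude
    drawn uniformly from ``weight_range`` (fresh per trial). Zero-mean
    Gaussian noise is added last, its standard deviation set so that the
    pooled variance ratio signal/noise equals ``config.snr``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L, R = config.n_categories, config.regions_per_category
    grid = tuple(int(g) for g in config.grid_shape)
    T = L * config.trials_per_category

    centers = rng.uniform(low=0.0, high=np.array(grid, dtype=float) - 1.0, size=(L, R, 3))
    widths = rng.uniform(*config.rbf_width_range, size=(L, R))
    basis = np.empty((L, R) + grid)
    for l in range(L):
        for r in range(R):
            basis[l, r] = _rbf_image(grid, centers[l, r], widths[l, r])

    labels = np.repeat(np.arange(L), config.trials_per_category)
    run_ids = np.tile(
        np.arange(config.trials_per_category) % config.n_runs, L
    )
    weights = rng.uniform(*config.weight_range, size=(T, R))
    # (T, R) @ (R, voxels) per category
    signal = np.empty((T,) + grid)
    for l in range(L):
        mask = labels == l
        signal[mask] = np.tensordot(weights[mask], basis[l], axes=(1, 0))

    sig_var = float(np.var(signal))
    if math.isinf(config.snr):
        noise_sd = 0.0
        noise = np.zeros_like(signal)
    else:
        noise_sd = math.sqrt(sig_var / config.snr) if sig_var > 0 else 0.0
        noise = rng.normal(scale=noise_sd, size=signal.shape) if noise_sd > 0 else np.zeros_like(signal)

    truth = BoldTruth(
        centers=centers,
        widths=widths,
        weights=weights,
        noise_sd=noise_sd,
        signal=signal,
        noise=noise,
    )
    return TrialVolumeSet(volumes=signal + noise, labels=labels, run_ids=run_ids, truth=truth)


def empirical_snr(data: TrialVolumeSet) -> float:
    """Realised signal-variance / noise-variance of a generated dataset.

    Returns ``math.inf`` when the realised noise variance is zero; requires
    the generative truth record.
    """
    if data.truth is None:
        raise ValueError("empirical_snr requires the generative truth record")
    noise_var = float(np.var(data.truth.noise))
    sig_var = float(np.var(data.truth.signal))
    if noise_var == 0.0:
        return math.inf
    return sig_var / noise_var


# ---------------------------------------------------------------------------
# Autonomic (cardiovascular) event generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnsGeneratorConfig:
    """Gaussian-mixture generator of six-feature cardiovascular event vectors.

    Events are drawn from ``n_clusters`` equiprobable Gaussian components in
    the six-dimensional change-score space (IBI, RSA, PEP, LVET, SV, CO); the
    free-text emotion label of each event is drawn from the row of
    ``label_given_cluster`` for its latent component, giving the many-to-many
    label-to-physiology mapping seen in free-labelled experience sampling.
    """

    n_events: int
    n_clusters: int
    cluster_means: np.ndarray  # (K, 6)
    cluster_covariances: np.ndarray  # (K, 6, 6)
    label_vocabulary: tuple[str, ...]
    label_given_cluster: np.ndarray  # (K, V) row-stochastic
    seed: int = 0

    def validate(self) -> None:
        K = self.n_clusters
        means = np.asarray(self.cluster_means, dtype=float)
        covs = np.asarray(self.cluster_covariances, dtype=float)
        P = np.asarray(self.label_given_cluster, dtype=float)
        if means.shape != (K, 6):
            raise ValueError(f"cluster_means must be ({K}, 6), got {means.shape}")
        if covs.shape != (K, 6, 6):
            raise ValueError(f"cluster_covariances must be ({K}, 6, 6), got {covs.shape}")
        for k in range(K):
            if not np.allclose(covs[k], covs[k].T):
                raise ValueError(f"covariance {k} is not symmetric")
            if np.min(np.linalg.eigvalsh(covs[k])) < -1e-10:
                raise ValueError(f"covariance {k} is not positive semi-definite")
        if P.shape != (K, len(self.label_vocabulary)):
            raise ValueError("label_given_cluster shape mismatch with vocabulary")
        if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0):
            raise ValueError("label_given_cluster rows must be distributions")

    @classmethod
    def well_separated(
        cls,
        n_clusters: int,
        n_events: int,
        separation: float = 8.0,
        labels_per_cluster: int = 2,
        seed: int = 0,
    ) -> "AnsGeneratorConfig":
        """Convenience builder: spherical unit-variance clusters at pairwise
        distance ~``separation``, each emitting ``labels_per_cluster`` labels."""
        rng = np.random.default_rng(seed)
        means = np.zeros((n_clusters, 6))
        # place cluster means on scaled random orthogonal-ish directions
        raw = rng.normal(size=(n_clusters, 6))
        q, _ = np.linalg.qr(raw.T)
        means = q.T[:n_clusters] * separation
        covs = np.tile(np.eye(6), (n_clusters, 1, 1))
        vocab = tuple(f"emotion_{i}" for i in range(n_clusters * labels_per_cluster))
        P = np.zeros((n_clusters, len(vocab)))
        for k in range(n_clusters):
            P[k, k * labels_per_cluster : (k + 1) * labels_per_cluster] = 1.0 / labels_per_cluster
        return cls(
            n_events=n_events,
            n_clusters=n_clusters,
            cluster_means=means,
            cluster_covariances=covs,
            label_vocabulary=vocab,
            label_given_cluster=P,
            seed=seed,
        )


@dataclass
class EventFeatureTable:
    """Per-event cardiovascular change scores with labels and affect ratings."""

    table: pd.DataFrame  # columns: event_id, *ANS_FEATURES, label, valence, arousal
    truth_clusters: np.ndarray | None = None

    @property
    def n_events(self) -> int:
        return len(self.table)

    def features(self) -> np.ndarray:
        """Events x 6 matrix of change scores."""
        return self.table.loc[:, list(ANS_FEATURES)].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EventFeatureTable":
        return cls(table=pd.read_csv(path, sep="\t"))


def generate_ans_events(config: AnsGeneratorConfig) -> EventFeatureTable:
    """Draw events from the configured Gaussian mixture with labelled output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    K = config.n_clusters
    means = np.asarray(config.cluster_means, dtype=float)
    covs = np.asarray(config.cluster_covariances, dtype=float)
    P = np.asarray(config.label_given_cluster, dtype=float)

    clusters = rng.integers(0, K, size=config.n_events)
    X = np.empty((config.n_events, 6))
    for k in range(K):
        mask = clusters == k
        if mask.any():
            X[mask] = rng.multivariate_normal(
                means[k], covs[k], size=int(mask.sum()), method="svd"
            )
    vocab = np.asarray(config.label_vocabulary, dtype=object)
    labels = np.array(
        [vocab[rng.choice(len(vocab), p=P[k])] for k in clusters], dtype=object
    )
    lo, hi = VALENCE_AROUSAL_RANGE
    valence = rng.uniform(lo, hi, size=config.n_events)
    arousal = rng.uniform(lo, hi, size=config.n_events)

    table = pd.DataFrame(X, columns=list(ANS_FEATURES))
    table.insert(0, "event_id", np.arange(config.n_events))
    table["label"] = labels
    table["valence"] = valence
    table["arousal"] = arousal
    return EventFeatureTable(table=table, truth_clusters=clusters)


# ---------------------------------------------------------------------------
# Movie-clip rating corpus generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RatingsGeneratorConfig:
    """Topic-structured generator of mean clip ratings.

    Each clip is assigned one latent topic. Its mean yes/no category ratings
    are the topic's category profile plus Gaussian noise, clipped to [0, 1];
    its mean affect ratings are the topic's affect centroid plus noise,
    clipped to the nine-point Likert range [1, 9].
    """

    n_clips: int
    n_topics: int
    topic_category_profiles: np.ndarray  # (n_topics, n_categories) in [0, 1]
    affect_cluster_means: np.ndarray  # (n_topics, n_affect_dims) in [1, 9]
    n_categories: int = 34
    n_affect_dims: int = 14
    raters_per_clip: int = 9
    noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        profiles = np.asarray(self.topic_category_profiles, dtype=float)
        affect = np.asarray(self.affect_cluster_means, dtype=float)
        if profiles.shape != (self.n_topics, self.n_categories):
            raise ValueError("topic_category_profiles shape mismatch")
        if np.any(profiles < 0) or np.any(profiles > 1):
            raise ValueError("topic_category_profiles must lie in [0, 1]")
        if affect.shape != (self.n_topics, self.n_affect_dims):
            raise ValueError("affect_cluster_means shape mismatch")
        if np.any(affect < 1) or np.any(affect > 9):
            raise ValueError("affect_cluster_means must lie in [1, 9]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_clips < 1 or self.raters_per_clip < 1:
            raise ValueError("n_clips and raters_per_clip must be positive")


@dataclass
class RatingsMatrices:
    """Per-clip mean binary category ratings and mean Likert affect ratings."""

    category_means: pd.DataFrame  # clips x n_categories, values in [0, 1]
    affect_means: pd.DataFrame  # clips x n_affect_dims, values in [1, 9]
    raters_per_clip: np.ndarray
    truth_topics: np.ndarray | None = None

    @property
    def n_clips(self) -> int:
        return len(self.category_means)


def random_topic_profiles(
    n_topics: int,
    n_categories: int = 34,
    active_per_topic: int = 4,
    high: float = 0.8,
    low: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Sparse topic-category profiles: each topic strongly endorses a few
    disjoint (cyclically allocated) categories and barely endorses the rest."""
    rng = np.random.default_rng(seed)
    profiles = np.full((n_topics, n_categories), low)
    order = rng.permutation(n_categories)
    for t in range(n_topics):
        active = order[(t * active_per_topic) % n_categories :][:active_per_topic]
        profiles[t, active] = high
    return profiles


def generate_rating_corpus(config: RatingsGeneratorConfig) -> RatingsMatrices:
    """Simulate a clips x categories mean-rating matrix and a clips x affect
    mean matrix sharing one latent topic per clip."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    profiles = np.asarray(config.topic_category_profiles, dtype=float)
    affect = np.asarray(config.affect_cluster_means, dtype=float)

    topics = rng.integers(0, config.n_topics, size=config.n_clips)
    cat = profiles[topics] + rng.normal(scale=config.noise_sd, size=(config.n_clips, config.n_categories))
    cat = np.clip(cat, 0.0, 1.0)
    aff = affect[topics] + rng.normal(
        scale=config.noise_sd, size=(config.n_clips, config.n_affect_dims)
    )
    aff = np.clip(aff, 1.0, 9.0)

    cat_df = pd.DataFrame(cat, columns=[f"category_{j}" for j in range(config.n_categories)])
    aff_df = pd.DataFrame(aff, columns=[f"affect_{j}" for j in range(config.n_affect_dims)])
    raters = np.full(config.n_clips, config.raters_per_clip, dtype=int)
    return RatingsMatrices(
        category_means=cat_df,
        affect_means=aff_df,
        raters_per_clip=raters,
        truth_topics=topics,
    )
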