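"""LDA topic modelling of binary emotion-category ratings.

Mean yes/no ratings are discretised into pseudo-token counts (mean rating
times number of raters, rounded), a latent Dirichlet allocation model is fit
over a grid of topic counts, and held-out perplexity — exp(-loglik/tokens)
on left-out clips — is scanned for a clear interior minimum. Absence of such
a minimum is itself an outcome: the categories cannot be reduced to a
smaller set of separable topics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import LatentDirichletAllocation
from sklearn.model_selection import KFold

DEFAULT_TOPIC_WORD_PRIOR = 0.1
DEFAULT_REL_IMPROVEMENT = 0.05


@dataclass
class CountCorpus:
    """Clips x categories pseudo-token counts with per-clip rater counts."""

    counts: np.ndarray  # (n_clips, n_categories), nonnegative ints
    raters_per_clip: np.ndarray  # (n_clips,)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        raters = np.asarray(self.raters_per_clip)
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(counts > raters[:, None]):
            raise ValueError("counts cannot exceed the number of raters")
        if not np.any(counts.sum(axis=1) > 0):
            raise ValueError("corpus must contain at least one nonzero row")
        self.counts = counts.astype(int)
        self.raters_per_clip = raters.astype(int)

    @property
    def n_clips(self) -> int:
        return self.counts.shape[0]

    @property
    def n_categories(self) -> int:
        return self.counts.shape[1]


@dataclass
class PerplexityCurve:
    """Held-out perplexity per candidate topic count."""

    topic_grid: np.ndarray
    perplexity: np.ndarray
    minimum: int | None = None

    def __post_init__(self) -> None:
        self.topic_grid = np.asarray(self.topic_grid, dtype=int)
        self.perplexity = np.asarray(self.perplexity, dtype=float)
        if len(self.topic_grid) != len(self.perplexity):
            raise ValueError("grid and perplexity values must have equal length")


def ratings_to_corpus(mean_ratings, raters_per_clip) -> CountCorpus:
    """Discretise mean yes/no ratings into counts: round(mean * raters)."""
    ratings = np.asarray(mean_ratings, dtype=float)
    if hasattr(mean_ratings, "to_numpy"):
        ratings = mean_ratings.to_numpy(dtype=float)
    if np.any(ratings < 0) or np.any(ratings > 1):
        raise ValueError("mean ratings must lie in [0, 1]")
    raters = np.asarray(raters_per_clip, dtype=int)
    if raters.ndim == 0:
        raters = np.full(ratings.shape[0], int(raters))
    counts = np.rint(ratings * raters[:, None]).astype(int)
    return CountCorpus(counts=counts, raters_per_clip=raters)


def heldout_perplexity(
    lda: LatentDirichletAllocation, heldout_counts: np.ndarray
) -> tuple[float, float]:
    """(log-likelihood, token count) of held-out clips under a fitted model.

    Uses the posterior-mean document-topic proportions theta from
    ``lda.transform`` and the normalised topic-category distributions phi;
    per-token log-likelihood is log(theta @ phi). Rows without tokens are
    skipped with a warning.
    """
    counts = np.asarray(heldout_counts, dtype=float)
    nonzero = counts.sum(axis=1) > 0
    if not np.all(nonzero):
        warnings.warn("skipping empty held-out clips", stacklevel=2)
        counts = counts[nonzero]
    phi = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    theta = lda.transform(counts)
    probs = theta @ phi
    loglik = float(np.sum(counts * np.log(probs)))
    return loglik, float(counts.sum())


def fit_lda_perplexity_scan(
    corpus: CountCorpus,
    topic_grid=range(1, 11),
    n_folds: int = 5,
    seed: int = 0,
    topic_word_prior: float = DEFAULT_TOPIC_WORD_PRIOR,
    max_iter: int = 100,
    rel_improvement: float = DEFAULT_REL_IMPROVEMENT,
    folds=None,
    n_restarts: int = 5,
) -> PerplexityCurve:
    """Scan topic counts, scoring each by pooled held-out perplexity.

    Clips are split into ``n_folds`` folds (seeded, by clip). For each K an
    LDA with a sparse symmetric document-topic prior (alpha = 1/K) and
    topic-category prior ``topic_word_prior`` is fit on the held-in clips —
    ``n_restarts`` random initialisations, keeping the restart with the best
    training-set variational bound (batch variational LDA is prone to local
    optima, which otherwise masks the true minimum of the curve). Held-out
    log-likelihood and token counts are pooled across folds and
    perplexity(K) = exp(-pooled loglik / pooled tokens).
    """
    topic_grid = [int(k) for k in topic_grid]
    if min(topic_grid) < 1 or max(topic_grid) > corpus.n_categories:
        raise ValueError("topic_grid must lie within [1, n_categories]")
    if folds is None:
        if n_folds < 2 or n_folds > corpus.n_clips:
            raise ValueError("n_folds must be in [2, n_clips]")
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = list(splitter.split(np.arange(corpus.n_clips)))

    perplexities = []
    for K in topic_grid:
        total_ll, total_tokens = 0.0, 0.0
        for fold_idx, (train, test) in enumerate(folds):
            best, best_bound = None, -np.inf
            for restart in range(max(1, n_restarts)):
                lda = LatentDirichletAllocation(
                    n_components=K,
                    doc_topic_prior=1.0 / K,
                    topic_word_prior=topic_word_prior,
                    learning_method="batch",
                    max_iter=max_iter,
                    random_state=seed * 1000 + fold_idx * 17 + restart,
                )
                lda.fit(corpus.counts[train])
                bound = lda.score(corpus.counts[train])
                if bound > best_bound:
                    best, best_bound = lda, bound
            ll, tokens = heldout_perplexity(best, corpus.counts[test])
            total_ll += ll
            total_tokens += tokens
        perplexities.append(float(np.exp(-total_ll / total_tokens)))

    curve = PerplexityCurve(topic_grid=np.asarray(topic_grid), perplexity=np.asarray(perplexities))
    curve.minimum = detect_topic_minimum(curve, rel_improvement)
    return curve


def detect_topic_minimum(
    curve: PerplexityCurve, rel_improvement: float = DEFAULT_REL_IMPROVEMENT
) -> int | None:
    """Topic count at a *clear* perplexity minimum, else ``None``.

    The minimum must be interior (not the first or last grid point), must be
    a local minimum, must improve on the first grid value by more than
    ``rel_improvement`` (relative), and must lie strictly below the last
    grid value. Monotone or flat curves therefore yield ``None`` — the
    "no clear minimum" outcome.
    """
    if len(curve.topic_grid) == 0:
        raise ValueError("empty curve")
    if len(curve.topic_grid) < 3:
        return None
    p = curve.perplexity
    i = int(np.argmin(p))
    if i == 0 or i == len(p) - 1:
        return None
    if not (p[i] < p[i - 1] and p[i] <= p[i + 1]):
        return None
    if not (p[i] < (1.0 - rel_improvement) * p[0] and p[i] < p[-1]):
        return None
    return int(curve.topic_grid[i])
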