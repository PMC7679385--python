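"""Supervised baselines and their statistical evaluation.

Fold construction (leave-one-run-out or k-fold), minority oversampling,
cross-validated classification with either a volumetric (3D conv) or
feed-forward network, an imbalance-preserving permutation null, and
one-sample t-tests against chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from emocat import _nets


@dataclass
class FoldSpec:
    """A disjoint, exhaustive partition of samples into test folds."""

    scheme: str  # "leave-one-run-out" | "k-fold"
    k: int
    assignments: np.ndarray  # (n_samples,) fold index in 0..k-1

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)
        present = np.unique(self.assignments)
        if not np.array_equal(present, np.arange(self.k)):
            raise ValueError("fold assignments must cover 0..k-1")

    def split(self):
        """Yield (train_indices, test_indices) per fold."""
        idx = np.arange(len(self.assignments))
        for f in range(self.k):
            test = idx[self.assignments == f]
            train = idx[self.assignments != f]
            yield train, test


@dataclass
class AccuracyResult:
    per_fold_accuracy: np.ndarray
    mean_accuracy: float
    chance_level: float | None = None
    per_unit: dict | None = None


@dataclass
class PermutationNull:
    n_permutations: int
    null_means: np.ndarray
    observed: float
    tail_p: float


@dataclass(frozen=True)
class ClassifierConfig:
    """Architecture/training settings for the two classifier contracts.

    ``model`` is "feed-forward" (two ReLU hidden layers + dropout on vector
    features) or "volumetric-conv" (two 3x3x3 conv blocks with max pooling,
    dropout on the input volume and flattened features, for 3D arrays).
    """

    model: str = "feed-forward"
    hidden: tuple[int, ...] = (64, 32)
    channels: tuple[int, int] = (8, 16)
    dropout: float = 0.25
    conv_dropout: float = 0.5
    input_dropout: float = 0.2
    max_epochs: int = 60
    batch_size: int = 32
    lr: float = 3e-3
    seed: int = 0

    def validate(self) -> None:
        if self.model not in ("feed-forward", "volumetric-conv"):
            raise ValueError(f"unknown model {self.model!r}")


def build_folds(
    labels,
    run_ids=None,
    scheme: str = "k-fold",
    k: int = 5,
    seed: int = 0,
) -> FoldSpec:
    """Construct cross-validation folds.

    ``leave-one-run-out`` makes one fold per distinct run id. ``k-fold``
    deals samples to folds round-robin within a label-stratified seeded
    shuffle, so fold sizes differ by at most one and labels spread evenly.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if scheme == "leave-one-run-out":
        if run_ids is None:
            raise ValueError("leave-one-run-out requires run_ids")
        run_ids = np.asarray(run_ids)
        runs = np.unique(run_ids)
        mapping = {r: i for i, r in enumerate(runs)}
        assignments = np.array([mapping[r] for r in run_ids])
        return FoldSpec(scheme=scheme, k=len(runs), assignments=assignments)
    if scheme != "k-fold":
        raise ValueError(f"unknown scheme {scheme!r}")
    if k > n:
        raise ValueError("k cannot exceed the number of samples")
    rng = np.random.default_rng(seed)
    order = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        order.extend(rng.permutation(idx))
    assignments = np.empty(n, dtype=int)
    for pos, sample in enumerate(order):
        assignments[sample] = pos % k
    return FoldSpec(scheme="k-fold", k=k, assignments=assignments)


def oversample_minority(train_indices, labels, seed: int = 0) -> np.ndarray:
    """Expand a training index list so every class matches the majority count.

    Sampling is with replacement from each minority class's own training
    indices; the originals are always kept. Indices outside the training
    split are never touched.
    """
    train_indices = np.asarray(train_indices)
    labels = np.asarray(labels)
    y = labels[train_indices]
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes in the training split")
    majority = counts.max()
    rng = np.random.default_rng(seed)
    out = [train_indices]
    for cls, cnt in zip(classes, counts):
        if cnt < majority:
            pool = train_indices[y == cls]
            out.append(rng.choice(pool, size=majority - cnt, replace=True))
    return np.concatenate(out)


def _standardize(train, test):
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (train - mean) / sd, (test - mean) / sd


def _fit_predict_fold(X, y_enc, n_classes, train, test, config, fold_rng, perm_rng=None):
    y_train = y_enc[train]
    if perm_rng is not None:  # permutation null: shuffle TRAINING labels only
        y_train = perm_rng.permutation(y_train)
    if not set(np.unique(y_enc[test])) <= set(np.unique(y_train)):
        raise ValueError("label unseen in training split")
    onehot = np.zeros((len(train), n_classes))
    onehot[np.arange(len(train)), y_train] = 1.0

    if config.model == "volumetric-conv":
        Xtr, Xte = X[train], X[test]
        mean, sd = Xtr.mean(), Xtr.std() or 1.0
        Xtr = ((Xtr - mean) / sd)[:, None]  # add channel axis
        Xte = ((Xte - mean) / sd)[:, None]
        net = _nets.volumetric_net(
            X.shape[1:],
            n_classes,
            fold_rng,
            channels=config.channels,
            input_dropout=config.input_dropout,
            dropout=config.conv_dropout,
        )
    else:
        Xtr, Xte = _standardize(X[train], X[test])
        net = _nets.feed_forward_net(
            X.shape[1], n_classes, fold_rng, hidden=config.hidden, dropout=config.dropout
        )
    net.fit(
        Xtr,
        onehot,
        max_epochs=config.max_epochs,
        batch_size=config.batch_size,
        lr=config.lr,
    )
    return net.predict(Xte)


def crossval_classifier(
    features,
    labels,
    folds: FoldSpec,
    model_config: ClassifierConfig = ClassifierConfig(),
    oversample: bool = False,
    _perm_rng=None,
) -> AccuracyResult:
    """Cross-validated classification accuracy.

    Trains a fresh network per fold on the training split only (optionally
    minority-oversampled) and reports per-fold test accuracy plus their
    mean. Deterministic for a fixed ``model_config.seed``.
    """
    model_config.validate()
    X = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    labels = np.asarray(labels)
    classes = np.unique(labels)
    class_index = {c: i for i, c in enumerate(classes)}
    y_enc = np.array([class_index[c] for c in labels])

    accs = []
    for fold, (train, test) in enumerate(folds.split()):
        if oversample:
            train = oversample_minority(train, labels, seed=model_config.seed * 997 + fold)
        fold_rng = np.random.default_rng(
            np.random.SeedSequence([model_config.seed, fold])
        )
        pred = _fit_predict_fold(
            X, y_enc, len(classes), train, test, model_config, fold_rng, _perm_rng
        )
        accs.append(float(np.mean(pred == y_enc[test])))
    accs = np.asarray(accs)
    return AccuracyResult(
        per_fold_accuracy=accs,
        mean_accuracy=float(accs.mean()),
        chance_level=1.0 / len(classes),
    )


def permutation_null(
    features,
    labels,
    folds,
    model_config: ClassifierConfig = ClassifierConfig(),
    n_permutations: int = 1000,
    seed: int = 0,
    oversample: bool = False,
) -> PermutationNull:
    """Group permutation test preserving per-unit label imbalance.

    ``features``/``labels``/``folds`` may be single-unit inputs or lists
    (one entry per participant/unit). The observed statistic is the mean
    over units of each unit's cross-validated mean accuracy. Each
    permutation shuffles every unit's *training* labels within each fold and
    averages the resulting unit accuracies into one null mean; the tail
    probability is (1 + #{null >= observed}) / (n_permutations + 1).
    """
    if not isinstance(features, (list, tuple)):
        features, labels, folds = [features], [labels], [folds]
    units = list(zip(features, labels, folds))

    observed = float(
        np.mean(
            [
                crossval_classifier(X, y, f, model_config, oversample=oversample).mean_accuracy
                for X, y, f in units
            ]
        )
    )
    rng = np.random.default_rng(seed)
    null_means = np.empty(n_permutations)
    for p in range(n_permutations):
        unit_accs = [
            crossval_classifier(
                X, y, f, model_config, oversample=oversample, _perm_rng=rng
            ).mean_accuracy
            for X, y, f in units
        ]
        null_means[p] = np.mean(unit_accs)
    tail_p = (1.0 + np.sum(null_means >= observed)) / (n_permutations + 1.0)
    return PermutationNull(
        n_permutations=n_permutations,
        null_means=null_means,
        observed=observed,
        tail_p=float(tail_p),
    )


def t_test_vs_chance(unit_accuracies, chance: float) -> tuple[float, float, int]:
    """Two-sided one-sample t-test of unit accuracies against chance.

    Returns (t, p, df) with df = n - 1. Zero variance raises ``ValueError``
    (the statistic is undefined).
    """
    acc = np.asarray(unit_accuracies, dtype=float)
    if len(acc) < 2:
        raise ValueError("need at least two units")
    if np.var(acc, ddof=1) == 0:
        if np.allclose(acc, chance):
            return 0.0, 1.0, len(acc) - 1
        raise ValueError("zero variance: t statistic undefined")
    res = stats.ttest_1samp(acc, popmean=chance)
    return float(res.statistic), float(res.pvalue), len(acc) - 1


def top_labels_filter(labels, top_n: int = 3) -> tuple[np.ndarray, list]:
    """Indices of events bearing a unit's ``top_n`` most frequent labels.

    Ties at the rank boundary are broken by first occurrence in the event
    sequence. Returns (selected indices, the selected labels).
    """
    labels = np.asarray(labels)
    first_seen: dict = {}
    counts: dict = {}
    for i, lab in enumerate(labels):
        counts[lab] = counts.get(lab, 0) + 1
        first_seen.setdefault(lab, i)
    ranked = sorted(counts, key=lambda lab: (-counts[lab], first_seen[lab]))
    top = ranked[:top_n]
    mask = np.isin(labels, top)
    return np.flatnonzero(mask), top
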