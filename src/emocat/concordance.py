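"""Cluster-label concordance metrics and the end-to-end comparison pipeline.

A discovered clustering is compared against observed emotion labels via the
proportion table (cluster x label, rows sum to 1), per-cluster majority
labels, and majority-label accuracy: name each cluster after its most
prevalent label and score the fraction of samples whose label matches their
cluster's name. Also hosts the clip-labelling utilities (arg-max labelling
of rating rows, prevalence filtering) and :func:`run_pipeline`, which runs a
supervised arm and an unsupervised arm on one modality and emits a JSON
report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from emocat import dpgmm as dpgmm_mod
from emocat import lcgmm as lcgmm_mod
from emocat import reduction, supervised, synthetic, topics


@dataclass
class ClusterAssignment:
    """Per-sample cluster membership with soft responsibilities."""

    hard_labels: np.ndarray  # (T,)
    responsibilities: np.ndarray  # (T, B), rows sum to 1
    pi: np.ndarray  # (B,) occupancy or marginal prior

    @classmethod
    def from_lcgmm(cls, model, scores, labels) -> "ClusterAssignment":
        resp = model.responsibilities(scores, labels)
        uniq, counts = np.unique(np.asarray(labels), return_counts=True)
        freqs = counts / counts.sum()
        return cls(
            hard_labels=np.argmax(resp, axis=1),
            responsibilities=resp,
            pi=lcgmm_mod.mixing_proportions(model, freqs),
        )

    @classmethod
    def from_hard(cls, hard_labels, n_clusters=None) -> "ClusterAssignment":
        hard = np.asarray(hard_labels, dtype=int)
        B = int(n_clusters if n_clusters is not None else hard.max() + 1)
        resp = np.zeros((len(hard), B))
        resp[np.arange(len(hard)), hard] = 1.0
        return cls(hard_labels=hard, responsibilities=resp, pi=resp.mean(axis=0))


@dataclass
class ConcordanceReport:
    """Cluster x label proportion table with majority-label summaries."""

    proportion_table: pd.DataFrame  # rows: clusters, cols: labels; rows sum to 1
    majority_labels: list
    majority_accuracy: float
    pi: np.ndarray
    tie_clusters: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "proportion_table": {
                str(b): {str(c): float(v) for c, v in row.items()}
                for b, row in self.proportion_table.iterrows()
            },
            "majority_labels": [str(m) for m in self.majority_labels],
            "majority_accuracy": self.majority_accuracy,
            "pi": [float(p) for p in self.pi],
            "tie_clusters": self.tie_clusters,
        }


def concordance_table(assignment: ClusterAssignment, labels) -> ConcordanceReport:
    """Per-cluster label-proportion rows, majority labels, and accuracy.

    Empty clusters are dropped with a warning; label columns follow sorted
    unique label order, and majority ties break to the lowest label index.
    """
    labels = np.asarray(labels)
    hard = np.asarray(assignment.hard_labels)
    if len(labels) != len(hard):
        raise ValueError("assignment and labels must have equal length")
    label_values = np.unique(labels)
    clusters = np.unique(hard)
    all_clusters = np.arange(assignment.responsibilities.shape[1])
    empty = sorted(set(all_clusters) - set(clusters))
    if empty:
        shown = [int(e) for e in empty[:5]]
        warnings.warn(
            f"dropping {len(empty)} empty clusters (e.g. {shown})", stacklevel=2
        )

    rows, majorities, ties = [], [], []
    for b in clusters:
        in_cluster = labels[hard == b]
        counts = np.array([np.sum(in_cluster == lv) for lv in label_values], dtype=float)
        rows.append(counts / counts.sum())
        top = counts.max()
        winners = np.flatnonzero(counts == top)
        if len(winners) > 1:
            ties.append(int(b))
        majorities.append(label_values[winners[0]])

    table = pd.DataFrame(rows, index=clusters, columns=label_values)
    majority_map = dict(zip(clusters, majorities))
    accuracy = float(np.mean([labels[t] == majority_map[hard[t]] for t in range(len(labels))]))
    pi = np.asarray(assignment.pi)[clusters] if len(assignment.pi) > len(clusters) else assignment.pi
    return ConcordanceReport(
        proportion_table=table,
        majority_labels=majorities,
        majority_accuracy=accuracy,
        pi=np.asarray(pi),
        tie_clusters=ties,
    )


def majority_label_accuracy(assignment: ClusterAssignment, labels) -> float:
    """Fraction of samples whose label equals their cluster's majority label."""
    return concordance_table(assignment, labels).majority_accuracy


def argmax_label_videos(mean_category_ratings) -> tuple[np.ndarray, np.ndarray]:
    """Label each clip by its highest-rated category.

    Returns (labels, tie_flags): ties break to the lowest category index and
    are flagged. A clip whose ratings are all zero cannot be labelled and
    raises ``ValueError``.
    """
    if hasattr(mean_category_ratings, "to_numpy"):
        columns = np.asarray(mean_category_ratings.columns)
        ratings = mean_category_ratings.to_numpy(dtype=float)
    else:
        ratings = np.asarray(mean_category_ratings, dtype=float)
        columns = np.arange(ratings.shape[1])
    if np.any(ratings < 0) or np.any(ratings > 1):
        raise ValueError("mean ratings must lie in [0, 1]")
    zero_rows = np.flatnonzero(ratings.sum(axis=1) == 0)
    if len(zero_rows):
        raise ValueError(f"unlabeled clips (all-zero ratings) at rows {zero_rows.tolist()}")
    best = np.argmax(ratings, axis=1)
    row_max = ratings[np.arange(len(ratings)), best]
    tie_flags = (ratings == row_max[:, None]).sum(axis=1) > 1
    return columns[best], tie_flags


def prevalence_filter(per_clip_labels, n_categories: int) -> tuple[list, np.ndarray]:
    """Keep categories labelling strictly more than n_clips/n_categories clips.

    The threshold is the exact fraction 1/n_categories of the clip count.
    Returns (retained categories, indices of clips bearing them).
    """
    labels = np.asarray(per_clip_labels)
    n_clips = len(labels)
    threshold = n_clips / n_categories
    values, counts = np.unique(labels, return_counts=True)
    retained = [v for v, c in zip(values, counts) if c > threshold]
    clip_idx = np.flatnonzero(np.isin(labels, retained))
    return retained, clip_idx


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """One modality run: synthetic generation settings + analysis settings.

    ``modality`` is "bold", "ans", or "ratings". ``n_participants`` repeats
    the whole generate-and-analyse cycle with per-participant sub-seeds and
    aggregates (as the multi-participant studies do). Supervised arms can be
    switched off (``run_supervised=False``) for clustering-only sweeps.
    """

    modality: str = "bold"
    n_participants: int = 1
    seed: int = 0
    run_supervised: bool = True
    # bold settings
    snr: float = 10.0
    d_grid: tuple = tuple(range(2, 13))
    b_grid: tuple = tuple(range(1, 7))
    em_restarts: int = 10
    classifier_epochs: int = 30
    # ans settings
    ans_clusters: int = 4
    ans_events: int = 150
    dp_restarts: int = 10
    n_permutations: int = 100
    # ratings settings
    n_clips: int = 200
    n_topics: int = 3
    topic_grid: tuple = tuple(range(1, 9))
    ratings_folds: int = 8


def _participant_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)]


def _run_bold_participant(pseed: int, cfg: PipelineConfig) -> dict:
    data = synthetic.generate_bold(
        synthetic.BoldGeneratorConfig(snr=cfg.snr, seed=pseed)
    )
    d_max = max(cfg.d_grid)
    _, scores = reduction.fit_project_pca(data, d_max=d_max)
    trace, model = lcgmm_mod.select_model_order(
        scores,
        data.labels,
        d_grid=cfg.d_grid,
        b_grid=cfg.b_grid,
        n_restarts=cfg.em_restarts,
        seed=pseed,
    )
    D_star = trace.selected[0]
    assignment = ClusterAssignment.from_lcgmm(model, scores[:, :D_star], data.labels)
    report = concordance_table(assignment, data.labels)
    out = {
        "selected_D": int(trace.selected[0]),
        "selected_B": int(trace.selected[1]),
        "bic_min": float(np.min(trace.bic_values)),
        "majority_accuracy": report.majority_accuracy,
        "concordance": report.to_dict(),
    }
    if cfg.run_supervised:
        folds = supervised.build_folds(data.labels, data.run_ids, scheme="leave-one-run-out")
        acc = supervised.crossval_classifier(
            data.volumes,
            data.labels,
            folds,
            supervised.ClassifierConfig(
                model="volumetric-conv", max_epochs=cfg.classifier_epochs, seed=pseed
            ),
        )
        out["supervised_accuracy"] = acc.mean_accuracy
    return out


def _run_ans_participant(pseed: int, cfg: PipelineConfig) -> dict:
    gen = synthetic.AnsGeneratorConfig.well_separated(
        n_clusters=cfg.ans_clusters, n_events=cfg.ans_events, seed=pseed
    )
    events = synthetic.generate_ans_events(gen)
    idx, top = supervised.top_labels_filter(events.labels, top_n=3)
    X, y = events.features()[idx], events.labels[idx]
    result = dpgmm_mod.fit_best_of_restarts(
        events, dpgmm_mod.DpGmmConfig(n_restarts=cfg.dp_restarts, seed=pseed)
    )
    assignment = ClusterAssignment.from_hard(
        result.hard_assignments, n_clusters=len(result.weights)
    )
    report = concordance_table(assignment, events.labels)
    out = {
        "n_effective_clusters": int(result.n_effective),
        "top_labels": [str(t) for t in top],
        "n_classified_events": int(len(idx)),
        "majority_accuracy": report.majority_accuracy,
        "concordance": report.to_dict(),
    }
    if cfg.run_supervised:
        folds = supervised.build_folds(y, scheme="k-fold", k=5, seed=pseed)
        acc = supervised.crossval_classifier(
            X, y, folds, supervised.ClassifierConfig(seed=pseed, max_epochs=cfg.classifier_epochs)
        )
        out["supervised_accuracy"] = acc.mean_accuracy
        out["folds"] = folds
        out["features"] = X
        out["labels"] = y
    return out


def _run_ratings(seed: int, cfg: PipelineConfig) -> dict:
    profiles = synthetic.random_topic_profiles(cfg.n_topics, seed=seed)
    affect = np.clip(
        np.random.default_rng(seed).uniform(2, 8, size=(cfg.n_topics, 14)), 1, 9
    )
    corpus_cfg = synthetic.RatingsGeneratorConfig(
        n_clips=cfg.n_clips,
        n_topics=cfg.n_topics,
        topic_category_profiles=profiles,
        affect_cluster_means=affect,
        seed=seed,
    )
    ratings = synthetic.generate_rating_corpus(corpus_cfg)

    corpus = topics.ratings_to_corpus(ratings.category_means, ratings.raters_per_clip)
    curve = topics.fit_lda_perplexity_scan(corpus, topic_grid=cfg.topic_grid, seed=seed)

    labels, tie_flags = argmax_label_videos(ratings.category_means)
    retained, clip_idx = prevalence_filter(labels, corpus_cfg.n_categories)
    out = {
        "perplexity_curve": {
            "topic_grid": curve.topic_grid.tolist(),
            "perplexity": curve.perplexity.tolist(),
            "minimum": curve.minimum,
        },
        "retained_categories": [str(r) for r in retained],
        "n_retained_clips": int(len(clip_idx)),
        "n_tied_clips": int(tie_flags.sum()),
    }

    affect_X = ratings.affect_means.to_numpy(dtype=float)[clip_idx]
    y = labels[clip_idx]
    if cfg.run_supervised and len(retained) >= 2:
        folds = supervised.build_folds(y, scheme="k-fold", k=cfg.ratings_folds, seed=seed)
        acc = supervised.crossval_classifier(
            affect_X,
            y,
            folds,
            supervised.ClassifierConfig(seed=seed, max_epochs=cfg.classifier_epochs),
            oversample=True,
        )
        out["supervised_accuracy"] = acc.mean_accuracy
        out["chance_level"] = acc.chance_level

    # Label-free GMM (single label class) on the affect dimensions, BIC over B
    flat_labels = np.zeros(len(affect_X), dtype=int)
    trace, model = lcgmm_mod.select_model_order(
        affect_X,
        flat_labels,
        d_grid=[affect_X.shape[1]],
        b_grid=cfg.b_grid,
        n_restarts=cfg.em_restarts,
        seed=seed,
    )
    assignment = ClusterAssignment.from_lcgmm(model, affect_X, flat_labels)
    report = concordance_table(assignment, y)
    out["affect_gmm_B"] = int(trace.selected[1])
    out["affect_concordance"] = report.to_dict()
    out["affect_majority_accuracy"] = report.majority_accuracy
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the supervised and unsupervised arms for one modality.

    Returns a JSON-serialisable report with per-participant results and
    group-level statistics (t-test vs. chance for labelled modalities, a
    permutation null for the imbalance-preserving autonomic protocol).
    Deterministic for a fixed config + seed.
    """
    cfg = config
    seeds = _participant_seeds(cfg.seed, cfg.n_participants)
    report: dict = {"modality": cfg.modality, "seed": cfg.seed, "participants": []}

    if cfg.modality == "bold":
        for pseed in seeds:
            report["participants"].append(_run_bold_participant(pseed, cfg))
        report["bstar_histogram"] = {
            str(b): sum(1 for p in report["participants"] if p["selected_B"] == b)
            for b in sorted({p["selected_B"] for p in report["participants"]})
        }
        report["mean_majority_accuracy"] = float(
            np.mean([p["majority_accuracy"] for p in report["participants"]])
        )
        if cfg.run_supervised:
            accs = [p["supervised_accuracy"] for p in report["participants"]]
            report["mean_supervised_accuracy"] = float(np.mean(accs))
            if len(accs) >= 2 and np.var(accs, ddof=1) > 0:
                t, p, df = supervised.t_test_vs_chance(accs, 1.0 / 3.0)
                report["t_test"] = {"t": t, "p": p, "df": df, "chance": 1.0 / 3.0}
    elif cfg.modality == "ans":
        per_unit = [_run_ans_participant(pseed, cfg) for pseed in seeds]
        if cfg.run_supervised:
            null = supervised.permutation_null(
                [u.pop("features") for u in per_unit],
                [u.pop("labels") for u in per_unit],
                [u.pop("folds") for u in per_unit],
                supervised.ClassifierConfig(seed=cfg.seed, max_epochs=cfg.classifier_epochs),
                n_permutations=cfg.n_permutations,
                seed=cfg.seed,
            )
            report["permutation_test"] = {
                "observed": null.observed,
                "null_mean": float(null.null_means.mean()),
                "tail_p": null.tail_p,
                "n_permutations": null.n_permutations,
            }
        report["participants"] = per_unit
        report["cluster_histogram"] = {
            str(b): sum(1 for u in per_unit if u["n_effective_clusters"] == b)
            for b in sorted({u["n_effective_clusters"] for u in per_unit})
        }
    elif cfg.modality == "ratings":
        report["ratings"] = _run_ratings(cfg.seed, cfg)
    else:
        raise ValueError(f"unknown modality {cfg.modality!r}")
    return report


def report_to_json(report: dict, path=None) -> str:
    """Serialise a pipeline report deterministically."""
    text = json.dumps(report, indent=1, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
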