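# Methods

This note documents the models, default parameters, synthetic generators,
and numerical conventions of `emocat`, and states what the test suite does
and does not establish.

## Label-conditional Gaussian mixture (`emocat.lcgmm`)

Trials with observed emotion label Λ_t and PCA features α_t ∈ R^D are
modelled as p(α_t | Λ_t = l) = Σ_b γ_bl N(α_t; μ_b, Σ) with B cluster
means μ_b, one diagonal covariance Σ shared across clusters (defensible
after PCA, which decorrelates globally), and a column-stochastic mixing
matrix γ ∈ R^{B×L}. EM updates:

* E-step: r_tb ∝ γ_{b,Λ_t} · N(α_t; μ_b, Σ), normalised per trial.
* M-step: μ_b = Σ_t r_tb α_t / Σ_t r_tb; Σ_d = (Σ_t α_td² − Σ_b N_b μ_bd²)/T,
  floored at 1e-6 to prevent degenerate likelihood spikes;
  γ_bl = Σ_{t:Λ_t=l} r_tb / |{t: Λ_t=l}|.

Initialisation is k-means++ seeding of the means with uniform γ; defaults:
10 restarts (best final log-likelihood kept), tolerance 1e-6 on the
log-likelihood gain, at most 500 iterations. The log-likelihood sequence
is asserted nondecreasing on every run. With L = 1 the model is exactly a
shared-diagonal-covariance GMM; the suite cross-checks its converged
log-likelihood against R/mclust's `EEI` parameterisation (agreement to
~3e-7 on a 50-point instance).

Model order is selected by minimising BIC = −2 log L + p ln T with
p = B·D + D + (B−1)·L free parameters (means, shared variances, and L
independent B-simplex columns). The joint search grids default to
D ∈ {2..12} and B ∈ {1..6}; the first D columns of the full score matrix
are used at each D, and ties break toward smaller B, then smaller D
(parsimony). Two cluster-size summaries are provided, because figures in
this literature report π_k without defining it: the label-marginalised
prior π_k = Σ_l f_l γ_kl (`mixing_proportions`) and the empirical soft
occupancy (`cluster_occupancy`).

## Dirichlet-process GMM protocol (`emocat.dpgmm`)

Six-dimensional event vectors are clustered with truncated variational
inference for a DP mixture (scikit-learn's `BayesianGaussianMixture`,
stick-breaking weight prior). The protocol this module owns: full
covariances; the data mean as the Gaussian mean prior; truncation equal to
the number of events; concentration prior 1/truncation (a common default;
configurable); many restarts with distinct sub-seeds (default 100),
keeping the run with the highest evidence lower bound. The "discovered
cluster" count is the number of components with weight above a threshold
(default 1/(2·n_events)) *and* at least one hard-assigned event.

A measured caveat: with full covariances in six dimensions, truncated
variational inference needs on the order of 100 events per cluster before
it stops splitting genuine clusters into fragments. Below that (e.g. 50
events per cluster) the selected solution routinely reports 5–8 effective
clusters for 4 well-separated generative clusters, at any truncation
level. Recovery tests therefore use 400 events for 4 clusters, and the
single-cluster collapse check uses 500 events.

## LDA topic scan (`emocat.topics`)

Mean yes/no category ratings are discretised to pseudo-token counts,
counts[i][j] = round(mean[i][j] × raters[i]) — the declared convention for
turning averaged binary ratings into the discrete input LDA requires. For
each candidate topic count K, batch variational LDA is fit with a sparse
symmetric document-topic prior α = 1/K and topic-category prior η = 0.1,
on the held-in clips of a 5-fold split (by clip, seeded). Held-out
perplexity is computed directly as exp(−Σ n·log(θφ) / Σ n) from the
posterior-mean document-topic proportions θ and the normalised topic
distributions φ, so that K = 1 reduces *exactly* to the Dirichlet-smoothed
corpus unigram (a closed-form oracle in the tests).

Batch variational LDA is prone to local optima precisely at the true topic
count (one topic swallows two modes), which flattens or shifts the
perplexity curve's minimum; the scan therefore fits each (K, fold) with 5
random restarts and keeps the best training bound — the same
restart-max-bound logic the DP-GMM protocol uses. Measured effect: without
restarts the curve minimum recovered a 3-topic generative corpus ~50% of
the time, with restarts 10/10.

A "clear minimum" (`detect_topic_minimum`) must be (i) interior to the
grid, (ii) a local minimum, (iii) more than `rel_improvement` (default 5%)
below the first grid value, and (iv) strictly below the last grid value.
Monotone or flat curves yield "no clear minimum" — a legitimate outcome
meaning the categories do not reduce to fewer separable topics. Condition
(iv) is deliberately weaker than (iii): near-plateau tails are common even
when an interior minimum is real, so demanding a 5% margin over *both*
ends would misclassify genuinely structured curves.

## Supervised baselines (`emocat.supervised`, `emocat._nets`)

Two classifier contracts, both trained with Adam (default learning rate
3e-3) on softmax cross-entropy with an early stop on a training-loss
plateau, implemented as a compact NumPy layer stack:

* **feed-forward** — two ReLU hidden layers (64, 32) with dropout 0.25,
  for vector features (z-scored per feature with training-fold statistics);
* **volumetric-conv** — two 3×3×3 conv blocks (8 then 16 channels, each
  followed by ReLU and 2×2×2 max-pooling), dropout 0.2 on the input volume
  and 0.5 on the flattened features, then a softmax layer; volumes are
  standardised with training-fold global mean/sd. Convolution uses
  im2col + a single BLAS matmul per pass in float32; 6-fold
  leave-one-run-out cross-validation on 180 trials of 16³ volumes runs in
  well under a minute per participant on one CPU.

These are the smallest architectures that pass the separable-data and
high-SNR checks; no hyperparameter search is performed. Fold construction:
leave-one-run-out folds coincide with run indices; k-fold deals samples
round-robin within a label-stratified seeded shuffle (sizes differ by at
most one). Minority oversampling resamples each training class with
replacement up to the majority count, touching only training indices.

The permutation null preserves class imbalance: each of n_permutations
iterations shuffles every unit's *training* labels within each fold,
re-runs the cross-validation, and averages unit accuracies into one null
mean; tail_p = (1 + #{null ≥ observed}) / (n_permutations + 1). Type-I
calibration is verified by simulation (100 permutations × 50 replicates on
label-independent features). The t-test against chance is the standard
two-sided one-sample test with df = n − 1; zero variance raises rather
than fabricating a statistic (the all-identical above-chance case is
handled by the caller as unambiguous evidence).

## Dimension reduction (`emocat.reduction`)

PCA is fit on centered data only (no per-voxel z-scoring: amplitude scale
is meaningful for beta-like data whose normalisation happens upstream).
Parallel analysis compares observed covariance eigenvalues with the
pointwise 95th percentile of eigenvalues from column-independent
permutation surrogates (500 draws by default) and retains the leading run
of exceedances.

## Synthetic generators (`emocat.synthetic`)

**Beta maps.** Each of L categories (default 3) owns 5 isotropic Gaussian
radial basis functions exp(−‖v−c‖²/2w²) with centers uniform over a
16×16×16 voxel grid and widths uniform in [2, 6] voxels. A trial's
noiseless map is the sum of its category's RBF images scaled by per-trial,
per-region amplitudes uniform in [0.5, 1.5] ("varying BOLD amplitude");
i.i.d. zero-mean Gaussian noise is added, scaled so the pooled variance
ratio var(signal)/var(noise) over all voxels and trials equals the
configured SNR. 60 trials per category are dealt round-robin over 6 runs,
so runs are label-balanced. Defaults are desk-scale stand-ins for brain
resolution; all are configurable.

Two measured properties of this design matter for interpretation:

* *Clusterability vs. SNR has a sharp threshold that depends on the grid.*
  With i.i.d. voxel noise, every PCA direction carries noise variance
  var(signal)/SNR while the category signal concentrates ~n_voxels ×
  var(signal) of energy in a few directions, so separability scales with
  n_voxels × SNR. At 4096 voxels, majority-label cluster accuracy is at
  chance (B* = 1) for SNR ≤ 1e-3 and ≈0.88 at SNR = 1e-2. Any statement
  "accuracy is X at SNR = s" is meaningful only jointly with the SNR
  convention and the grid size.
* *At high SNR, BIC resolves the amplitude jitter itself.* The per-trial
  region weights give each category a box-shaped within-category
  distribution; once noise is small, the shared-diagonal GMM gains real
  likelihood by splitting categories into label-pure sub-clusters
  (B* of 4–6 with majority accuracy 1.0 at SNR = 10, under any jitter down
  to ±2%). This is over-clustering, not mis-clustering, and it is the
  expected behaviour of a consistent criterion applied to a model-misfit
  generator; recovery of B* = L requires amplitude jitter below the noise
  level.

**Autonomic events.** Events are drawn from equiprobable multivariate
Gaussians in the six-feature space; each event's free-text label is drawn
from its latent cluster's row of a row-stochastic label matrix, producing
the many-to-many label-physiology structure of free-labelled experience
sampling; valence/arousal are uniform on [−50, 50]. The
`well_separated` builder places unit-variance clusters ~8 units apart with
two labels per cluster.

**Clip ratings.** Each clip gets one latent topic; its mean category
ratings are the topic's sparse profile (a few strongly endorsed
categories) plus Gaussian noise clipped to [0, 1]; its mean affect ratings
are the topic's 14-vector plus noise clipped to [1, 9]; 9 raters per clip
by default.

What the generators do **not** emulate: hemodynamics and temporal
structure, spatially correlated noise, anatomy or inter-subject alignment,
physiological artifact structure, rater-level (as opposed to clip-level)
variation, and label noise. Passing tests therefore establish correctness
of the machinery and its behaviour under known structure — not that real
brain, autonomic, or self-report data contain (or lack) label-concordant
clusters.

## Numerical conventions

* Variance floor 1e-6 on shared diagonal covariances; γ entries floored at
  1e-12 before renormalising.
* All ties break to the lowest index and are flagged where surfaced
  (majority labels, clip arg-max labels, rank boundaries in top-k label
  selection use first occurrence).
* Prevalence filtering retains categories whose clip count strictly
  exceeds n_clips/n_categories (the exact fraction, not its percentage
  rounding).
* Every stochastic routine takes an explicit seed and derives sub-seeds
  through `numpy.random.SeedSequence`/`default_rng`; identical
  config + seed reproduces outputs bitwise.
* Degenerate inputs raise: constant data for PCA, rank-deficient event
  tables for the DP-GMM, zero-variance accuracies for the t-test, all-zero
  rating rows for clip labelling.

## Problem sizes

The test suite and the validation script run at desk scale by design:
16³-voxel grids with 180 trials per synthetic participant, 400-500 events
per autonomic dataset, 40-150 clips per rating corpus, 100-permutation
nulls with 50 replicates for calibration, and 10-20 generator seeds for
stochastic recovery claims.

## Known limitations

* The volumetric and feed-forward networks are deliberately minimal
  baselines; they demonstrate above-chance supervised decodability, not
  state-of-the-art accuracy.
* The DP-GMM inherits the small-sample over-splitting of truncated
  variational inference documented above.
* Perplexity-based topic-number recovery is reliable only with the
  restart protocol and a grid extending past the true count; on corpora
  with real within-topic structure, extra topics genuinely improve
  held-out likelihood and the scan will (correctly) not report a minimum.
* Real-data results for the three modalities require the original
  datasets; the two laboratory datasets are private, and the public
  clip-rating dataset must be downloaded separately
  (`emocat.io.load_public_clip_ratings`).
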