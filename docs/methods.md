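# Methods

## Problem and pipeline

The package classifies subjects into cases and controls (the motivating
application is autism spectrum disorder vs typical controls) from two
modalities: parcellated resting-state fMRI time series (T timepoints × R
atlas regions, e.g. R = 200 for the cc200 parcellation) and tabular
phenotypes (collection site, sex, age, FIQ/VIQ/PIQ, eye status at scan,
handedness category).  The stages are:

1. **Graph construction.**  Each subject becomes an undirected weighted graph
   on R nodes.  Node i's feature vector is row i of the R × R Pearson
   correlation matrix of the ROI time series.  The edge weight between i and
   j is |ρ̃_ij|, the absolute partial correlation, read off the precision
   matrix Θ of a shrinkage-regularized covariance estimate:
   ρ̃_ij = −Θ_ij/√(Θ_ii Θ_jj).  The graph is complete by default (a
   `top_k`-per-node sparsification is available); the absolute partial
   correlations damp indirect (transitive) dependence, which counteracts
   over-smoothing in the graph convolutions.
2. **Feature selection (SVM-RFE).**  The strict upper triangle of the Pearson
   matrix — R(R−1)/2 features, 19,900 at R = 200 — is z-scored and ranked by
   recursive elimination with a linear SVM (C = 1): at each round the
   `max(1, ⌊step_fraction·m⌋)` features with the smallest |w_j|/‖w‖₂ are
   dropped, until `n_keep` remain.  The retained edge set is symmetrized and
   applied to the Pearson matrix as a zero-mask (diagonal kept), so node
   features keep dimension R.
3. **Graph encoder.**  Two edge-weighted graph convolutions
   h_i ← W₁h_i + W₂ Σ_{j∈N_i} Ω_ji h_j (R → d₁ → d₂), each followed by batch
   normalization and ReLU, then global max pooling over nodes to give the
   graph representation g ∈ ℝ^{d₂}.  Two layers only: deeper stacks
   over-smooth node representations on dense connectome graphs.
4. **Phenotype encoder (PFE).**  Categorical phenotype columns are one-hot
   encoded against vocabularies fitted on the training split; numeric columns
   are min-max scaled to [0, 1] with training extrema and clipped.  The
   encoded vector passes through an MLP with L = 1 hidden layer (affine +
   ReLU) whose output dimension equals d₂.
5. **Attention fusion.**  A = g ⊕ p′ (length D = 2d₂).  A per-subject scaled
   dot-product score matrix S = (A Aᵀ)/D is row-softmaxed into α and applied
   to A; the attended vector feeds a dense → ReLU → dense head emitting two
   logits, trained with mean cross-entropy (log clamped at 1e−12).

## Training protocol

Adam, learning rate 1e−3, weight decay 0.05, batch size 64, 100 epochs,
learning rate halved every 20 epochs; a single random 8:2 train/test split;
no validation split or early stopping (the per-epoch history is logged
instead).  The RFE mask and the phenotype schema are fitted on the training
split only and frozen before the test split is touched.

Two optimization details matter and are deliberate:

* **Weight decay exempts normalization and bias parameters.**  With decay
  applied uniformly, the L2 pull on the BatchNorm gains shrinks activations
  while the attention layer (whose early-training output is close to the mean
  of A in every component) shrinks gradients; together they pin the model at
  chance on moderate-signal data.  Dense/convolution weights keep the full
  0.05 decay; BatchNorm gains/shifts and all biases are exempt — the standard
  no-decay-on-norm/bias convention.
* **Attention is computed per subject.**  A batch-level reading of the
  score softmax would couple subjects and make predictions depend on batch
  composition at test time; the per-subject outer-product form (D × D scores,
  divisor exactly D) is the only batch-size-independent reading.

Other defaults: d₁ = 64, d₂ = 16, classifier hidden width 32 — small enough
for CPU training while leaving the encoder over-parameterized relative to the
synthetic cohorts.  The width d₂ doubles as the attention temperature (the
scores are divided by D = 2d₂), so wide graph representations flatten the
attention softmax and attenuate gradients through the fusion roughly as 1/D;
at d₂ = 32 training frequently stalls at chance on moderate-signal cohorts,
while d₂ = 16 conditions the fusion well — hence the default.
Glorot-uniform initialization; BatchNorm ε = 1e−5,
momentum 0.1 (running statistics used in evaluation mode, so inference is
deterministic).  All training is a pure function of (data, config, seed).

## Synthetic cohorts

Real multi-site cohorts cannot be redistributed, so validation uses generated
data in exactly the shapes the pipeline consumes.  Cases and controls are
drawn as i.i.d. multivariate-normal timepoints from two population
correlation matrices that are identical except on a planted set of uniformly
sampled ROI pairs, where they differ by exactly `effect_size` (control
−e/2, case +e/2).  A shared sparse background (density 0.1, magnitudes ≤
0.15) makes the matrices non-trivial; positive definiteness is enforced by
halving the background until the minimum eigenvalue of both matrices exceeds
0.01 — the planted entries are never altered, so the planted contrast is
exact by construction, and infeasible requests are rejected with the maximum
feasible effect (2·(1−0.01)/specrad of the planted pattern).  Phenotypes are
drawn from fixed marginals loosely matched to multi-site cohort demographics
(age ~ N(15, 6²) truncated at 6, IQ scores ~ N(108, 15²), 80% male, 85%
right-handed, 2–3 sites); an optional per-column additive shift of the case
group plants a phenotypic signal.  Imaging and phenotypic signals are
independently switchable so ablations have ground truth.

What the generator does **not** emulate: temporal autocorrelation and
hemodynamics (timepoints are exchangeable), site batch effects beyond
optional mean shifts, missing phenotype values, heavy-tailed noise, and the
head-motion artifacts of real fMRI.  Passing tests therefore demonstrate that
the pipeline recovers the kind of second-order group structure it targets
under clean conditions; they do not certify accuracy on real cohorts.

## Validation experiments and problem sizes

All experiment scales below are the package's chosen study conditions,
executed both by `tests/test_acceptance.py` and `scripts/acceptance.py`:

* **Null calibration** — 20 seeds, 100 cases/100 controls, R = 20, T = 150,
  zero effect, zero shift.  Mean held-out accuracy must fall in the two-sided
  99% binomial band around 0.5.  This experiment uses the *stratified* split
  flag: with an unstratified split of a fixed balanced cohort, train and test
  imbalances are anti-correlated, and a no-signal model that majority-votes
  the training imbalance lands at 0.5 − E|test imbalance| ≈ 0.443 — a
  finite-sample split artifact, not miscalibration.  Stratification makes the
  null expectation exactly 0.5.
* **Power and recovery** — 20 seeds, 150/150 subjects, effect 0.6 on 15
  planted edges, R = 20, T = 150.  Held-out accuracy ≥ 0.9 in ≥ 18/20 seeds,
  and the 30 RFE-retained edges enriched for planted edges against the
  hypergeometric null at p < 0.01.
* **Ablation ordering** — 20 seeds, 100/100 subjects, imaging effect 0.3 on
  10 edges with T = 100, plus a −7.5-point shift of the case group's
  FIQ/VIQ/PIQ (half an IQ standard deviation).  Mean accuracy: full model ≥
  imaging-only ≥/and ≥ no-selection variant.
* **Oracle equivalence** — Pearson vs a brute-force double loop (1e−12);
  partial correlation vs regression-residual correlation (1e−8); one-at-a-time
  RFE vs an exhaustive refit-and-drop oracle; trapezoidal AUC vs exhaustive
  concordant-pair counting; analytic vs finite-difference gradients (1e−4).

The test cohorts use R = 20–30 rather than 200: every algorithmic path is
dimension-independent, and the 200-region case is covered by the
dimensionality identity (19,900 features) and the shape contracts.

## Numerical choices and degenerate inputs

* Shrinkage intensity `"auto"` uses the analytic Ledoit–Wolf estimate toward
  the scaled identity; explicit λ ∈ [0, 1] is accepted, and λ = 0 on a
  singular covariance raises an error instructing nonzero shrinkage.
* Constant (zero-variance) ROI columns are a hard error naming the ROI;
  a permissive mode zero-fills that row/column instead.
* RFE ties are broken by eliminating the lower original feature index first;
  survivors of the final round are ranked by the final fit's importances, so
  the ranking is a total order and masks for any keep count can be re-derived
  by rank thresholding (the sweep command reuses one deep ranking this way).
* Metrics with zero denominators are reported as 0 with an explicit
  `undefined` flag; AUC uses the midrank tie convention.
* The 8:2 split takes `round(0.8·n)` training subjects; stratified splitting
  applies the ratio within each class.
* Max-pooling gradient routes to the first arg-max on ties; the capacity
  test (perfect memorization of a 16-subject batch) runs 600 epochs at a
  constant learning rate with weight decay off, since the default schedule
  freezes the learning rate long before memorization completes.

## Known limitations

The literal per-feature importance formula printed in the motivating work
measures sample-to-hyperplane distance (it ranks subjects, not features); the
default criterion here is the standard SVM-RFE weight magnitude, with the
literal unit-point reading available as `importance="unit_point"`.  Whether
the graph encoder should consume full or mask-zeroed Pearson rows is not
decidable from the motivating description; masked is the default, unmasked is
a config flag away (`selection.enabled: false`).  The generator's i.i.d.
timepoints make partial-correlation estimation easier than on autocorrelated
BOLD data, so shrinkage requirements on real data will be higher.
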