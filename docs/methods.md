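# Methods

This note documents the models, the numerical choices, and the synthetic
cohorts the package is validated on — including what those validations do
and do not establish.

## Stationary wavelet decomposition

Each sample's expression profile is treated as a 1-D signal over the
ordered gene list and decomposed with the stationary (undecimated) wavelet
transform. Only the approximation (low-pass) bands cA₁…cA_m are kept and
stacked as the m input channels of the classifier; detail bands are
discarded as noise, following standard wavelet denoising practice. Twelve
candidate wavelet functions are supported (db1/3/5, coif1/3/5,
bior3.1/3.3/3.5, sym2/4/6); `select_wavelet` picks among them by inner
validation AUC. The decomposition depth defaults to 3 — deeper levels
increasingly smooth away per-gene information with little effect on
classification in our synthetic runs — and is configurable.

Numerics: profiles are tail-padded to a multiple of 2^m by symmetric
reflection and the coefficients truncated back, so positions stay aligned
with genes; inside the transform PyWavelets uses periodic extension, which
makes the transform exactly shift-invariant (tested). The test suite pins
the coefficient convention against a brute-force à-trous oracle: level-j
approximation = circular convolution with the reversed low-pass filter,
upsampled by 2^(j−1), advanced by L/2−1 taps.

## The one-convolutional-layer classifier

Architecture (fixed): input (p, m) → conv(64 filters, kernel 8, stride 1,
length-preserving zero padding, relu) → max-pool(window 8, ceiling
padding) → flatten → dense(32, relu) → dense(2, softmax). Pooling window 8
is forced by the printed feature arithmetic (26,270 positions → 3,284
pooled features); kernel length, dense width, epochs (50), batch size (16)
and the RMSprop learning rate (1e-4) are conventional defaults, all
configurable. Loss is the binary cross-entropy; training is plain
minibatch RMSprop (ρ = 0.9) implemented in numpy (im2col convolution,
manual backprop), bit-reproducible from the seed.

Input normalization: raw FPKM-scale wavelet coefficients span five orders
of magnitude, under which gradient training either stalls or collapses to
the class prior through dead relu units. The network therefore learns a
*single global* affine transform from its training tensor — one scalar
center and one scalar scale for the whole tensor, stored with the model.
This preserves every relative magnitude (genes are not individually
standardized, so the network still over-weights high-magnitude genes — a
property the scoring analysis depends on) while making optimisation
behave. `input_norm="none"` disables it.

Model selection mirrors the repeated-training protocol:
`repeat_train_select_best` trains N networks with derived seeds on an
inner 70/30 split of the training data and keeps the highest
inner-validation AUC; there is no early stopping — best-of-N plays that
role. The "best model" criterion (inner-validation AUC) is our choice, as
is the 70/30 inner split.

## Gene scoring by least-squares back-mapping

With representative features X (f pooled features × n samples; post-pool
activations averaged over the 64 filters) and Y the original expression
matrix, the score matrix is the minimum-norm least-squares solution
B = Y·X⁺ = Y·Xᵀ(X·Xᵀ)⁺. The pseudoinverse replaces the plain inverse
because X·Xᵀ has rank ≤ n and is singular whenever f > n. A gene's score
is the mean of its row of B; ranking is by descending score with
deterministic lexical tie-breaking. A configuration switch
(`y_source="swt_level1"`) substitutes the level-1 approximation
coefficients for Y; the default is the expression matrix, matching the
dimensions of the worked example that defines the method.

A structural property worth knowing: the row mean of B collapses
algebraically to a single projection, score_g = y_g · v with
v = X⁺·1_f / f. The gene ranking is therefore one linear functional of the
samples, determined entirely by the feature geometry. Empirically (see
"What the synthetic validation shows") v carries little class information
at balanced feature/sample counts and drifts toward a mean-expression
weighting when f ≫ n — which reproduces the known failure mode where
very-high-expression genes (mitochondrial-like) dominate the top ranks
when the network sees raw profiles, and motivates the wavelet smoothing.

Ranking stability across bootstrap refits is quantified by Kendall's
tau-b over the union of top-k sets (full-list ranks, two-sided p-values).

## Cox modelling

Univariate screening fits one proportional-hazards coefficient per gene by
Newton iteration on the Efron-tie-corrected partial likelihood, vectorized
across genes (all genes share the risk-set bookkeeping; covariates are
centred; steps clipped to ±2; convergence |Δβ| < 1e-10). This hand-rolled
solver exists because the pipeline screens up to a thousand genes inside a
tuning loop; it is tested to 1e-6 against explicit partial-likelihood
maximization and against lifelines. Genes with constant expression, or
with |β̂| diverging (monotone likelihood), are skipped with a warning.
Wald p < 0.05 selects genes.

The joint model uses lifelines' `CoxPHFitter`. Genes with joint Wald
p < 0.05 form the signature, refit on that subset for the final
coefficients. If the standard fit fails to converge or yields non-finite
standard errors (e.g. collinear genes), the model falls back to
ridge-penalized partial likelihood, with the penalty chosen by 3-fold
cross-validated partial log-likelihood over {0.01, 0.1, 1.0}; in penalized
mode no Wald pruning is applied (penalized Wald p-values are not reliable)
and `fit_mode="penalized"` is recorded.

Risk score = Σ βᵢxᵢ. The classification cutoff maximizes Youden's J over
an explicit threshold scan using strict ">" semantics (a sample is
high-risk iff its score strictly exceeds the cutoff; ties between
thresholds resolve to the lower one) so that the stored cutoff and the
stratification rule are mutually consistent. Kaplan–Meier curves, group
medians and the two-group log-rank test come from lifelines and are
cross-checked against a hand-tabulated observed-minus-expected oracle.

The top-n pool size is tuned over 100…1000 in steps of 100 (capped at the
gene count) by the same univariate→multivariate→risk-score chain on an
inner split, maximizing inner-validation AUC with ties to the smallest n;
the tuning criterion is our choice. On desk-scale cohorts (p ≈ 500) inner
validation usually selects the largest n — effectively genome-wide
univariate screening — which is what gives the Cox arm most of its power.

## Baselines and evaluation

SVM (RBF; cost and kernel width grid-searched over 10⁻³…10³ by stratified
3-fold CV), random forest and logistic regression at library defaults,
each behind the conventional pre-filter: pooled-variance two-sample
t-test p < 0.05 and |log₂ fold change| > 1, fold change computed as the
ratio of class means with a 1e-9 pseudocount. AUC is the rank-based
Mann–Whitney statistic with half-credit for ties; `run_benchmark` executes
a seeded repeated-random-split plan (train size ⌊0.7·n⌋) and reports the
per-split AUCs, their mean, and SE = SD/√(#splits).

## Synthetic cohorts

`simulate_cohort` emulates a TCGA-like FPKM cohort:

- **Expression**: log-normal; per-gene log-means ~ Normal(2.0, 1.0), within-
  gene log-sd 0.5 (a realistic bulk RNA-seq dispersion).
- **Prognostic genes** (k = 20 of p = 2000 by default): one contiguous
  co-regulated block (the grouped-gene structure wavelet smoothing
  exploits). Their log-hazard acts on *standardized log-expression*
  (effect 1.0/SD by default, positive = up-regulated risk), so raw-scale
  magnitude is decoupled from prognostic signal. Most planted genes are
  abundantly expressed (log-mean +1.5), matching the collagen/ribosomal
  character of real survival signatures; `n_low_informative` = 5 of them
  are instead shifted to low expression (−2) to probe the magnitude-bias
  failure mode.
- **Nuisance genes**: 10 uninformative genes at log-mean +5
  (mitochondrial-like), scattered away from the block.
- **Survival**: exponential baseline hazard ln 2/1095 per day (median
  survival of an average patient at the 3-year horizon, balancing the
  3-year classes); uniform right censoring calibrated by root-finding to
  a 30% target; tumor stage = indicator(linear predictor > median) with
  10% flip noise, mapped to stages I–IV.

`expected_auc_bound` Monte-Carlo-estimates the Bayes-optimal 3-year AUC
from the true linear predictor; a pipeline test asserts the held-out AUC
never beats this ceiling beyond noise.

What the generator does **not** model: gene–gene correlation beyond the
planted block, batch effects, platform noise, non-proportional hazards,
or competing risks. Passing tests on these cohorts shows the pipeline's
internal consistency and its behaviour under a known ground truth — not
performance on real tumors.

## What the synthetic validation shows

- The Cox risk-score arm is the workhorse: on strong-signal cohorts
  (10 planted genes, effect 2.5/SD, n = 400) it reaches held-out AUC
  0.91–0.95 across seeds, against a Bayes ceiling ≈ 0.99, and stays at
  0.52–0.58 on null cohorts. It beats the all-gene network classifier in
  every sparse-signal seed tested.
- The all-gene network plateaus near AUC 0.55–0.75 here: with only a
  handful of informative genes among hundreds, the flattened dense layer
  memorizes before it generalizes. Best-of-N selection mitigates but does
  not remove this.
- The back-mapped gene ranking is *weakly* enriched for planted genes
  (typically 3–6 of 20 in the top 100 of 2000, hypergeometric p ~ 1e-2 to
  3e-4 across seeds, versus an expectation of 1) and its bootstrap
  Kendall tau is modest. The projection analysis above explains why: the
  scoring direction v is set by feature geometry, not by the class
  contrast, so enrichment flows mainly through expression magnitude. The
  wavelet-motivation property does hold — with SWT preprocessing the
  low-expressed informative genes rank no worse (and usually better) than
  with a raw-expression network, at every seed tested.

## Known limitations

- Two-class endpoints only; no c-index, time-dependent covariates or
  competing risks.
- The network is single-conv-layer by design; no GPU path.
- The gene ranking should be treated as a magnitude-weighted candidate
  pool to be screened by Cox regression (as the pipeline does), not as a
  calibrated per-gene effect estimate.
- KM curves are emitted as data tables; no plotting.
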