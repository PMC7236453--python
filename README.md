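# waverisk

Prognostic risk stratification for gene-expression cohorts by a
wavelet-CNN pipeline: per-sample **stationary wavelet decomposition** of the
expression profile, a **one-convolutional-layer classifier**, least-squares
**back-mapping of the network's representative features to per-gene
importance scores**, and a **Cox proportional-hazards risk signature** with a
ROC-derived cutoff for high/low-risk assignment.

It is aimed at computational biologists who want to (a) classify tumor
samples into clinical risk groups (by tumor stage or 3-year overall
survival) directly from bulk RNA-seq FPKM-like matrices without a gene
pre-filter, and (b) extract a ranked gene list from the trained network for
downstream signature building. A synthetic cohort generator with planted
prognostic genes makes the whole pipeline testable without any data
download.

## Method

Given an expression matrix *Y* (p genes × n samples):

1. **SWT.** Each sample's profile is decomposed with the stationary
   (undecimated, à-trous) wavelet transform; the approximation bands
   cA₁…cA_m (default m = 3, twelve candidate wavelet functions
   db1…sym6) are stacked into an n × p × m tensor. The undecimated
   transform keeps coefficient positions aligned with genes and smooths
   co-located genes into regional signals, damping isolated
   high-magnitude genes (e.g. mitochondrial transcripts).
2. **CNN.** The tensor feeds a fixed one-convolutional-layer network —
   conv(64 filters, length 8, relu, length-preserving) → max-pool(8,
   ceiling padding) → dense(32, relu) → softmax(2) — trained with RMSprop
   on the binary cross-entropy. For a 26,270-gene profile the pooling
   yields ⌈26270/8⌉ = 3,284 feature positions.
3. **Gene scoring.** The post-pooling activations, averaged over the 64
   filters, form the representative feature matrix *X* (f × n). The score
   matrix is the least-squares back-mapping **B = Y·Xᵀ(X·Xᵀ)⁺** (Moore–
   Penrose pseudoinverse; X·Xᵀ is singular when f > n), and each gene's
   importance is the mean of its row of B. Genes are ranked by descending
   score.
4. **Cox risk model.** The top-n genes (n tuned on 100…1000 by inner
   validation) are screened by univariate Cox regression (Efron ties,
   Wald p < 0.05), fitted jointly by multivariate Cox (ridge-penalized
   fallback on non-convergence), and combined into the risk score
   Σᵢ βᵢxᵢ. The ROC threshold maximizing Youden's J on the training set
   stratifies validation samples into high/low-risk groups, compared by
   Kaplan–Meier curves and the log-rank test.
5. **Protocol.** Repeated random 70/30 splits, rank-based AUC, and
   best-of-N network selection on an inner split; SVM (RBF, grid-searched),
   random forest and logistic-regression baselines behind a t-test +
   fold-change gene filter.

## Worked example

```bash
waverisk simulate --n-samples 300 --n-genes 512 --n-prognostic 10 \
    --effect-size 2.5 --seed 7 --outdir data
echo '{"epochs": 20, "n_runs": 2}' > cfg.json
waverisk pipeline --expression data/expression.tsv --clinical data/clinical.tsv \
    --config cfg.json --seed 7 --outdir run
```

prints (abridged):

```json
{
  "n_samples": 298, "n_train": 208, "n_validation": 90,
  "top_n": 400, "n_univariate_selected": 29, "signature_size": 11,
  "cnn_validation_auc": 0.518,
  "risk_score_validation_auc": 0.913,
  "logrank_statistic": 63.099, "logrank_p_value": 1.97e-15,
  "median_survival_high": 6.3, "median_survival_low": 148868.6
}
```

Reading: on this deliberately strong-signal cohort (10 planted prognostic
genes, log-hazard 2.5 per SD of log-expression — hence the extreme median
survival gap) the all-gene network alone is a weak classifier
(AUC 0.52), but the gene ranking it induces feeds a Cox signature of 11
genes whose risk score separates held-out patients well (AUC 0.91,
log-rank p < 1e-14). That ordering — risk-score model over all-gene
classifier — is the pipeline's central claim, and is what the acceptance
tests check across seeds. `run/` also receives the score table
(`gene_scores.tsv`), the univariate Cox table, the fitted network, the risk
model with its cutoff, the per-sample risk table and a manifest.

Other subcommands: `ingest` (validate + zero-fraction gene filter),
`train`, `score-genes`, `cox`, `stratify`, `benchmark` — each a thin
wrapper over the library (`waverisk <cmd> --help`).

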