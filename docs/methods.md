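# Methods

`hrclassify` predicts homologous-recombination (HR) status — deficient
(HRD) versus proficient (HRP) — in high-grade serous ovarian carcinoma
(HGSC) from bulk or pseudobulked single-cell RNA-seq counts.  The model
is an elastic-net penalized logistic regression over a signature of
differentially expressed genes; this note documents the statistical
procedure, its assumptions, the tunable parameters, and what the
synthetic study conditions can and cannot show.

## The classification problem

Roughly half of HGSCs carry defects in homologous-recombination DNA
repair that predict response to PARP inhibitors.  The clinical ground
truth is a genomic scar score (the unweighted sum of telomeric allelic
imbalance, loss-of-heterozygosity and large-scale transition counts),
dichotomized at **score ≥ 42 → HRD**.  Because HR deficiency leaves a
transcriptional footprint — in particular recurrent copy-number events
with expression consequences (8q24.2 amplification enriched in HRD,
5q13.2 loss in HRD, 19q12 amplification in HR-proficient tumours) — a
supervised classifier on expression alone can recover the genomic label
without DNA sequencing.

## Training procedure

1. **Gene-universe filter.**  Non-coding genes and genes on chrM/chrY
   are removed (annotation-driven; unannotated genes are dropped and
   counted in the report).
2. **Expression filter.**  A gene is retained iff its CPM (raw library
   sizes, no prior) is ≥ 10 in at least `ceil(0.7 × min(group sizes))`
   samples.  Both the threshold (10) and proportion (0.7) are exposed;
   the rule is implemented literally rather than delegating to any
   package's internal heuristic.
3. **TMM normalization.**  Composition bias between libraries is
   corrected with trimmed-mean-of-M-values factors: reference = the
   sample whose upper-quartile CPM is closest to the mean upper
   quartile; M-values trimmed at 30%, A-values at 5%; weights from the
   binomial delta-method variance; factors rescaled to geometric mean 1.
4. **Moderated differential expression.**  log2-CPM uses
   `log2((count + 0.5) / (eff_lib + 1) × 1e6)` (the doubled prior keeps
   zero counts finite).  A per-gene linear model with design
   `intercept + HRD indicator` (no other covariates) is fitted; the
   sqrt of the residual SD is smoothed against mean log2-count by
   lowess (span 0.5, 3 robustness iterations) and observation weights
   are the inverse fourth power of the predicted sqrt-SD — the standard
   precision-weighting treatment of the RNA-seq mean-variance trend.
   Residual variances are shrunk toward an empirical-Bayes prior
   (d0, s0²) estimated by closed-form moment matching on log-variances
   via the digamma/trigamma identities; robust mode winsorizes the
   log-variances at the (0.05, 0.10) tails first.  Moderated t
   statistics use d0 + d residual degrees of freedom.  Closed-form
   moment matching was chosen over iterative ML because it is
   deterministic and easily testable; the non-robust mode backs the
   analytic identity tests.
5. **Signature selection.**  Genes with Benjamini-Hochberg adjusted
   p < 0.05 (strict) form the signature, partitioned into up/down in
   HRD.  Arm-level enrichment of up- vs down-regulation is tested per
   chromosome arm with Yates-corrected chi-square (2×2: direction ×
   on-arm/elsewhere), Bonferroni-corrected over arms tested.
6. **Standardization.**  Counts are re-normalized to log2-CPM **with
   the library size computed over the signature genes only** and
   z-scaled per gene.  The per-gene mean and sample SD (n−1) are stored
   in the model bundle; prediction always reuses these stored
   statistics.  Training uses norm factor 1 at this stage so the
   transformation is identical to the prediction-time contract.
7. **Hyperparameter search.**  A grid of elastic-net mixing values
   α ∈ {0.00, 0.01, …, 1.00} is cross-validated with 5 stratified folds
   (fixed, recorded seed).  For each α a 100-value lambda path is built
   once on the full training matrix, log-spaced from
   `λ_max = max_j |x_jᵀ(y − ȳ)| / (N·max(α, 0.001))` down to
   `10⁻⁴·λ_max`, and refitted on each training fold with warm starts;
   out-of-fold AUC is computed at every lambda and the lambda
   maximizing the mean per-fold AUC is kept (larger lambda on ties).
   Building the path once per α rather than per fold keeps "mean AUC at
   a lambda" well defined across folds (this mirrors cv.glmnet).
8. **One-standard-error selection.**  Let α* maximize mean AUC with
   fold SD s*.  Among all α with mean AUC ≥ mean(α*) − s*, the α with
   the smallest fold SD is selected; ties break toward larger α (the
   sparser model).  The reference SD is that of the best α; an
   alternative mode admits each α within its own SD.  The final model
   refits the selected (α, λ) on the full training cohort — the
   CV-chosen λ is used directly, with no second CV.
9. **Label convention.**  Internally HRP = 1, so the raw linear-model
   probability is P(HRP); the reported probability of deficiency is
   P(HRD) = 1 − P(HRP).  The bundle records this convention.

## The solver

The penalized objective is

    (1/N) Σᵢ [log(1 + e^{ηᵢ}) − yᵢ ηᵢ]  +  λ[(1−α)/2·‖β‖₂² + α·‖β‖₁],
    η = β₀ + Xβ,   intercept unpenalized,

minimized by coordinate descent on the IRLS-weighted quadratic
approximation with soft-thresholding.  Implementation details:

- IRLS weights are clipped below at 1e-5; the working response is the
  usual `η + (y − p)/w`.
- The inner quadratic solve (numba-compiled) alternates full sweeps
  with active-set sweeps over the current support.
- A backtracking step between outer iterations guarantees the penalized
  objective never increases; convergence is declared when the largest
  parameter change falls below 1e-7 or the objective decrease vanishes
  (the latter handles separable data, where the unpenalized likelihood
  saturates while coefficients drift).
- Coefficients below 1e-10 in magnitude are reported as exact zeros
  when an L1 penalty is present, so support sizes are meaningful.
- Optimality is verified against the subgradient KKT conditions
  (residual ≤ 1e-5 in tests) and against a generic Powell minimizer of
  the same objective (≤ 1e-4 relative objective gap).
- Features are standardized once on the full training cohort; internal
  per-fit re-standardization is off, making the stored means/SDs the
  single source of truth.

## Prediction contract

Scoring a new cohort needs only raw counts and the bundle:

1. Subset to the signature genes in bundle order; genes absent from the
   input become all-zero rows and are reported (warning at any
   missingness; hard error above 50%, configurable).
2. Library size = per-sample sum over signature genes only; log2-CPM
   with prior 0.5 and norm factor 1 (no TMM against a reference cohort
   — scoring is strictly per-sample).
3. z-scale with the stored training means/SDs.
4. η = intercept + βᵀz; P(HRD) = 1 − logistic(η); **P(HRD) ≥ threshold
   → HRD**, threshold 0.5 by default.  A grid search over thresholds
   {0.00, …, 1.00} maximizing accuracy (smallest maximizer returned) is
   provided for cohort-specific recalibration.

## Benchmark classifiers

Three simpler transcriptomic rules are provided for comparison, all
operating on the same z-scored matrices: (a) 2-means clustering of a
gene signature (25 restarts, lowest within-cluster SS; the cluster with
the lower mean over designated marker genes is called HRD, ties calling
the first cluster HRP); (b) centroid correlation (Pearson r against an
HRD centroid; r > 0 → HRD, r ≤ 0 → HRP — the tie goes to HRP to avoid
over-calling the treatable class); (c) score thresholding at 42 with an
exhaustive integer cutoff search over 1–114.  Published centroid values
for external signatures are not redistributed; the centroid classifier
takes centroids as input and the test suite uses synthetic stand-ins.
Partition agreement is summarized by the adjusted Rand index
(permutation-model expectation).

## Synthetic study conditions

The generator draws, per sample: a binary label at 50% HRD prevalence;
a latent HRD score from truncated normals — HRP ~ N(20, 10²) on
[0, 42), HRD ~ N(62, 12²) on [42, ∞), so labels and scores are always
consistent with the 42 cutoff; a tumour purity ~ U(0.30, 1.00); and a
library size ~ log-normal with median 6×10⁷ reads.  Per gene: a
log-normal baseline abundance (log-SD 1.2) and a log-normal NB
dispersion (median 0.08).  Three regions plant effects on 50 genes
each: 8q24.2 up in HRD, 5q13.2 and 19q12 down in HRD, |log2FC| ~
U(0.5, 1.5).  A sample's realized shift is
`purity × [(1−c)·label + c·ramp(score)] × log2FC` with coupling
c = 0.5 and a logistic ramp centred at 42 (width 12): purity dilutes
tumour-specific shifts against a shared baseline, and the coupling
makes expression track the *continuous* score so that predicted
probabilities can correlate with it, as observed on real tumours.
Null genes are exchangeable NB draws.  A few non-coding/chrY/chrM decoy
genes exercise the upstream filters.  The default study size is 240
training and 60 held-out samples over 3000 coding genes (one cohort
split by sample so gene-level parameters are shared).

What the generator does **not** emulate: gene-gene co-expression,
batch and platform effects, subclonal heterogeneity, genome-wide
copy-number drift, and realistic single-cell dropout (cells are plain
multinomial draws from their parent profile).  Passing tests therefore
demonstrate correctness of the pipeline's machinery and its parameter
recovery under a favourable, well-specified model — not clinical
performance.

## Numerical choices and degenerate inputs

- Sample SD uses the n−1 denominator throughout and is persisted.
- Zero-variance genes abort standardizer fitting with the gene named.
- Constant labels, single-class folds, all-zero libraries, empty
  filters and empty signatures raise typed errors early.
- All-equal residual variances short-circuit the prior estimation to
  d0 = ∞ with s0² equal to the common variance (with a warning).
- Arm tests with degenerate 2×2 marginals report chi-square 0, p 1.
- The cytoband convention is 0-based half-open; genes are assigned by
  TSS when available, else interval midpoint — one deterministic
  assignment per gene.

## Known limitations

- **Missing-gene sensitivity at small signature sizes.**  The
  prediction library is the column sum over signature genes only, so a
  missing high-abundance gene shrinks the library share of every other
  gene and shifts all z-scores coherently.  With the default ~160-gene
  synthetic signature, zero-filling 4% of the signature can move
  held-out accuracy by well over 5 percentage points (the acceptance
  script reports the measured change).  At realistic signature sizes
  (thousands of genes) single-gene library shares are far smaller and
  the contract is correspondingly more robust; callers scoring cohorts
  with known missingness should inspect the missing-gene report.
- The CV grid (101 α × 5 folds × 100 λ) dominates training time;
  `TrainingConfig.alpha_grid` (or the CLI's `--alpha-step`) coarsens it
  when exploring.
- Probabilities are not recalibrated (no Platt/isotonic step); the
  threshold optimizer is the intended remedy when a labelled tuning
  cohort exists.
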