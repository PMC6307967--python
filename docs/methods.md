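# Methods

This note documents the models and procedures `episig` implements, the
assumptions behind them, the synthetic study conditions used for testing,
and the numerical choices made where the design was genuinely open. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Candidate discovery from paired stimulation experiments

Cultured airway epithelial cells stimulated with a cytokine are compared
with matched unstimulated cultures from the same donor. Counts are
normalized by **median-of-ratios size factors**: per sample, the median
over genes (restricted to genes with positive counts in every sample) of
the count over the gene's geometric mean, rescaled so the factors'
geometric mean is 1. Per gene, the paired response is

    d_i = log2((stim_i / sf + 1) / (ctrl_i / sf + 1)),   i = 1..pairs

with log2FC the mean of d_i, a two-sided paired t-test on the d_i, and
Benjamini–Hochberg step-up q-values. The top-k (default k = 100) genes by
descending log2FC among significant upregulated genes (FDR ≤ 0.05,
disableable) form the candidate set; ties break by ascending q then gene
id, so the set is a deterministic function of its inputs.

This stage is a deliberate simplification of negative-binomial GLM testing:
transparent, dependency-free, and adequate for *ranking* candidates by
fold change, which is all the downstream pipeline consumes. The +1 offset
inside the ratio keeps zeros finite and biases very small counts toward
zero fold change — acceptable here because candidates are, by
construction, strongly induced genes. Dispersion shrinkage and Wald/LRT
inference are out of scope.

## 2. Anchored elastic-net refinement

Culture models cannot reproduce the in-vivo environment, so the candidate
set is refined against an independent cohort: genes that do not co-vary
tightly with an *anchor* gene in vivo are discarded. The anchor (default
*CCL20*) is chosen a priori for biological specificity; its (centered)
log2 expression is the response, the other candidates the predictors, and
the fit minimizes the glmnet-parameterized objective

    (1/2n) Σᵢ (yᵢ − β₀ − xᵢᵀβ)² + λ (α‖β‖₁ + (1−α)/2 ‖β‖₂²).

* **α = 0.75**: just below pure lasso, keeping selection sparse while
  letting tightly correlated genes enter together.
* **Predictors standardized** to unit variance inside each CV fold
  (coefficients reported on the original scale); the response is centered.
  Both are configurable.
* **λ grid**: 100 log-spaced values from λ_max = maxⱼ|xⱼᵀy|/(nα) down to
  10⁻³ λ_max.
* **Cross-validation**: leave-one-out by default (k-fold available).
* **λ rule**: the **one-standard-error rule** — the largest λ whose CV MSE
  is within one SE of the minimum. The minimal-MSE rule is available but
  not the default: on this problem (one strongly co-regulated block among
  many independent decoys) the CV minimum is shallow and systematically
  drags spurious predictors into the model, whereas the 1-SE rule recovers
  the planted block with essentially no false selections and returns an
  empty model on null data. Solving delegates to scikit-learn's
  coordinate descent, whose objective matches the form above exactly.
* Degenerate cases: constant predictor genes are dropped with a warning;
  a CV fold with constant response is skipped with a warning.

The selected genes plus the anchor form the signature. A pairwise
intercorrelation check (Spearman by default, min ρ = 0.3 — the notion of
"intercorrelated" is not standardized, so both are configurable) verifies
that the refinement actually removed loosely correlated genes.

**Platform adaptation.** When a signature is carried to another platform
or tissue, genes absent from the platform annotation are excluded (reason
`unannotated`) and genes not expressed above background in the target —
expression above a configurable threshold in fewer than 10% of samples —
are excluded (reason `background`). Exclusions are recorded in the
signature file so scoring can skip them without error; excluding the
anchor itself is flagged but not fatal.

## 3. Scoring

The signature score of sample *s* is the unweighted mean over signature
genes *g* of x_gs − mean_ref(x_g), with the centering reference defaulting
to all samples of the matrix being scored. Consequences worth knowing:

* scores are relative to the scored dataset (cohort mean 0 by
  construction); cross-dataset score comparability is *not* claimed;
* the score is invariant to per-gene additive shifts (platform offsets);
* elastic-net coefficients are *not* used as weights — the metric is the
  plain mean, so it transfers across platforms that preserve rank scale.

`standardized_mean` mode (per-gene z-score over the reference, then mean,
using the sample SD) serves ad-hoc gene-set covariates; "standardized" is
interpreted as per-gene z-scoring, an assumption rather than a settled
convention.

qPCR input is supported by reference-gene normalization: expression(g, s)
= mean(Ct of reference genes in s) − Ct(g, s), i.e. ΔCt in log2 units
(one cycle = one doubling), with reference-gene rows retained.

## 4. Dichotomization into signature-high / low

Because smoking strongly shifts airway gene expression, cohorts are first
stratified by smoking status. Within each stratum:

1. Samples are clustered on the **samples × signature-genes matrix**
   (per-stratum centered) with Euclidean distance and **average linkage**
   (UPGMA, implemented with the exact Lance–Williams average update;
   distance ties break deterministically toward the lexicographically
   smallest pair of minimal member ids).
2. The number of clusters k ∈ {2..6} is chosen by **majority vote of a
   declared panel of 8 internal validity indices**: Calinski–Harabasz,
   mean silhouette, Davies–Bouldin, Dunn, C-index, McClain–Rao,
   point-biserial, and a WSS elbow (largest second difference). Each
   defined index votes for its optimal k; undefined indices abstain; vote
   ties resolve toward smaller k. The panel replaces the much larger
   index collections of R clustering packages, many of whose members are
   redundant or underspecified; the contract is "majority vote over a
   declared panel", and the panel is config-extensible.
3. The largest cluster anchors the "low" group; every cluster whose mean
   score exceeds the majority cluster's mean is merged into "high"
   (multiple high clusters are common — indices often split the high tail
   further); clusters *below* the majority mean (low-scoring outliers)
   stay low.
4. The **partition boundary** is the midpoint between the minimum high
   score and the maximum low score — the original description never
   defines the partition geometrically, so this score-axis midpoint is
   this package's documented choice. The round(0.10 · n_stratum) samples
   nearest the boundary are relabeled `trimmed` (per-stratum, also a
   documented choice since global-vs-stratum trimming is unstated), and
   remaining labels are made consistent with the boundary so that every
   untrimmed high score strictly exceeds every low score.

Strata with fewer than 4 samples are skipped with a warning. If no
cluster sits above the majority mean the stratum is all-low and no
boundary or trimming exists (warned). The top-quartile rule (high iff
score ≥ 75th percentile, linear interpolation, boundary ties high) is the
alternative cutoff.

Note an inherent property of boundary trimming: samples near the boundary
are drawn from both modes in roughly equal numbers, so when the high mode
is the minority, trimming depletes it disproportionately — the recovered
high fraction among untrimmed samples sits a couple of points below the
population fraction even when every untrimmed label is correct.

## 5. Association models

* **Cross-sectional**: OLS (logistic for binary outcomes) of the outcome
  on score plus covariates (age and smoking status in the canonical
  adjusted model); Wald p for the score term; optional BH adjustment
  across a declared outcome family. Rank-deficient designs are rejected
  naming a redundant column.
* **Trial interaction**: Δoutcome = b₀ + b₁·trt + b₂·score +
  b₃·(trt×score) + covariates, by OLS; b₃, its Wald p and 95% CI, and the
  r² of the score-only model within the treated arm are reported.
  Secondary adjustment variants (tissue eosinophils, type-2 score,
  neutrophils, macrophages) enter through the covariates argument;
  combining active arms is a metadata-preparation step, not hard-coded.
* **Longitudinal**: random-intercept linear mixed model (REML, via
  statsmodels) of the score on treatment, time, and treatment×time, with
  subject as the grouping factor. The interaction's Wald statistic is
  referred to a t distribution with **between-within degrees of freedom**
  df = (N − n_subjects) − 2 (the within-subject fixed terms): the
  asymptotic normal reference is anticonservative at trial-sized designs,
  while this df reduces exactly to the two-sample t test on per-subject
  changes in the balanced pre/post case, and the simulated null rejection
  rate is nominal with uniform p-values.
* **Biomarker performance**: AUC is the Mann–Whitney probability computed
  via midranks (identical to the all-pairs count with ½ for ties).
  For the dichotomized signature, "high" is the test-positive call for
  steroid unresponsiveness, operationalized as no improvement
  (Δoutcome ≤ 0) over the trial; specificity = TN/(TN+FP) among
  responders. Trimmed samples are excluded before the 2×2 table.

## 6. Synthetic study conditions

The generators define the conditions every recovery test runs under; they
emulate the workflow's two platforms (NB counts for sequencing-like
cultures, Gaussian log2 noise for array-like cohorts) and record all
planted truth.

**Stimulation** (`gen_stimulation`): 6 donor pairs, 1000 genes; baseline
means log-normal (log2 mean 6, SD 1.5); NB dispersion 0.05; shared
per-donor effect SD 0.2 log2 units; per-sample depth SD 0.25 log2 units.
100 genes respond: the anchor at log2FC 2.92, the top responder at 8.51
(the fold changes the pipeline is expected to recover), the rest between
1 and 6.

**Cohort** (`gen_cohort`): n = 200; 100 candidate genes of which an
11-gene block (anchor loading 1.0, others uniform 0.7–0.95) shares a
bimodal latent activity L; the other 89 are independent decoys. L is a
two-group mixture: fraction π_high = 0.31 sits Δ = 2.0 log2 units above
the low group (about four per-gene residual SDs at noise SD 0.5), with
within-group jitter SD 0.25. The high subgroup is enriched in former
smokers (P(high) 0.36 vs 0.26) and the block genes carry a direct smoking
effect (0.4 × loading), so former smokers score visibly higher while the
high subgroup remains a within-stratum minority — the structural premise
of majority-cluster dichotomization. Age adds a small latent slope
(0.01/yr). `delta_for_score_separation(s)` returns the Δ at which the two
modes sit s score-SDs apart (the score's own SD being the scale on which
group separations of the signature are naturally expressed); the
dichotomization recovery tests run at s = 2. What the generator does
*not* model: full-transcriptome covariance, batch effects, platform
probe-level artifacts — so passing tests demonstrate estimator
correctness under the stated model, not robustness to real-data
pathologies.

**Trial** (`gen_trial`): 33 active / 16 placebo; Δ = b₀ + b_trt·trt +
b_score·score + b_int·trt·score + ε with defaults b₀ = −2, b_trt = 2,
b_score = 0, **b_int = −5** percentage points of FEV₁ per score unit,
σ = 6, baseline-score SD 0.66. Under these conditions the score-only
model within the treated arm explains on the order of a quarter of the
outcome variance; the acceptance script computes the realized value.

**Longitudinal** (`gen_longitudinal`): 6 treated / 4 placebo subjects,
biopsies at weeks 0 and 2; lesional baseline latent 2.0 (SD 0.3) above
nonlesional tissue; treated-arm latent declines 0.75/week; subject
random-intercept SD 0.3; expression generated from the latent exactly as
in the cohort model, restricted to the 7 skin-expressed signature genes.

All generators are fully determined by their seed.

## 7. Problem sizes used by the test and acceptance runs

Oracle checks: 1000 random p-vectors (length ≤ 200) against a
from-definition BH step-up; 20 small elastic-net instances (n ≤ 20,
p ≤ 3) against a direct numerical minimizer of the penalized objective
(agreement 1e-6); 50 random 12-point instances against a from-scratch
O(n³) UPGMA (exact, including tie-breaks); validity indices against
sklearn/brute-force formulas on ≤ 10-point instances; AUC against the
all-pairs construction for n ≤ 50. Recovery checks: 20 seeds for anchored
selection and dichotomization, 200 for interaction coverage and mixed
power, 1000 for the interaction and mixed-model nulls (500 in the
acceptance script). These sizes make the full suite and the acceptance
script each run in a few minutes on one core.

## 8. Known limitations

* The DE stage ranks well but its t-test p-values are not a substitute
  for NB inference at small counts.
* Signature scores are dataset-relative; "high"/"low" cutoffs are
  population-dependent by construction.
* The validity-index panel is a representative subset; a different panel
  can change the chosen k on ambiguous data (the vote table is returned
  for audit).
* Mixed-model degrees of freedom use a between-within approximation, not
  a Satterthwaite/Kenward–Roger correction.
* The generators' covariance structure is block-plus-noise; conclusions
  about real cohorts require real cohorts.
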