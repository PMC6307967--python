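# episig

Airway epithelial cytokine-response gene signatures: derivation, scoring,
dichotomization, and clinical association models.

## The problem

Chronic obstructive pulmonary disease (COPD) is biologically heterogeneous,
and only some patients respond to inhaled corticosteroids. One way to find
treatment-relevant subgroups is to measure how a patient's airway
epithelium is responding to a specific cytokine — here, an IL-17-driven
inflammatory program — via a compact gene-expression signature. `episig`
implements that workflow end to end, for bioinformaticians analyzing
bulk airway-epithelial transcriptomes (RNA-seq cultures, microarray or
qPCR cohorts):

1. **Candidate discovery** (`stim_de`): paired stimulated-vs-control
   cultures are normalized by median-of-ratios size factors; genes are
   ranked by mean paired log2 fold change with a paired t-test and
   Benjamini–Hochberg FDR; the top-*k* (default 100) upregulated genes
   become candidates.
2. **Anchored refinement** (`signature_refine`): in an independent in-vivo
   cohort, an elastic net (α = 0.75, leave-one-out CV) regresses a
   biologically chosen *anchor* gene (e.g. the Th17-recruiting chemokine
   *CCL20*) on the remaining candidates:

       min over (β₀, β) of  (1/2n) Σᵢ (yᵢ − β₀ − xᵢᵀβ)²
                            + λ [α‖β‖₁ + ((1−α)/2)‖β‖₂²]

   Nonzero-coefficient genes at the cross-validated λ, plus the anchor,
   form the signature. Selection is independent of clinical outcomes.
3. **Scoring** (`signature_score`): each sample's score is the mean of the
   zero-centered log2 expression of the signature genes (equal weights);
   a per-gene z-score variant serves generic gene-set covariates such as
   the 3-gene type-2 score (*POSTN*, *SERPINB2*, *CLCA1*).
4. **Dichotomization** (`discretize`): within smoking strata, samples are
   clustered on the signature genes (Euclidean, average linkage); the
   number of clusters is chosen by majority vote of 8 internal validity
   indices; clusters scoring above the majority cluster are "high"; 10% of
   samples nearest the high/low score boundary are trimmed. A top-quartile
   rule is the simpler alternative.
5. **Association models** (`assoc_models`): covariate-adjusted linear and
   logistic regressions, treatment × baseline-score interaction on change
   in FEV₁ in a randomized trial, random-intercept mixed models for
   repeated biopsies, ROC/AUC and 2×2 sensitivity/specificity for the
   dichotomized signature.

Every stage is testable without external data: `synthetic_data` generates
stimulation experiments, cohorts, trials, and longitudinal designs with
planted, recorded truth (negative-binomial counts for cultures, Gaussian
log2 noise with a bimodal latent activity factor for cohorts).

## Worked example

```bash
# generate a paired stimulation experiment and an in-vivo cohort
episig simulate --what stimulation --seed 7 --out sim/
episig simulate --what cohort --seed 7 --out sim/

# derive -> score -> discretize -> associate from one config
cat > config.yaml <<EOF
inputs:
  counts: sim/counts.tsv
  pairs: sim/pairs.tsv
  cohort: sim/cohort.tsv
  metadata: sim/metadata.tsv
EOF
episig run --config config.yaml --out run/
```

prints

```
pipeline complete: 4 stages -> run/
```

and leaves in `run/`: `signature.json` (here a 10-gene signature anchored
on *CCL20*: the anchor plus 9 elastic-net-selected co-varying genes),
`scores.tsv` (per-sample scores; mean 0 by construction), `labels.tsv`
(per-sample high/low/trimmed with stratum and score; here 24.6% of
untrimmed samples labeled high against a planted subgroup fraction of
31%), `associations.tsv` (the score's adjusted association with FEV₁ %
predicted), and `manifest.json` (parameters, seeds, and sha256 checksums —
re-running the same config reproduces byte-identical outputs).

Individual stages are also available as `episig derive/score/discretize/
associate`, and as plain library calls (`episig.signature_refine.
elastic_net_select`, `episig.discretize.stratified_discretize`, ...).

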