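# Methods

This note documents the models, numerical choices and limitations of
each stage, and what the synthetic cohorts do and do not emulate.

## Synthetic cohorts (`syndata`)

The generator produces the statistical structure the analysis assumes,
with every planted quantity recorded in a `CohortTruth` ledger.

* **Signature matrix.** A marker-block design: each of the (default 22)
  cell types owns a disjoint block of `n_genes // n_cell_types` marker
  genes whose expression in that type is ~10× a log-normal background
  (fold ≥ 8 guarantees identifiability, so deconvolution failures
  indicate bugs rather than ill-posedness). Cell-type labels mirror the
  usual 22-type immune panel.
* **Cell fractions.** Dirichlet draws per planted subtype — simplex-valid
  by construction and with closed-form expectations for recovery tests.
  The default three subtypes concentrate mass on a myeloid/resting axis
  (I), a cytotoxic "hot" axis (II: CD8 T, M1 macrophages, plasma cells,
  activated memory CD4, memory B, activated DC) and a naive "cold" axis
  (III); a two-subtype hot/cold design serves binary-truth experiments.
* **Expression.** `S · F` plus Gaussian noise with sd =
  `noise_sd × gene mean` (default 0.1), clipped at zero. Batch effects
  are planted on the log2(x+1) scale — an additive per-gene offset and a
  multiplicative scale about the grand mean — because that is the scale
  on which technical shifts between merged cohorts act and on which the
  correction operates. Batch assignment is a randomized balanced draw;
  a cyclic assignment would confound batch with the (cyclic) subtype
  layout and make batch correction erase biology.
* **Survival.** Exponential event times with rate `baseline_hazard ×
  hazard_multiplier(subtype)` (per month) and independent exponential
  censoring whose rate is calibrated against the mean event rate to hit
  the requested censored proportion. Proportional multipliers make
  log-rank/Cox recovery targets closed-form (median = ln 2 / λm).
* **Mutations.** Per sample, a Poisson number of non-silent records with
  mean `tmb_true × exome_mb`, distributed uniformly over genes with a
  missense-dominated class mix, plus a Silent stream to exercise the
  class filter. `tmb_true = 1 + 6 × hot_score` couples mutation burden
  positively to the immune-hot axis (hot_score = summed hot-type
  fractions).
* **Drug training.** Cell-line expression i.i.d. log-normal; per drug,
  log-IC50 is a sparse linear function (5 active genes) of z-scored
  expression plus N(0, noise_sd) noise.

What the generator does **not** emulate: realistic transcriptome-wide
correlation (genes are conditionally independent given fractions),
cell-type-internal expression variability, copy-number structure, or
non-proportional hazards. Passing tests therefore demonstrate that the
algorithms recover their planted targets under the stated model, not
that they are robust to every property of real tumor data.

## Preprocessing

`fpkm_to_tpm` is the per-sample renormalization TPM = FPKM / ΣFPKM ×
10⁶. `combat_correct` is parametric empirical-Bayes batch correction:
log2(x+1) values are gene-wise standardized against the grand mean and
pooled variance; per-batch location γ and scale δ² estimates are shrunk
toward a normal and an inverse-gamma prior whose hyperparameters come
from method-of-moments fits across genes, iterating the standard fixed
point to relative tolerance 1e-4; corrected values are rescaled and
back-transformed with negatives clipped at 0. Choices: the log scale is
the convention for expression batch correction (the input is linear
TPM-like data); a non-parametric mode replaces the parametric posterior
by a likelihood-weighted average over the other genes' estimates (O(G²),
for small panels; its residual gaps are larger because it borrows
strength indiscriminately); genes with zero pooled variance pass through
untouched with a warning, since merged cohorts routinely contain them;
a batch with one sample raises (its scale is undefined). With a single
batch the function is exactly the identity. Note the EB scale step
leaves sampling noise of order |z|·√(2/n)/2 on extreme entries even for
null batches — the correction is an approximate identity there, not an
exact one.

## Deconvolution

`svr_deconvolve` follows the ν-SVR recipe: over the genes shared with
the signature, the signature matrix is standardized **jointly** (one
grand mean and sd for the whole matrix, preserving relative scales
between cell types) and each mixture column is z-scored; a linear ν-SVR
is fit for ν ∈ {0.25, 0.5, 0.75} and the fit with the lowest
reconstruction RMSE wins; negative coefficients are clamped to zero and
the rest renormalized to the simplex; per-sample RMSE and Pearson fit
correlation are reported. Joint (not per-column) standardization is what
makes recovery of pure types and of noiseless mixtures exact up to
solver tolerance. C = 1 (the libsvm default): larger values buy nothing
measurable in accuracy and slow convergence on noisy mixtures by orders
of magnitude. An NNLS backend on the raw scale is kept as the exact
oracle for noiseless mixtures and as a fast alternative; quantile
normalization is not applied (TPM-scale input). The empirical
permutation p-value compares the observed fit correlation against
gene-permuted mixtures with add-one smoothing, p ∈ [1/(n_perm+1), 1].
`estimate_scores` scores immune/stromal panels by ssGSEA; the published
purity polynomial is out of scope since only the scores feed downstream.

## Consensus clustering

For each of `n_reps` repetitions a fraction (default 0.9) of items is
drawn without replacement, hierarchically clustered under the chosen
distance (1 − Pearson/Spearman correlation, or Euclidean) and linkage,
and cut at *k*; consensus(i,j) = co-clustering count / co-sampling count
(0/0 → 0). The final partition clusters 1 − consensus with **average**
linkage (the hierarchical-consensus convention). Ward on a precomputed
dissimilarity follows the Ward.D2-style update scipy implements.
Subsampling draws items only, not features. Constant items under a
correlation distance get zero distance with a warning. Runs are
bit-reproducible under a seed; group labels are canonicalized by first
appearance. Diagnostics report the CDF area of off-diagonal consensus
values, its increment over the previous *k*, and PAC = CDF(0.9) −
CDF(0.1). The reference repetition count is 500; 100 is the default
here because on separable data the consensus matrix is already crisp
(PAC ≈ 0) and ARI = 1 — the workflow fixes *k* = 3 and reports
diagnostics rather than auto-selecting *k*.

## Differential expression

The moderated *t*: per gene an ordinary two-group fit gives the mean
difference β, residual variance s² and df *d*; hyperparameters
(d₀, s₀²) are fit by matching the mean and variance of log s² to their
theoretical digamma/trigamma moments, inverting the trigamma by Newton
iteration (tol 1e-8; divergence falls back to a fully pooled prior,
d₀ = ∞); the posterior variance is the precision-weighted blend and the
statistic gains d₀ extra df. d₀ = 0 reproduces the ordinary
equal-variance *t* exactly. BH adjustment evaluates the step-up
definition q_i = min_{j≥i} p_(j)·m/j literally (bit-identical to a
brute-force evaluation of the definition). DEG selection runs
one-vs-rest contrasts on log2(x+1) (the contrast design and FC scale
are conventions chosen here: a linear fold of 1.5 ⇔ |log2fc| >
log2 1.5, strict; BH within each contrast). A DEG is assigned to the
cluster with the highest mean expression among contrasts where it is
significantly up-regulated; the rare purely-down DEG falls back to the
overall highest-mean cluster so that assignment exists iff the cutoffs
pass.

## ICI score

Signature assignment correlates each DEG with a numeric encoding of the
gene clusters — by default the clusters ranked by mean immune score, so
"higher" is reproducibly the immune-hot direction (an indicator
encoding of the top cluster is available); r > 0 → set A, r < 0 →
set B, r = 0 or undefined → dropped with a warning. Boruta pairs every
candidate with a permuted shadow copy, scores both with a random-forest
importance backend, counts hits against the best shadow, and decides by
one-sided binomial tests at a Bonferroni-corrected α (tentative
features at the iteration cap are resolved by comparing median
importance to the median best-shadow importance, so every gene receives
a decision). Boruta's target is the gene-cluster label (the
construction is about cluster-discriminating genes, not survival).
ssGSEA ranks a sample's genes (average ranks on ties; descending walk
is stable-sorted for determinism), weights set genes by rank^0.25, and
integrates the difference between the cumulative weighted in-set curve
and the uniform out-of-set curve; no across-sample normalization is
applied since only within-cohort differences are used. The ssGSEA ICI
score is score A − score B with a median split (ties to "low" —
deterministic and conservative). The PCA variant z-scores the genes of
each set, projects on the set's first principal component, orients each
component to correlate positively with the immune score (PCA sign is
arbitrary), and combines as |PC1_A| + |PC1_B| (the literal "absolute"
mode) or PC1_A − PC1_B ("difference" mode). The absolute form destroys
direction, so survival-facing analyses use the difference mode; both
are exposed rather than guessing a single intent. The univariate
prognostic screen (Cox p < 0.05, no multiplicity correction) applies
only to the PCA variant.

## Survival

The product-limit estimator is computed directly with the classic
conventions stated explicitly: subjects censored exactly at an event
time count as at risk at that time; uncertainty is the Greenwood
variance. Log-rank (k groups, hypergeometric variance, χ² with k−1 df)
and Cox fits are delegated to lifelines. lifelines handles ties by the
Efron method; with continuous simulated event times ties do not occur
and Efron and Breslow coincide. Non-convergent Cox fits (monotone
likelihood) are flagged with NaN and the gene excluded with a warning.
The prognostic screen uses univariate Cox on z-scored continuous
expression rather than a median-split log-rank — it needs no extra
threshold parameter.

## Mutation / TMB

MAF parsing is case-insensitive on headers, skips `#` comments and
preserves unknown columns. TMB = non-silent records / exome_mb with the
standard non-silent class set (missense, nonsense, frameshifts,
in-frame indels, splice site, translation start, nonstop); Silent,
UTR and intronic classes are excluded. The default denominator is
38 Mb, a common whole-exome convention, and configurable because
reported TMB values depend on it. Samples on a roster but absent from
the MAF get TMB 0. Group comparisons use the rank-sum (2 groups) or
Kruskal–Wallis (> 2) tests; the TMB-score association is Pearson r with
the t-distribution p.

## Drug sensitivity, enrichment, rank statistics

Drug response is a per-drug ridge regression of log-IC50 on cell-line
expression z-scored with training statistics (zero-variance genes
dropped), the penalty chosen by efficient leave-one-out cross-validation
over a log-spaced grid (1e-2…1e3, 13 points). Prediction standardizes
tumor expression with the stored training moments, imputes absent genes
at z = 0 and refuses to run below 50 % gene overlap. Drugs are ranked
between ICI groups by two-sided rank-sum p (ties broken by effect
magnitude, direction = sign of the median difference).

Preranked GSEA uses the weighted Kolmogorov–Smirnov running sum (hit
steps ∝ |score|^weight, miss steps 1/(N−|set|)), ES = the deviation of
maximum magnitude. The null permutes gene labels (equivalently,
re-draws the set's positions) — a deliberate divergence from
phenotype-permutation GSEA, appropriate because the input is already a
preranked list; NES divides by the mean |null ES| of matching sign and
p is one-sided on the matching sign with add-one smoothing. ORA is the
upper hypergeometric tail with BH across terms. The rank-sum test is
exact for min(n) ≤ 8 without ties and a tie-corrected normal
approximation otherwise; fully tied data returns p = 1 by convention.

## Pipeline

`run_pipeline` wires simulate → batch-correct → deconvolve → cluster →
DEG → gene-cluster → signature/score → survival → TMB → drugs →
enrichment from one config dict (YAML via the CLI), with per-stage
seeds derived by hashing the master seed and stage name, independent
stage toggles, and a JSON manifest of parameters, seeds and outputs.
Reruns with the same config are reproducible. Default problem sizes
(200 samples, 220 genes, 100 consensus repetitions, 30 Boruta
iterations with 60 trees) are chosen so a full run completes in well
under a minute on one CPU while every recovery property is comfortably
detectable; the validation script scales the prognosis experiment to
600 samples, where the planted hazard ratio of 2 separates the high/low
ICI groups decisively.

## Known limitations

Deconvolution reports relative fractions only (no absolute mode);
ComBat supports no protected covariates; the moderated-t design has no
covariates or count weighting; Cox is univariate; GSVA-style kernel
CDF scoring, driver-gene clustering and CNV analysis are out of scope.
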