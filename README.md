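# iciscope

Immune-cell-infiltration (ICI) scoring for bulk tumor expression cohorts.

Bulk tumor RNA profiles mix malignant, immune and stromal cells. A
recurring analysis pattern in tumor-immunology studies turns that mixture
into a per-patient immune score that stratifies prognosis and predicted
therapy response:

1. **Deconvolution.** Estimate the relative abundance of 22 immune cell
   types per sample by linear ν-support-vector regression of the
   (standardized) bulk profile on an LM22-style signature matrix *S*
   (CIBERSORT approach): solve for *f ≥ 0, Σf = 1* in *m ≈ S f*, and add
   per-sample immune/stromal enrichment scores (ssGSEA over gene panels,
   ESTIMATE approach).
2. **Immune subtypes.** Subsampled consensus clustering of samples on
   their 22 fractions (90 % subsamples, Spearman distance, Ward linkage,
   *k* = 3) gives ICI clusters; the consensus matrix records pairwise
   co-clustering frequency.
3. **Differential expression.** Empirical-Bayes moderated *t* between
   subtypes (variance shrinkage with method-of-moments prior
   *d₀, s₀²*), DEGs at |FC| > 1.5 and BH-FDR < 0.05; a second consensus
   clustering on DEG expression (Pearson distance, complete linkage)
   yields gene clusters.
4. **ICI score.** DEGs positively correlated with the immune-hot
   ordering of the gene clusters form signature set **A**, negatively
   correlated ones set **B**; both are reduced by the Boruta
   all-relevant selector; per patient,
   `ICI score = ssGSEA(A) − ssGSEA(B)`, median-split into high/low
   groups (a PCA-projection variant is also provided).
5. **Downstream.** Kaplan–Meier/log-rank and univariate Cox survival,
   tumor mutation burden from MAF files (non-silent mutations per Mb),
   ridge-regression drug-sensitivity transfer from cell lines
   (log-IC50), preranked GSEA and hypergeometric over-representation.

Real cohorts of this kind are access-controlled downloads, so the
package ships a synthetic-cohort generator (`iciscope.syndata`) that
plants known cell fractions, subtypes, batch effects, survival hazards,
TMB and drug effects — every stage is validated by recovering what was
planted.

## Worked example

Run the full workflow on a small simulated cohort:

```
iciscope run --config configs/demo.yaml --out runs/demo --seed 11
```

prints

```
{
 "n_degs": 90,
 "n_signature_A": 34,
 "n_signature_B": 41,
 "logrank_ici_group_p": 0.19260622561294344,
 "elapsed_s": 2.71
}
```

meaning: 90 genes passed the DEG cutoffs between the three immune
subtypes, the Boruta-reduced signature kept 34 set-A and 41 set-B genes,
and at this demo size (80 patients) the high/low ICI split does not yet
separate survival (log-rank p = 0.19; the planted hazard contrast is
detected reliably from n ≈ 600, see the acceptance script). The run
directory contains every stage's output (`fractions.tsv`,
`ici_clusters.tsv`, `degs.tsv`, `ici_scores.tsv`, `tmb.tsv`,
`drug_ranking.tsv`, `gsea.tsv`, …) plus `manifest.json` with all seeds
and parameters.

The same stages are available as library calls
(`deconv.svr_deconvolve`, `consensus.consensus_cluster`,
`dge.select_degs`, `ici_score.compute_ici_score_ssgsea`, …) and as
sklearn-style estimators (`SVRDeconvolution`, `ConsensusCluster`,
`BorutaSelector`, `RidgeIC50`) that compose with sklearn pipelines.

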