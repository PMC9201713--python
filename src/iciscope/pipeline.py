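"""End-to-end orchestration of the ICI scoring workflow.

``run_pipeline`` executes simulate -> batch-correct -> deconvolve ->
consensus-cluster -> differential expression -> ICI score -> survival ->
TMB -> drugs -> enrichment from a single configuration dict, writing each
stage's outputs as TSV under the run directory plus a JSON manifest with
every seed and parameter. Stages consume only prior-stage files/objects,
may be toggled off independently, and a rerun with the same configuration
is reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from iciscope import (consensus, deconv, dge, downstream, ici_score, io,
                      mutation, preprocess, survival, syndata)

DEFAULT_CONFIG: dict = {
    "n_samples": 200,
    "n_genes": 220,
    "n_cell_types": 22,
    "noise_sd": 0.1,
    "batch_spec": {"n_batches": 2, "shift": 1.0, "scale": 1.2,
                   "offset_sd": 0.2},
    "hazard_multiplier": {"I": 1.0, "II": 0.5, "III": 2.0},
    "baseline_hazard": 0.02,
    "censor_rate": 0.3,
    "k": 3,
    "n_reps": 100,
    "subsample_fraction": 0.9,
    "fc_cut": 1.5,
    "fdr_cut": 0.05,
    "alpha": 0.05,
    "exome_mb": 38.0,
    "boruta_max_iter": 30,
    "boruta_trees": 60,
    "deconv_backend": "svr",
    "n_drugs": 12,
    "n_drug_lines": 120,
    "gsea_perms": 200,
    "seed": 7,
    "stages": {"mutation": True, "drugs": True, "enrichment": True,
               "pca_score": True},
}


def _seed_for(base: int, stage: str) -> int:
    h = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31 - 1)


def run_pipeline(config: dict | None = None,
                 out_dir: str | Path = "run") -> dict:
    """Run the full workflow; returns a results dict and writes TSVs plus
    ``manifest.json`` under ``out_dir``."""
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    stages = dict(DEFAULT_CONFIG["stages"])
    stages.update((config or {}).get("stages", {}))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    t0 = time.time()
    results: dict = {}

    # --- simulate ---------------------------------------------------
    sig = syndata.make_signature_matrix(
        cfg["n_genes"], cfg["n_cell_types"], seed=_seed_for(seed, "sig"))
    profiles = cfg.get("subtype_profiles")
    if profiles is not None:
        profiles = {k: np.asarray(v, dtype=float)
                    for k, v in profiles.items()}
    expr, truth = syndata.simulate_bulk_cohort(
        sig, n_samples=cfg["n_samples"], noise_sd=cfg["noise_sd"],
        subtype_profiles=profiles,
        batch_spec=cfg["batch_spec"],
        hazard_multiplier=cfg["hazard_multiplier"],
        seed=_seed_for(seed, "cohort"))
    clinical = syndata.simulate_survival(
        truth, baseline_hazard=cfg["baseline_hazard"],
        censor_rate=cfg["censor_rate"], seed=_seed_for(seed, "surv"))
    io.write_expression(sig, out / "signature.tsv")
    io.write_expression(expr, out / "expression.tsv")
    io.write_clinical(clinical, out / "clinical.tsv")
    io.write_truth(truth.to_dict(), out / "truth.json")
    gene_sets = syndata.make_gene_sets(sig)
    io.write_gmt(gene_sets, out / "panels.gmt")

    # --- preprocess (batch correction) ------------------------------
    expr_bc = preprocess.combat_correct(expr, truth.batch)
    io.write_expression(expr_bc, out / "expression_combat.tsv")

    # --- deconvolution + immune/stromal scores ----------------------
    frac = deconv.svr_deconvolve(expr_bc, sig,
                                 backend=cfg["deconv_backend"])
    fractions = frac[sig.columns.tolist()]
    scores = deconv.estimate_scores(expr_bc, gene_sets["IMMUNE"],
                                    gene_sets["STROMAL"])
    frac.join(scores).to_csv(out / "fractions.tsv", sep="\t",
                             index_label="sample")
    results["fractions"] = fractions
    results["immune_scores"] = scores

    # --- consensus clustering on fractions (immune subtypes) --------
    ici_res = consensus.consensus_cluster(
        fractions, k=cfg["k"], n_reps=cfg["n_reps"],
        subsample_fraction=cfg["subsample_fraction"],
        distance="spearman", linkage="ward",
        seed=_seed_for(seed, "cluster"))
    io.write_labels(ici_res.labels, out / "ici_clusters.tsv")
    results["ici_clusters"] = ici_res.labels

    # --- DEGs between immune subtypes -------------------------------
    deg_table = dge.select_degs(expr_bc, ici_res.labels,
                                fc_cut=cfg["fc_cut"],
                                fdr_cut=cfg["fdr_cut"])
    deg_table.to_csv(out / "degs.tsv", sep="\t")
    degs = deg_table.index[deg_table["cluster"] != ""].tolist()
    results["degs"] = degs
    if len(degs) < 4:
        raise RuntimeError("dge stage found too few DEGs to continue")

    # --- gene clusters on DEG expression ----------------------------
    deg_expr = expr_bc.loc[degs]
    gene_res = consensus.consensus_cluster(
        deg_expr.T, k=cfg["k"], n_reps=cfg["n_reps"],
        subsample_fraction=cfg["subsample_fraction"],
        distance="pearson", linkage="complete",
        seed=_seed_for(seed, "genecluster"))
    io.write_labels(gene_res.labels, out / "gene_clusters.tsv")
    results["gene_clusters"] = gene_res.labels

    # --- ICI signature genes + scores -------------------------------
    sets = ici_score.assign_signature_genes(
        deg_expr, gene_res.labels, immune_score=scores["immune_score"])
    reduced = {}
    for name, genes in (("A", sets.set_A), ("B", sets.set_B)):
        if len(genes) > 2:
            kept = ici_score.boruta_reduce(
                expr_bc.loc[genes].T, gene_res.labels,
                max_iter=cfg["boruta_max_iter"],
                n_estimators=cfg["boruta_trees"],
                seed=_seed_for(seed, f"boruta{name}"))
            reduced[name] = kept if len(kept) >= 2 else genes
        else:
            reduced[name] = genes
    sets = ici_score.SignatureGeneSets(set_A=reduced["A"],
                                       set_B=reduced["B"])
    io.write_gmt({"ICI_signature_A": sets.set_A,
                  "ICI_signature_B": sets.set_B},
                 out / "ici_signature.gmt")
    score_tab = ici_score.compute_ici_score_ssgsea(expr_bc, sets)
    score_tab.to_csv(out / "ici_scores.tsv", sep="\t",
                     index_label="sample")
    results["ici_scores"] = score_tab

    if stages.get("pca_score", True):
        prog = survival.prognostic_gene_filter(
            expr_bc, clinical, sets.set_A + sets.set_B,
            alpha=cfg["alpha"])
        try:
            pca_tab = ici_score.compute_ici_score_pca(
                expr_bc, sets, prognostic_filter=prog or None,
                immune_score=scores["immune_score"], mode="difference")
            pca_tab.to_csv(out / "ici_scores_pca.tsv", sep="\t",
                           index_label="sample")
            results["ici_scores_pca"] = pca_tab
        except ValueError:
            results["ici_scores_pca"] = None

    # --- survival ----------------------------------------------------
    chi2, df, p = survival.logrank_test(clinical, score_tab["group"])
    results["logrank_ici_group"] = {"chi2": chi2, "df": df, "p": p}
    chi2c, dfc, pc = survival.logrank_test(clinical, ici_res.labels)
    results["logrank_ici_cluster"] = {"chi2": chi2c, "df": dfc, "p": pc}

    # --- mutation / TMB ----------------------------------------------
    if stages.get("mutation", True):
        maf = syndata.simulate_maf(truth, exome_mb=cfg["exome_mb"],
                                   seed=_seed_for(seed, "maf"))
        mutation.write_maf(maf, out / "mutations.maf")
        tmb = mutation.compute_tmb(mutation.read_maf(out / "mutations.maf"),
                                   exome_mb=cfg["exome_mb"],
                                   sample_roster=list(expr.columns))
        tmb.to_csv(out / "tmb.tsv", sep="\t")
        results["tmb"] = tmb
        results["tmb_by_group"] = mutation.compare_tmb_by_group(
            tmb, score_tab["group"])
        r, p_r = mutation.tmb_score_correlation(tmb,
                                                score_tab["ici_score"])
        results["tmb_score_corr"] = {"r": r, "p": p_r}
        strata = (tmb["tmb"] > tmb["tmb"].median()).map(
            {True: "TMB-high", False: "TMB-low"}).str.cat(
            score_tab["group"], sep="/")
        _, results["logrank_tmb_ici"] = survival.stratified_km(
            clinical, strata)

    # --- drug sensitivity --------------------------------------------
    if stages.get("drugs", True):
        n_dg = min(100, cfg["n_genes"])
        train_expr, train_ic50, effects = syndata.simulate_drug_training(
            n_lines=cfg["n_drug_lines"], n_genes=n_dg,
            n_drugs=cfg["n_drugs"],
            gene_names=list(expr.index[:n_dg]),
            seed=_seed_for(seed, "drugs"))
        model = downstream.RidgeIC50().fit(train_expr, train_ic50)
        preds = model.predict(expr_bc)
        drug_rank = downstream.rank_drugs_between_groups(
            preds, score_tab["group"], top_k=12)
        drug_rank.to_csv(out / "drug_ranking.tsv", sep="\t")
        results["drug_ranking"] = drug_rank

    # --- enrichment ---------------------------------------------------
    if stages.get("enrichment", True):
        hi = score_tab.index[score_tab["group"] == "high"].tolist()
        lo = score_tab.index[score_tab["group"] == "low"].tolist()
        ranking = dge.moderated_t(np.log2(expr_bc + 1.0), hi, lo)["t_mod"]
        blocks = syndata.marker_blocks(sig)
        term_sets = {f"MARKERS_{ct}": genes
                     for ct, genes in blocks.items() if len(genes) >= 2}
        gsea = downstream.gsea_preranked(
            ranking, term_sets, n_perm=cfg["gsea_perms"],
            seed=_seed_for(seed, "gsea"))
        gsea.to_csv(out / "gsea.tsv", sep="\t")
        results["gsea"] = gsea
        ora = downstream.ora_hypergeometric(
            sets.set_A, term_sets, universe=list(expr.index))
        ora.to_csv(out / "ora_signature_A.tsv", sep="\t")
        results["ora"] = ora

    manifest = {
        "config": {k: v for k, v in cfg.items()
                   if isinstance(v, (int, float, str, bool, dict, list))},
        "stage_seeds": {s: _seed_for(seed, s) for s in
                        ("sig", "cohort", "surv", "cluster", "genecluster",
                         "borutaA", "borutaB", "maf", "drugs", "gsea")},
        "outputs": sorted(p.name for p in out.iterdir()
                          if p.name != "manifest.json"),
        "elapsed_s": round(time.time() - t0, 2),
        "n_degs": len(degs),
        "n_signature_A": len(sets.set_A),
        "n_signature_B": len(sets.set_B),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    results["manifest"] = manifest
    results["clinical"] = clinical
    results["truth"] = truth
    results["signature_sets"] = sets
    return results
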