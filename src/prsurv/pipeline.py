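"""End-to-end pipeline driver on synthetic inputs.

Runs the full analysis in dependency order: simulate genotypes and trial
phenotypes, GWAS, LD matrices, fine-mapping, score construction and
scoring, survival meta-analyses (PRS -> irAE, time-dependent irAE -> OS,
landmark, hormone model), survival lasso, and predictor evaluation. Every
stage writes plain-text tables with a provenance footer into a fixed
directory layout, so a re-run with the same configuration reproduces the
artifact byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, finemap, lassoimp, predeval, prscore, survkit, synthpop
from .config import PipelineConfig
from .io import write_ld_matrix, write_scoring_file, write_sumstats, write_table

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "planted_panel", "planted_architecture"]

N_BLOCKS = 8
BLOCK_SIZE = 25
# planted causal variants: three loci, the middle one carrying two
# independent signals (variants far enough apart in the block for weak LD)
CAUSAL = {"rs30": 0.40, "rs105": 0.42, "rs120": 0.38, "rs155": 0.40}


def planted_panel(config: PipelineConfig) -> synthpop.HaplotypePanel:
    blocks = [synthpop.BlockSpec(BLOCK_SIZE, (0.1, 0.5), 0.85) for _ in range(N_BLOCKS)]
    return synthpop.simulate_haplotypes(
        config.n_haplotypes, blocks, seed=config.seed,
        variant_spacing=1_000, block_gap=1_500_000,
    )


def planted_architecture() -> synthpop.CausalArchitecture:
    return synthpop.CausalArchitecture(log_odds=dict(CAUSAL), prevalence=0.05)


def _locus_stats(sumstats: pd.DataFrame, locus: finemap.Locus) -> pd.DataFrame:
    m = (sumstats["chrom"] == locus.chrom) & \
        (sumstats["pos"] >= locus.start) & (sumstats["pos"] <= locus.end)
    return sumstats[m & sumstats["p"].notna()].reset_index(drop=True)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the configured stages; returns the in-memory results."""
    config.validate()
    out = Path(outdir)
    for sub in ("sumstats", "ld", "finemap", "scores", "survival",
                "lasso", "eval", "logs"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    prov = {"config": config.digest(), "seed": config.seed}
    config.to_yaml(out / "logs" / "config.yaml")

    res: dict = {}
    stages = set(config.stages)

    if "simulate" in stages:
        panel = planted_panel(config)
        arch = planted_architecture()
        cohort = synthpop.simulate_gwas_cohort(
            panel, arch, config.n_cases, config.n_controls, seed=config.seed)
        res.update(panel=panel, cohort=cohort)

    if "gwas" in stages:
        sumstats = assoc.logistic_gwas(
            res["cohort"].genotypes.astype(float), res["cohort"].phenotype,
            res["panel"].variants)
        write_sumstats(sumstats, out / "sumstats" / "sumstats.tsv", provenance=prov)
        res["sumstats"] = sumstats

    if "ld" in stages:
        res["loci"] = finemap.define_loci(
            res["sumstats"], config.significance, config.window_bp)
        ld_by_locus = {}
        panel = res["panel"]
        geno = panel.genotype_matrix().astype(float)
        for loc in res["loci"]:
            stats = _locus_stats(res["sumstats"], loc)
            idx = panel.variants["id"].isin(stats["id"]).to_numpy()
            ld = assoc.ld_matrix(geno[:, idx], list(panel.variants["id"][idx]))
            ld_by_locus[loc.locus_id] = ld
            safe = loc.locus_id.replace(":", "_")
            write_ld_matrix(ld, out / "ld" / f"{safe}.tsv", provenance=prov)
        res["ld"] = ld_by_locus

    if "finemap" in stages:
        prior = finemap.FinemapPrior(
            W=config.prior_W, level=config.credible_level,
            threshold=config.significance, half_width=config.window_bp)
        sets: list[finemap.CredibleSet] = []
        for loc in res["loci"]:
            stats = _locus_stats(res["sumstats"], loc)
            sets.extend(finemap.finemap_locus(
                stats, res["ld"][loc.locus_id], prior, locus_id=loc.locus_id))
        rows = []
        for cs in sets:
            m = cs.members.copy()
            m.insert(0, "locus", cs.locus_id)
            m.insert(1, "signal", cs.signal_index)
            rows.append(m)
        table = (pd.concat(rows, ignore_index=True) if rows
                 else pd.DataFrame(columns=["locus", "signal", "id", "ppa"]))
        write_table(table, out / "finemap" / "credible_sets.tsv", provenance=prov)
        res["credible_sets"] = sets

    if "score" in stages:
        weights = prscore.build_score(res["credible_sets"])
        write_scoring_file(weights, out / "scores" / "scoring.tsv", provenance=prov)
        res["weights"] = weights

    if "survival" in stages:
        weights = res["weights"]
        freqs = res["panel"].variants.set_index("id").loc[
            weights.table["rsID"], "freq"].to_numpy()
        score_table = pd.DataFrame({
            "variant": weights.table["rsID"],
            "freq": freqs,
            "effect_weight": weights.table["effect_weight"].to_numpy(),
        })
        n_active = config.n_trial_arms - max(1, config.n_trial_arms // 3)
        per = config.n_trial_patients // config.n_trial_arms
        arms = []
        for a in range(config.n_trial_arms):
            n = per if a < config.n_trial_arms - 1 else \
                config.n_trial_patients - per * (config.n_trial_arms - 1)
            arms.append(synthpop.ArmSpec(
                name=f"arm{a + 1}", n=n, active=a < n_active))
        patients = synthpop.simulate_trial_cohort(
            config.n_trial_patients, arms,
            prs_log_hr=float(np.log(config.prs_hr)),
            covariate_effects=synthpop.CovariateEffects(
                gender_log_hr=0.3, tsh_log_hr=0.35,
                irae_os_log_hr=float(np.log(config.irae_os_hr))),
            seed=config.seed, score_table=score_table)
        pheno = survkit.patients_to_frame(patients)
        write_table(pheno, out / "survival" / "phenotypes.csv", sep=",",
                    provenance=prov)

        active = pheno[pheno["active"]]
        simple = active.assign(tstart=0.0)
        meta_irae = survkit.meta_hr(
            simple.rename(columns={"hypo_time": "tstop", "hypo_event": "status"}),
            "prs", ev_covariates=survkit.EV_NAMES)
        iv = survkit.interval_frame(active)
        meta_os = survkit.meta_hr(iv, "irae")
        lm = survkit.landmark_analysis(active, config.landmark_days)
        hormones = survkit.hormone_model(active)

        summary = pd.concat([
            meta_irae.stratified.summary().head(1).assign(model="prs_irae_meta"),
            meta_os.stratified.summary().head(1).assign(model="irae_os_td_meta"),
            lm.summary().assign(model="landmark"),
            hormones.summary().assign(model="hormones"),
        ])
        write_table(summary.reset_index(names="covariate"),
                    out / "survival" / "fits.tsv", provenance=prov)
        res.update(patients=patients, pheno=pheno, meta_irae=meta_irae,
                   meta_os=meta_os, landmark=lm, hormones=hormones)

        labs = synthpop.simulate_lab_series(
            patients, abnormal_threshold=config.tsh_threshold,
            ordering_prob=config.ordering_prob,
            symptomatic_lag_days=config.precedence_window_days,
            seed=config.seed)
        events = survkit.derive_thyroid_events(
            labs, threshold=config.tsh_threshold,
            precede_window_days=config.precedence_window_days)
        orderings = [e.ordering for e in events if e.ordering]
        res["hyper_first_fraction"] = (
            float(np.mean([o == "hyper-first" for o in orderings]))
            if orderings else float("nan"))
        res["lab_events"] = events

    if "lasso" in stages:
        active = res["pheno"][res["pheno"]["active"]]
        weights = res["weights"]
        dosages = pd.DataFrame(
            np.vstack([p.dosages for p in res["patients"] if p.active]),
            columns=list(weights.table["rsID"]), index=active.index)
        design = lassoimp.build_lasso_design(
            dosages, weights, active["hypo_time"].to_numpy(),
            active["hypo_event"].to_numpy(),
            eigenvectors=active[survkit.EV_NAMES].to_numpy())
        lam, _, _ = lassoimp.cv_select_lambda(
            design, k=config.lasso_folds, repeats=config.lasso_repeats,
            seed=config.seed)
        fit = lassoimp.fit_nonneg_cox_lasso(design, lam)
        imp = lassoimp.importance(
            fit.coef[design.penalized], design.effect_sizes,
            names=[n for n, p in zip(design.names, design.penalized) if p])
        write_table(imp.table, out / "lasso" / "importance.tsv", provenance=prov)
        res.update(lasso_lambda=lam, lasso_fit=fit, importance=imp)

    if "evaluate" in stages:
        active = res["pheno"][res["pheno"]["active"]]
        curve = predeval.ppv_sensitivity_curve(
            active["prs"].to_numpy(), active["hypo_event"].to_numpy())
        write_table(curve.frame(), out / "eval" / "ppv_sensitivity.tsv",
                    provenance=prov)
        d_cv = predeval.cv_effect_size(
            active["prs"].to_numpy(), active["hypo_event"].to_numpy(),
            k=config.eval_folds, seed=config.seed)
        subgroup = predeval.combined_subgroup_hr(active)
        eval_summary = {
            "cv_effect_size": d_cv,
            "power_d_at_24_vs_819_alpha_0.01": predeval.power_two_sample(
                d_cv, 24, 819, alpha=0.01),
            "subgroup_hr": float(subgroup.hr[0]),
        }
        (out / "eval" / "summary.json").write_text(
            json.dumps(eval_summary, indent=2))
        res.update(ppv_curve=curve, cv_effect_size=d_cv, subgroup=subgroup)

    return res
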