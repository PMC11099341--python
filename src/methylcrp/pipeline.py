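"""End-to-end study replica on synthetic data.

``run_pipeline`` executes the full analysis sequence — generate cohorts,
prepare CRP, run basic/full EWAS, fit the Bayesian mixture model (variance
partitioning, probe grouping), cross-check with ORM-REML, train the five
DNAm predictors, project them into a held-out test cohort, and run the
evaluation battery — and writes a machine-readable JSON summary plus
per-stage TSV tables.

Desk-scale defaults (1,000 samples, 2,000 probes, reduced MCMC) complete
in a few minutes on one core. Discovery thresholds are configurable: the
epigenome-wide default of 3.6e-8 is calibrated to studies of tens of
thousands of samples and hundreds of thousands of probes, so desk-scale
runs use a proportionally lenient threshold.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import bayesr, evaluate, ewas, predictors, preprocess, reml, simulate
from .datatypes import MethylationDataset

__all__ = ["RunConfig", "run_pipeline", "compare_predictors"]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; the master seed fans out to every stage."""

    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    mcmc: bayesr.MixtureModelConfig = field(
        default_factory=lambda: bayesr.MixtureModelConfig.desk_scale()
    )
    ewas_threshold: float = 1e-4
    prefilter_p: float = 1e-4
    pgs_p_threshold: float = 1e-4
    n_folds: int = 20
    elnet_n_lambda: int = 50
    n_test_samples: int = 600
    probes_missing_in_test: int = 25
    joint_genetic: bool = True
    out_dir: str | Path | None = None
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        """Build a RunConfig from a TOML file.

        Top-level keys map to RunConfig fields; ``[sim]`` and ``[mcmc]``
        tables map to :class:`~methylcrp.simulate.SimConfig` and
        :class:`~methylcrp.bayesr.MixtureModelConfig` fields. Unknown keys
        raise, so typos fail loudly.
        """
        import tomllib

        raw = tomllib.loads(Path(path).read_text())
        sim_kw = raw.pop("sim", {})
        if "block_size_range" in sim_kw:
            sim_kw["block_size_range"] = tuple(sim_kw["block_size_range"])
        if "assay_per_wave" in sim_kw:
            sim_kw["assay_per_wave"] = tuple(sim_kw["assay_per_wave"])
        mcmc_kw = raw.pop("mcmc", {})
        if "mixture_variances" in mcmc_kw:
            mcmc_kw["mixture_variances"] = tuple(mcmc_kw["mixture_variances"])
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(
            sim=simulate.SimConfig(**sim_kw),
            mcmc=bayesr.MixtureModelConfig(**mcmc_kw),
            **raw,
        )

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "sim": asdict(self.sim),
                "mcmc": asdict(self.mcmc),
                "ewas_threshold": self.ewas_threshold,
                "prefilter_p": self.prefilter_p,
                "pgs_p_threshold": self.pgs_p_threshold,
                "n_folds": self.n_folds,
                "n_test_samples": self.n_test_samples,
                "probes_missing_in_test": self.probes_missing_in_test,
                "joint_genetic": self.joint_genetic,
                "seed": self.seed,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.md5(payload.encode()).hexdigest()[:12]


def _scaled(meth: MethylationDataset):
    X = meth.beta
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (X - mu) / sd, mu, sd


def run_pipeline(config: RunConfig | None = None) -> dict:
    """Run the full study replica; returns the summary dict (also written
    to ``<out_dir>/summary.json`` with per-stage TSVs when out_dir given)."""
    config = config or RunConfig()
    t0 = time.time()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    timings: dict[str, float] = {}

    def stage_done(name, t_start):
        timings[name] = round(time.time() - t_start, 3)

    # ------------------------------------------------------------------ simulate
    t = time.time()
    sim_cfg = replace(config.sim, seed=config.seed)
    train = simulate.generate_cohort(sim_cfg)
    meth, geno, pheno, truth = train
    test = simulate.derive_test_cohort(
        train,
        probes_missing=config.probes_missing_in_test,
        seed=config.seed + 1,
        n_samples=config.n_test_samples,
    )
    meth_t, geno_t, pheno_t, _ = test
    summary["stages"]["simulate"] = {
        "n_train": int(meth.n_samples),
        "n_test": int(meth_t.n_samples),
        "n_probes_train": int(meth.n_probes),
        "n_probes_test": int(meth_t.n_probes),
        "true_var_dnam": truth.true_var_dnam,
        "true_var_snp": truth.true_var_snp,
    }
    stage_done("simulate", t)

    # ------------------------------------------------------------------ prep
    t = time.time()
    prep = preprocess.transform_crp(
        pheno["crp_mg_per_l"], pheno["assay"], pheno["below_detection"],
        sample_id=pheno["sample_id"],
    )
    prep_t = preprocess.transform_crp(
        pheno_t["crp_mg_per_l"], pheno_t["assay"], pheno_t["below_detection"],
        sample_id=pheno_t["sample_id"],
    )
    geno_qc, qc_report = preprocess.qc_genotypes(geno)
    summary["stages"]["prep"] = {
        "n_excluded_outliers_train": prep.n_excluded,
        "n_imputed_low_sens_train": int(prep.imputed_low_sens.sum()),
        "snp_qc": qc_report,
    }
    stage_done("prep", t)

    # ------------------------------------------------------------------ EWAS
    t = time.time()
    mask = prep.included
    cov_basic = preprocess.build_covariate_matrix(pheno, "basic")
    cov_full = preprocess.build_covariate_matrix(pheno, "full")
    ewas_basic = ewas.run_ewas(meth, prep.log_crp, cov_basic, "basic", sample_mask=mask)
    ewas_full = ewas.run_ewas(meth, prep.log_crp, cov_full, "full", sample_mask=mask)
    thr = config.ewas_threshold
    atten = ewas.attenuation_stats(ewas_basic, ewas_full, thr)
    summary["stages"]["ewas"] = {
        "threshold": thr,
        "lambda_basic": ewas.genomic_inflation(ewas_basic["p"]),
        "lambda_full": ewas.genomic_inflation(ewas_full["p"]),
        "n_hits_basic": ewas.n_significant(ewas_basic, thr),
        "n_hits_full": ewas.n_significant(ewas_full, thr),
        "attenuation": atten,
    }
    stage_done("ewas", t)

    # ------------------------------------------------------- Bayesian mixture
    t = time.time()
    y_adj = preprocess.residualize(prep.log_crp[mask], pheno.loc[mask, ["age", "sex"]], scale=True)
    cov_probes = preprocess.build_covariate_matrix(pheno, "basic").loc[mask]
    X_adj = preprocess.residualize(meth.beta[mask], cov_probes, scale=True)
    mcmc = replace(config.mcmc, seed=config.seed + 10)
    post_meth = bayesr.gibbs_fit(
        X_adj, y_adj, mcmc, feature_ids=[meth.probe_ids], class_names=("methylation",)
    )
    var_meth_alone = bayesr.variance_partition(post_meth)[0]
    pip_tab = bayesr.compute_pip(post_meth)
    groups = bayesr.group_probes(post_meth, meth)

    bayes_summary = {
        "var_dnam_alone": var_meth_alone.as_dict(),
        "n_pooled_draws": post_meth.n_draws,
        "n_lead_groups": len(groups),
        "max_pip": float(pip_tab["pip"].max()),
    }
    if config.joint_genetic:
        Zg = geno_qc.dosage[mask]
        sdg = Zg.std(axis=0)
        keep_g = sdg > 1e-12
        Zg = (Zg[:, keep_g] - Zg[:, keep_g].mean(axis=0)) / sdg[keep_g]
        post_joint = bayesr.gibbs_fit(
            [X_adj, Zg],
            y_adj,
            replace(mcmc, seed=config.seed + 11),
            feature_ids=[meth.probe_ids, geno_qc.snp_ids[keep_g]],
            class_names=("methylation", "genetic"),
        )
        joint = bayesr.variance_partition(post_joint)
        bayes_summary["var_joint"] = [v.as_dict() for v in joint]
    summary["stages"]["bayes"] = bayes_summary
    stage_done("bayes", t)

    # ------------------------------------------------------------------ REML
    t = time.time()
    orm = reml.build_relationship_matrix(X_adj, kind="ORM")
    reml_res = reml.reml_fit(y_adj, orm)
    summary["stages"]["reml"] = {
        "var_dnam_reml": reml_res.estimates[0].as_dict(),
        "converged": reml_res.converged,
        "n_iter": reml_res.n_iter,
    }
    stage_done("reml", t)

    # ------------------------------------------------------------- predictors
    t = time.time()
    # prediction pipeline: scaled but unadjusted phenotype and probes
    y_pred = prep.log_crp[mask]
    meth_train = MethylationDataset(
        sample_ids=meth.sample_ids[mask],
        probe_ids=meth.probe_ids,
        beta=meth.beta[mask],
        probe_chr=meth.probe_chr,
        probe_pos=meth.probe_pos,
        array_tag=meth.array_tag,
    )
    w_elnet = predictors.train_elastic_net(
        meth_train, y_pred, n_folds=config.n_folds, seed=config.seed + 20,
        n_lambda=config.elnet_n_lambda,
    )
    Xs, mu_s, sd_s = _scaled(meth_train)
    ys = (y_pred - y_pred.mean()) / y_pred.std()
    post_pred = bayesr.gibbs_fit(
        Xs, ys, replace(mcmc, seed=config.seed + 21),
        feature_ids=[meth_train.probe_ids], class_names=("methylation",),
    )
    w_bayes = predictors.bayes_weights(post_pred, mu_s, sd_s, meth_train.probe_ids)
    # rescale standardized-y weights back to the log-CRP scale
    w_bayes.weights = w_bayes.weights * y_pred.std()
    w_bayes.intercept = float(w_bayes.intercept * y_pred.std() + y_pred.mean())
    w_pca = predictors.train_pca_elnet(
        meth_train, y_pred, prefilter=ewas_basic, p_threshold=config.prefilter_p,
        n_folds=config.n_folds, seed=config.seed + 22, n_lambda=config.elnet_n_lambda,
    )
    w_ewas_own = predictors.ewas_weight_score(ewas_basic, config.ewas_threshold, source="own")
    # "reference" EWAS stands in for an external study: the full-model scan
    w_ewas_ref = predictors.ewas_weight_score(ewas_full, config.ewas_threshold, source="ref")
    weight_sets = {
        "elnet": w_elnet,
        "bayes": w_bayes,
        "pca_elnet": w_pca,
        "ewas_own": w_ewas_own,
        "ewas_ref": w_ewas_ref,
    }
    summary["stages"]["predictors"] = {
        name: {"n_probes": int(w.n_probes)} for name, w in weight_sets.items()
    }
    stage_done("predictors", t)

    # ------------------------------------------------------------- evaluation
    t = time.time()
    mask_t = prep_t.included
    meth_test = MethylationDataset(
        sample_ids=meth_t.sample_ids[mask_t],
        probe_ids=meth_t.probe_ids,
        beta=meth_t.beta[mask_t],
        probe_chr=meth_t.probe_chr,
        probe_pos=meth_t.probe_pos,
        array_tag=meth_t.array_tag,
    )
    pheno_test = pheno_t.loc[mask_t].reset_index(drop=True)
    y_test = prep_t.log_crp[mask_t]

    gwas_tab = _snp_association_scan(geno_qc, prep.log_crp, mask)
    geno_test_qc = geno_t.subset_snps(
        np.isin(geno_t.snp_ids, geno_qc.snp_ids)
    )
    pgs_test = evaluate.polygenic_score(
        geno_test_qc, gwas_tab, p_threshold=config.pgs_p_threshold
    )
    pgs_scores = pgs_test.score[mask_t]

    base_cov = pheno_test[["age", "sex"]]
    eval_rows = []
    scores_by_method = {}
    for name, w in weight_sets.items():
        sv = predictors.project(w, meth_test, missing_policy="omit")
        scores_by_method[name] = sv
        corr = evaluate.correlation_eval(sv, y_test)
        inc = evaluate.incremental_r2(y_test, base_cov, sv)
        inc_over_genetic = evaluate.incremental_r2(
            y_test, base_cov, sv, prior_additions=pgs_scores
        )
        eval_rows.append(
            {
                "method": name,
                "r": corr["r"],
                "r_ci_low": corr["ci_low"],
                "r_ci_high": corr["ci_high"],
                "incremental_r2": inc["incremental_r2"],
                "incremental_r2_over_genetic": inc_over_genetic["incremental_r2"],
                "frac_missing": sv.frac_missing,
            }
        )
    genetic_inc = evaluate.incremental_r2(y_test, base_cov, pgs_scores)
    eval_tab = pd.DataFrame(eval_rows)

    battery = evaluate.outcome_battery(
        exposures={
            "dnam_crp_elnet": scores_by_method["elnet"].score,
            "assay_crp": y_test,
        },
        pheno=pheno_test,
        continuous_outcomes=[f"outcome_{j:02d}" for j in range(1, 22)],
        binary_outcomes=[f"disease_{j:02d}" for j in range(1, 5)],
    )
    n_fdr_hits = (
        battery.dropna(subset=["q"]).groupby("exposure")["q"].apply(lambda s: int((s < 0.05).sum()))
    )
    summary["stages"]["evaluate"] = {
        "predictors": eval_tab.to_dict(orient="records"),
        "genetic_score_incremental_r2": genetic_inc["incremental_r2"],
        "n_outcome_fdr_hits": n_fdr_hits.to_dict(),
    }
    stage_done("evaluate", t)

    summary["timings_s"] = timings
    summary["total_s"] = round(time.time() - t0, 3)

    if out_dir:
        ewas_basic.to_csv(out_dir / "ewas_basic.tsv", sep="\t", index=False)
        ewas_full.to_csv(out_dir / "ewas_full.tsv", sep="\t", index=False)
        pip_tab.to_csv(out_dir / "bayes_pip.tsv", sep="\t", index=False)
        eval_tab.to_csv(out_dir / "predictor_eval.tsv", sep="\t", index=False)
        battery.to_csv(out_dir / "outcome_battery.tsv", sep="\t", index=False)
        for name, w in weight_sets.items():
            w.save(out_dir / f"weights_{name}.tsv")
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary


def _snp_association_scan(geno, log_crp, mask) -> pd.DataFrame:
    """Per-SNP OLS of log CRP on dosage — the training-cohort GWAS whose
    summary statistics feed the polygenic score."""
    from scipy import stats as st

    y = np.asarray(log_crp, dtype=float)[mask]
    D = geno.dosage[mask]
    n = y.size
    yc = y - y.mean()
    Dc = D - D.mean(axis=0)
    sxx = np.einsum("ij,ij->j", Dc, Dc)
    sxx_safe = np.where(sxx < 1e-12, 1.0, sxx)
    beta = (Dc.T @ yc) / sxx_safe
    rss = yc @ yc - beta**2 * sxx_safe
    df = n - 2
    se = np.sqrt(np.maximum(rss, 0) / df / sxx_safe)
    tstat = np.where(se > 0, beta / se, 0.0)
    p = np.clip(2 * st.t.sf(np.abs(tstat), df), np.nextafter(0, 1), 1.0)
    return pd.DataFrame(
        {
            "snp_id": geno.snp_ids,
            "effect_allele": geno.allele_counted,
            "other_allele": geno.allele_other,
            "effect": np.where(sxx < 1e-12, 0.0, beta),
            "p": np.where(sxx < 1e-12, 1.0, p),
        }
    )


def stability_comparison(
    cohort,
    weights,
    n_waves: int = 3,
    tracking_corr: float = 0.7,
    assay_per_wave=("high", "high", "high"),
    meth_stability: float = 0.98,
    seed: int = 0,
) -> dict:
    """Temporal-stability contrast: DNAm score vs assay CRP over waves.

    Expands a cross-sectional cohort into repeated waves where CRP is
    phasic (wave-to-wave latent correlation ``tracking_corr``) while
    methylation drifts slowly (``meth_stability``); projects ``weights``
    onto each wave's methylation and returns the ICC(2,k) of the DNAm score
    and of log assay CRP.
    """
    from . import evaluate

    meth, _, pheno, _ = cohort
    long = simulate.generate_longitudinal(
        pheno, n_waves, tracking_corr, list(assay_per_wave), seed=seed
    )
    waves_meth = simulate.generate_wave_methylation(
        meth, n_waves, stability=meth_stability, seed=seed + 1
    )
    n = meth.n_samples
    crp_wide = np.empty((n, n_waves))
    score_wide = np.empty((n, n_waves))
    for w in range(n_waves):
        tab = long[long["wave"] == w + 1]
        prep_w = preprocess.transform_crp(
            tab["crp_mg_per_l"], tab["assay"], tab["below_detection"],
            apply_outlier_filter=False,
        )
        crp_wide[:, w] = prep_w.log_crp
        score_wide[:, w] = predictors.project(weights, waves_meth[w]).score
    return {
        "dnam_icc": evaluate.icc2k(score_wide, "dnam_score").icc2k,
        "assay_icc": evaluate.icc2k(crp_wide, "assay_crp").icc2k,
    }


def compare_predictors(summary: dict) -> pd.DataFrame:
    """Ranking table from a pipeline summary: r and incremental R2 per
    predictor, winner flagged by incremental R2."""
    rows = summary["stages"]["evaluate"]["predictors"]
    if len(rows) < 1:
        raise ValueError("no predictor evaluations in summary")
    tab = pd.DataFrame(rows).sort_values("incremental_r2", ascending=False)
    tab = tab.reset_index(drop=True)
    tab["rank"] = tab["incremental_r2"].rank(ascending=False, method="min").astype(int)
    tab["winner"] = tab["rank"] == 1
    return tab
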