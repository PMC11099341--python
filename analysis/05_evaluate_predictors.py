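"""Evaluate the trained predictors on the held-out test cohort.

Projects each serialized predictor onto the test methylation matrix
(25 probes absent; missing terms omitted), computes Pearson correlations
with log CRP and incremental R2 over age+sex (alone and stacked on the
polygenic score), contrasts temporal stability (ICC2k of per-wave DNAm
scores vs phasic assay CRP), and runs the 26-outcome association battery
for the best DNAm predictor against assay CRP.

Run 04_train_predictors.py first (reads results/weights/).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from methylcrp import evaluate, pipeline, predictors, preprocess, simulate
from methylcrp.datatypes import MethylationDataset
from methylcrp.pipeline import _snp_association_scan
from study_config import RESULTS_DIR, RUN

wdir = Path(RESULTS_DIR) / "weights"
out = Path(RESULTS_DIR) / "evaluation"
out.mkdir(parents=True, exist_ok=True)

train = simulate.generate_cohort(RUN.sim)
meth, geno, pheno, truth = train
prep = preprocess.transform_crp(
    pheno["crp_mg_per_l"], pheno["assay"], pheno["below_detection"],
)
test = simulate.derive_test_cohort(
    train, probes_missing=RUN.probes_missing_in_test, seed=RUN.seed + 1,
    n_samples=RUN.n_test_samples,
)
meth_t, geno_t, pheno_t, _ = test
prep_t = preprocess.transform_crp(
    pheno_t["crp_mg_per_l"], pheno_t["assay"], pheno_t["below_detection"],
)
mask_t = prep_t.included
meth_test = MethylationDataset(
    sample_ids=meth_t.sample_ids[mask_t], probe_ids=meth_t.probe_ids,
    beta=meth_t.beta[mask_t], probe_chr=meth_t.probe_chr,
    probe_pos=meth_t.probe_pos, array_tag=meth_t.array_tag,
)
pheno_test = pheno_t.loc[mask_t].reset_index(drop=True)
y_test = prep_t.log_crp[mask_t]

geno_qc, _ = preprocess.qc_genotypes(geno)
gwas = _snp_association_scan(geno_qc, prep.log_crp, prep.included)
geno_t_qc = geno_t.subset_snps(np.isin(geno_t.snp_ids, geno_qc.snp_ids))
pgs = evaluate.polygenic_score(geno_t_qc, gwas, p_threshold=RUN.pgs_p_threshold)
pgs_scores = pgs.score[mask_t]

rows = []
scores = {}
for path in sorted(wdir.glob("*.tsv")):
    name = path.stem
    w = predictors.PredictorWeights.load(path)
    sv = predictors.project(w, meth_test, missing_policy="omit")
    scores[name] = sv
    corr = evaluate.correlation_eval(sv, y_test)
    inc = evaluate.incremental_r2(y_test, pheno_test[["age", "sex"]], sv)
    inc_g = evaluate.incremental_r2(
        y_test, pheno_test[["age", "sex"]], sv, prior_additions=pgs_scores
    )
    rows.append(
        {
            "method": name, "r": corr["r"], "ci_low": corr["ci_low"],
            "ci_high": corr["ci_high"],
            "incremental_r2": inc["incremental_r2"],
            "incremental_r2_over_genetic": inc_g["incremental_r2"],
            "frac_missing": sv.frac_missing,
        }
    )
tab = pd.DataFrame(rows).sort_values("incremental_r2", ascending=False)
tab.to_csv(out / "predictor_performance.tsv", sep="\t", index=False)
print(tab.to_string(index=False))

gen_inc = evaluate.incremental_r2(y_test, pheno_test[["age", "sex"]], pgs_scores)
print(f"\nPolygenic score incremental R2 = {gen_inc['incremental_r2']:.3f} "
      f"(generative genetic fraction {truth.true_var_snp:.2f}).")

w_el = predictors.PredictorWeights.load(wdir / "elnet.tsv")
stab = pipeline.stability_comparison(train, w_el, tracking_corr=0.7, seed=RUN.seed + 30)
print(f"ICC2k over 3 waves: DNAm score {stab['dnam_icc']:.2f}, "
      f"assay CRP {stab['assay_icc']:.2f}.")

battery = evaluate.outcome_battery(
    exposures={"dnam_crp_elnet": scores["elnet"].score, "assay_crp": y_test},
    pheno=pheno_test,
    continuous_outcomes=[f"outcome_{j:02d}" for j in range(1, 22)],
    binary_outcomes=[f"disease_{j:02d}" for j in range(1, 5)],
)
battery.to_csv(out / "outcome_battery.tsv", sep="\t", index=False)
hits = battery.dropna(subset=["q"]).groupby("exposure")["q"].apply(lambda s: (s < 0.05).sum())
print("\nOutcome associations at FDR 5%:")
print(hits.to_string())
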