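"""Train the five DNAm CRP predictors on the training cohort.

Elastic net (alpha 0.5, 20-fold CV, penalty at minimum CV error) and the
Bayesian posterior-mean predictor are fitted to scaled-but-unadjusted data;
PCA+elnet pre-filters probes by an external EWAS p threshold, fits
components, and composes weights back to CpG space; the two EWAS-weight
scores take regression effects directly. All weights are serialized on the
raw beta scale under results/weights/.
"""

from dataclasses import replace
from pathlib import Path

import numpy as np

from methylcrp import bayesr, ewas, predictors, preprocess, simulate
from methylcrp.datatypes import MethylationDataset
from study_config import RESULTS_DIR, RUN

out = Path(RESULTS_DIR) / "weights"
out.mkdir(parents=True, exist_ok=True)

meth, geno, pheno, truth = simulate.generate_cohort(RUN.sim)
prep = preprocess.transform_crp(
    pheno["crp_mg_per_l"], pheno["assay"], pheno["below_detection"],
)
mask = prep.included
y = prep.log_crp[mask]
meth_train = MethylationDataset(
    sample_ids=meth.sample_ids[mask], probe_ids=meth.probe_ids,
    beta=meth.beta[mask], probe_chr=meth.probe_chr, probe_pos=meth.probe_pos,
    array_tag=meth.array_tag,
)

basic = ewas.run_ewas(
    meth, prep.log_crp, preprocess.build_covariate_matrix(pheno, "basic"),
    "basic", sample_mask=mask,
)
full = ewas.run_ewas(
    meth, prep.log_crp, preprocess.build_covariate_matrix(pheno, "full"),
    "full", sample_mask=mask,
)

weights = {}
weights["elnet"] = predictors.train_elastic_net(
    meth_train, y, n_folds=RUN.n_folds, seed=RUN.seed + 20,
    n_lambda=RUN.elnet_n_lambda,
)
Xs = (meth_train.beta - meth_train.beta.mean(0)) / meth_train.beta.std(0)
ys = (y - y.mean()) / y.std()
post = bayesr.gibbs_fit(
    Xs, ys, replace(RUN.mcmc, seed=RUN.seed + 21),
    feature_ids=[meth_train.probe_ids],
)
w_b = predictors.bayes_weights(
    post, meth_train.beta.mean(0), meth_train.beta.std(0), meth_train.probe_ids
)
w_b.weights *= y.std()
w_b.intercept = float(w_b.intercept * y.std() + y.mean())
weights["bayes"] = w_b
weights["pca_elnet"] = predictors.train_pca_elnet(
    meth_train, y, prefilter=basic, p_threshold=RUN.prefilter_p,
    n_folds=RUN.n_folds, seed=RUN.seed + 22, n_lambda=RUN.elnet_n_lambda,
)
weights["ewas_own"] = predictors.ewas_weight_score(basic, RUN.ewas_threshold, "own")
weights["ewas_ref"] = predictors.ewas_weight_score(full, RUN.ewas_threshold, "ref")

for name, w in weights.items():
    w.save(out / f"{name}.tsv")
    in_sample = predictors.project(w, meth_train)
    r = np.corrcoef(in_sample.score, y)[0, 1]
    print(f"{name:10s} {w.n_probes:5d} probes, training r = {r:.3f}")
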