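"""Shared fixtures: small synthetic cohorts and one full pipeline run.

Everything is generated programmatically with fixed seeds; the expensive
fixtures are session-scoped so the end-to-end study is executed once and
reused by the pipeline, ordering and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import methylcrp as mc
from methylcrp import bayesr, pipeline, preprocess


@pytest.fixture(scope="session")
def small_cohort():
    """Cross-sectional cohort: 500 samples x 400 probes x 120 SNPs."""
    cfg = mc.SimConfig(n_samples=500, n_probes=400, n_snps=120, seed=7)
    return mc.generate_cohort(cfg)


@pytest.fixture(scope="session")
def prepared_small(small_cohort):
    meth, geno, pheno, truth = small_cohort
    prep = preprocess.transform_crp(
        pheno["crp_mg_per_l"], pheno["assay"], pheno["below_detection"],
        sample_id=pheno["sample_id"],
    )
    return prep


@pytest.fixture(scope="session")
def pipeline_summary():
    """One full desk-scale study replica (n=1,000, m=2,000, reduced MCMC)."""
    return pipeline.run_pipeline(pipeline.RunConfig(seed=1))


@pytest.fixture(scope="session")
def desk_mcmc():
    return bayesr.MixtureModelConfig.desk_scale(seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_posterior(betas, labels, probe_ids=None):
    """Hand-built MixturePosterior for deterministic summary tests."""
    betas = np.asarray(betas, dtype=float)
    labels = np.asarray(labels, dtype=np.int8)
    T, m = betas.shape
    if probe_ids is None:
        probe_ids = np.array([f"cg{j:05d}" for j in range(m)])
    cfg = bayesr.MixtureModelConfig(
        n_iter=10, burn_in=5, thinning=1, n_chains=1, final_per_chain=5
    )
    return bayesr.MixturePosterior(
        betas=betas,
        labels=labels,
        pi=np.zeros((T, 1, 4)),
        sigma2_e=np.ones(T),
        feature_ids=np.asarray(probe_ids),
        class_of=np.zeros(m, dtype=np.int32),
        class_names=("methylation",),
        chain=np.zeros(T, dtype=np.int32),
        config=cfg,
    )


def standardize(x):
    x = np.asarray(x, dtype=float)
    return (x - x.mean(axis=0)) / x.std(axis=0)
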