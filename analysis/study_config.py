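"""Shared study configuration for the numbered analysis drivers.

Every driver regenerates the cohorts deterministically from this seed, so
the scripts can run independently and still describe one coherent study.
"""

from pathlib import Path

from methylcrp import bayesr, pipeline, simulate

MASTER_SEED = 1

SIM = simulate.SimConfig(seed=MASTER_SEED)
MCMC = bayesr.MixtureModelConfig.desk_scale(seed=MASTER_SEED + 10)
RUN = pipeline.RunConfig(sim=SIM, mcmc=MCMC, seed=MASTER_SEED)

#: repo-root results/ regardless of the working directory
RESULTS_DIR = Path(__file__).resolve().parent.parent / "results"
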