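# Desk-scale study configuration consumed by RunConfig.from_toml.
seed = 1
ewas_threshold = 1e-4
prefilter_p = 1e-4
pgs_p_threshold = 1e-4
n_test_samples = 600
probes_missing_in_test = 25

[sim]
n_samples = 1000
n_probes = 2000
n_snps = 500
var_dnam = 0.50
var_snp = 0.13

[mcmc]
n_iter = 1000
burn_in = 500
thinning = 2
n_chains = 2
final_per_chain = 250
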