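"""Generate the synthetic training and test cohorts and record the truth.

A training cohort of 1,000 adults with 2,000 CpG probes (organized in
correlated blocks within 2.5 kb), 500 SNPs in Hardy-Weinberg proportions,
CRP on the natural mg/L scale, and lifestyle/cell/batch confounding; the
generative variance budget assigns 50% of log-CRP variance to methylation
and 13% to genetics. A test cohort of 600 is drawn from the same law with
25 probes absent, emulating projection onto a smaller array.

Writes cohort demographics and the ground-truth record under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from methylcrp import simulate
from study_config import RESULTS_DIR, RUN

out = Path(RESULTS_DIR) / "cohort"
out.mkdir(parents=True, exist_ok=True)

train = simulate.generate_cohort(RUN.sim)
meth, geno, pheno, truth = train
test = simulate.derive_test_cohort(
    train, probes_missing=RUN.probes_missing_in_test, seed=RUN.seed + 1,
    n_samples=RUN.n_test_samples,
)

rows = []
for name, (m, g, p, _) in (("train", train), ("test", test)):
    rows.append(
        {
            "cohort": name,
            "n_samples": m.n_samples,
            "n_probes": m.n_probes,
            "n_snps": g.n_snps,
            "age_mean": round(p["age"].mean(), 1),
            "age_sd": round(p["age"].std(), 1),
            "pct_female": round(100 * p["sex"].mean(), 1),
            "crp_mean_mg_l": round(p["crp_mg_per_l"].mean(), 2),
            "crp_sd_mg_l": round(p["crp_mg_per_l"].std(), 2),
            "assay": p["assay"].iloc[0],
            "array": m.array_tag,
        }
    )
demo = pd.DataFrame(rows)
demo.to_csv(out / "demographics.tsv", sep="\t", index=False)
truth.to_json(out / "truth.json")
meth.annotation_frame().to_csv(out / "probe_annotation.tsv", sep="\t", index=False)

print(demo.to_string(index=False))
print(
    f"\nTrue variance fractions: methylation {truth.true_var_dnam:.2f}, "
    f"genetic {truth.true_var_snp:.2f}; {len(truth.causal_probe_ids)} causal "
    f"probes, {len(truth.causal_snp_ids)} causal SNPs."
)
print(f"Test cohort lacks {meth.n_probes - test[0].n_probes} probes of {meth.n_probes}.")
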