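"""Evaluation battery: correlations, incremental R2, ICC, mixed model,
outcome associations, FDR and polygenic scoring."""

import numpy as np
import pandas as pd
import pytest

from methylcrp import evaluate
from methylcrp.datatypes import GenotypeDataset


class TestCorrelation:
    def test_perfect_correlation(self, rng):
        y = rng.normal(size=50)
        out = evaluate.correlation_eval(y, y)
        assert out["r"] == pytest.approx(1.0)
        assert out["ci_high"] <= 1.0

    def test_independent_noise(self, rng):
        n = 2000
        out = evaluate.correlation_eval(rng.normal(size=n), rng.normal(size=n))
        assert abs(out["r"]) < 3 / np.sqrt(n)
        assert out["ci_low"] < out["r"] < out["ci_high"]

    def test_score_r_near_sqrt_explained_fraction(self):
        """A predictor capturing a fraction f of phenotypic variance
        correlates ~sqrt(f) with the phenotype."""
        gen = np.random.default_rng(4)
        n, f = 3000, 0.25
        signal = gen.normal(size=n)
        y = np.sqrt(f) * signal + np.sqrt(1 - f) * gen.normal(size=n)
        out = evaluate.correlation_eval(signal, y)
        assert out["r"] == pytest.approx(np.sqrt(f), abs=0.1)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            evaluate.correlation_eval(np.ones(20), np.arange(20.0))


class TestIncrementalR2:
    def test_orthogonal_addition_near_zero(self, rng):
        n = 500
        y = rng.normal(size=n)
        cov = rng.normal(size=(n, 2))
        add = rng.normal(size=n)
        out = evaluate.incremental_r2(y, cov, add)
        assert out["incremental_r2"] < 2 / n * 10

    def test_residual_addition_attains_limit(self, rng):
        n = 200
        cov = rng.normal(size=(n, 2))
        y = rng.normal(size=n) + cov[:, 0]
        D = np.column_stack([np.ones(n), cov])
        resid = y - D @ np.linalg.lstsq(D, y, rcond=None)[0]
        out = evaluate.incremental_r2(y, cov, resid)
        assert out["incremental_r2"] == pytest.approx(1.0 - out["r2_null"], abs=1e-10)

    def test_matches_two_regression_oracle_on_12_rows(self):
        y = np.array([2.3, 1.1, 4.5, 3.3, 2.2, 5.1, 0.4, 3.8, 2.9, 1.7, 4.2, 3.0])
        age = np.array([61, 72, 65, 70, 68, 75, 62, 71, 66, 69, 73, 64.0])
        sex = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1.0])
        score = np.array([0.2, -0.4, 1.1, 0.6, 0.1, 1.4, -0.9, 0.8, 0.5, -0.2, 1.0, 0.3])

        def r2(design):
            D = np.column_stack([np.ones(12), design])
            coef, *_ = np.linalg.lstsq(D, y, rcond=None)
            res = y - D @ coef
            return 1 - res @ res / np.sum((y - y.mean()) ** 2)

        oracle = r2(np.column_stack([age, sex, score])) - r2(np.column_stack([age, sex]))
        out = evaluate.incremental_r2(y, np.column_stack([age, sex]), score)
        assert out["incremental_r2"] == pytest.approx(oracle, abs=1e-10)

    def test_non_negative_since_full_nests_null(self, rng):
        for _ in range(5):
            y = rng.normal(size=100)
            out = evaluate.incremental_r2(y, rng.normal(size=(100, 2)), rng.normal(size=100))
            assert out["incremental_r2"] >= -1e-12

    def test_stacked_additions(self, rng):
        n = 300
        g = rng.normal(size=n)
        s = rng.normal(size=n)
        y = 0.5 * g + 0.8 * s + rng.normal(size=n)
        cov = rng.normal(size=(n, 1))
        alone = evaluate.incremental_r2(y, cov, s)["incremental_r2"]
        over_g = evaluate.incremental_r2(y, cov, s, prior_additions=g)["incremental_r2"]
        assert alone > 0.2 and over_g > 0.2


class TestIcc2k:
    def test_identical_columns_give_one(self, rng):
        x = rng.normal(size=30)
        M = np.column_stack([x, x, x])
        assert evaluate.icc2k(M).icc2k == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        vals = [evaluate.icc2k(rng.normal(size=(60, 3))).icc2k for _ in range(20)]
        assert abs(np.mean(vals)) < 0.15

    def test_matches_anova_mean_squares_oracle(self):
        M = np.array(
            [
                [9.0, 10.0, 8.0],
                [6.0, 7.0, 5.5],
                [8.0, 8.5, 7.0],
                [7.0, 8.0, 6.0],
                [10.0, 11.5, 9.0],
                [6.5, 7.5, 6.2],
            ]
        )
        n, k = M.shape
        grand = M.mean()
        msr = k * np.sum((M.mean(1) - grand) ** 2) / (n - 1)
        msc = n * np.sum((M.mean(0) - grand) ** 2) / (k - 1)
        mse = (
            np.sum((M - M.mean(1, keepdims=True) - M.mean(0, keepdims=True) + grand) ** 2)
            / ((n - 1) * (k - 1))
        )
        oracle = (msr - mse) / (msr + (msc - mse) / n)
        assert evaluate.icc2k(M).icc2k == pytest.approx(oracle, abs=1e-10)

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        gen = np.random.default_rng(3)
        M = gen.normal(size=(12, 4)) + gen.normal(size=(12, 1))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 4),
                "rater": np.tile(np.arange(4), 12),
                "score": M.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        # pingouin labels the average-random-raters model ICC(A,k)
        icc2k_ref = float(ref.loc[ref["Type"] == "ICC(A,k)", "ICC"].iloc[0])
        assert evaluate.icc2k(M).icc2k == pytest.approx(icc2k_ref, abs=1e-10)

    def test_complete_cases_only_and_guards(self, rng):
        M = rng.normal(size=(10, 3))
        M[0, 1] = np.nan
        rep = evaluate.icc2k(M)
        assert rep.n_subjects == 9
        with pytest.raises(ValueError):
            evaluate.icc2k(rng.normal(size=(4, 3)))


class TestBhFdr:
    def test_step_up_hand_example(self):
        q = evaluate.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert evaluate.bh_fdr([0.42])[0] == pytest.approx(0.42)

    def test_all_ones(self):
        assert np.allclose(evaluate.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_order_invariance_and_monotonicity(self, rng):
        p = rng.uniform(size=40)
        q = evaluate.bh_fdr(p)
        perm = rng.permutation(40)
        assert np.allclose(evaluate.bh_fdr(p[perm]), q[perm])
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_empty_and_invalid(self):
        assert evaluate.bh_fdr([]).size == 0
        with pytest.raises(ValueError):
            evaluate.bh_fdr([0.5, 0.0])


class TestLongitudinalMixedModel:
    def _long(self, n_subj, n_waves, slope_coupling, seed=0):
        gen = np.random.default_rng(seed)
        base = gen.normal(size=n_subj)
        intercepts = gen.normal(size=n_subj) * 0.8
        rows = []
        for w in range(n_waves):
            age = 73 + 3 * w
            y = (
                intercepts
                + 0.3 * base
                + slope_coupling * base * (w * 3)  # decline rate tied to baseline
                + gen.normal(size=n_subj) * 0.3
            )
            rows.append(
                pd.DataFrame(
                    {
                        "sample_id": [f"S{i}" for i in range(n_subj)],
                        "wave": w + 1,
                        "log_crp": y,
                        "age": age + gen.normal(size=n_subj) * 0.3,
                        "sex": np.tile([0, 1], n_subj // 2 + 1)[:n_subj],
                    }
                )
            )
        long = pd.concat(rows, ignore_index=True)
        baseline = pd.Series(base, index=[f"S{i}" for i in range(n_subj)])
        return long, baseline

    def test_null_interaction_near_zero(self):
        long, base = self._long(150, 3, slope_coupling=0.0, seed=1)
        out = evaluate.longitudinal_lmm(long, base)
        assert abs(out["effect"] / out["se"]) < 3

    def test_decline_coupled_to_baseline_gives_negative_interaction(self):
        long, base = self._long(150, 3, slope_coupling=-0.05, seed=2)
        out = evaluate.longitudinal_lmm(long, base)
        assert out["effect"] < 0
        assert out["p"] < 0.01

    def test_random_intercept_variance_recovered(self):
        long, base = self._long(200, 4, slope_coupling=0.0, seed=3)
        out = evaluate.longitudinal_lmm(long, base)
        # generated intercept SD 0.8 -> variance 0.64
        assert out["random_intercept_var"] == pytest.approx(0.64, abs=0.25)


class TestOutcomeBattery:
    def test_logistic_or_recovered(self):
        gen = np.random.default_rng(6)
        n = 5000
        x = gen.normal(size=n)
        logit = -1.0 + np.log(1.5) * x
        y = (gen.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        pheno = pd.DataFrame(
            {"age": gen.normal(70, 5, n), "sex": gen.integers(0, 2, n), "d": y}
        )
        tab = evaluate.outcome_battery(
            {"x": x}, pheno, continuous_outcomes=[], binary_outcomes=["d"], survival=None
        )
        assert np.exp(tab["effect"].iloc[0]) == pytest.approx(1.5, abs=0.15)

    def test_cox_hr_recovered(self):
        gen = np.random.default_rng(7)
        n = 5000
        x = gen.normal(size=n)
        rate = 0.05 * np.exp(np.log(1.5) * x)
        t = gen.exponential(1 / rate)
        censor = 30.0
        pheno = pd.DataFrame(
            {
                "age": gen.normal(70, 5, n),
                "sex": gen.integers(0, 2, n),
                "survival_time": np.minimum(t, censor),
                "death_event": (t <= censor).astype(int),
            }
        )
        assert pheno["death_event"].mean() < 0.9  # some censoring present
        tab = evaluate.outcome_battery(
            {"x": x}, pheno, continuous_outcomes=[], binary_outcomes=[]
        )
        assert np.exp(tab["effect"].iloc[0]) == pytest.approx(1.5, abs=0.15)

    def test_global_null_fdr_control(self):
        gen = np.random.default_rng(8)
        n = 800
        pheno = pd.DataFrame(
            {"age": gen.normal(70, 5, n), "sex": gen.integers(0, 2, n)}
        )
        for j in range(1, 22):
            pheno[f"outcome_{j:02d}"] = gen.normal(size=n)
        for j in range(1, 5):
            pheno[f"disease_{j:02d}"] = gen.integers(0, 2, n)
        tab = evaluate.outcome_battery(
            {"x": gen.normal(size=n)},
            pheno,
            continuous_outcomes=[f"outcome_{j:02d}" for j in range(1, 22)],
            binary_outcomes=[f"disease_{j:02d}" for j in range(1, 5)],
            survival=None,
        )
        assert (tab["q"] < 0.05).sum() == 0

    def test_height_rule_and_sparse_events_flagged(self, rng):
        n = 400
        pheno = pd.DataFrame(
            {
                "age": rng.normal(70, 5, n),
                "sex": rng.integers(0, 2, n),
                "height": rng.normal(165, 8, n),
                "fev": rng.normal(size=n),
                "grip": rng.normal(size=n),
                "rare_disease": np.r_[np.ones(3), np.zeros(n - 3)].astype(int),
            }
        )
        tab = evaluate.outcome_battery(
            {"x": rng.normal(size=n)},
            pheno,
            continuous_outcomes=["fev", "grip"],
            binary_outcomes=["rare_disease"],
            survival=None,
            height_rule={"outcomes": ["fev"], "column": "height"},
        )
        rare = tab[tab["outcome"] == "rare_disease"].iloc[0]
        assert rare["flagged"] and np.isnan(rare["effect"])
        assert tab["q"].notna().sum() == 2
        assert (tab.loc[tab["q"].notna(), "q"] >= tab.loc[tab["q"].notna(), "p"] - 1e-12).all()


class TestPolygenicScore:
    def _geno(self, dosage, a1, a2):
        dosage = np.atleast_2d(np.asarray(dosage, dtype=float))
        s = dosage.shape[1]
        return GenotypeDataset(
            sample_ids=np.array([f"S{i}" for i in range(dosage.shape[0])]),
            snp_ids=np.array([f"rs{j}" for j in range(s)]),
            dosage=dosage,
            allele_counted=np.asarray(a1),
            allele_other=np.asarray(a2),
        )

    def _gwas(self, n, effects, ps, ea, oa):
        return pd.DataFrame(
            {
                "snp_id": [f"rs{j}" for j in range(n)],
                "effect": effects,
                "p": ps,
                "effect_allele": ea,
                "other_allele": oa,
            }
        )

    def test_single_snp_arithmetic(self):
        geno = self._geno([[2.0]], ["A"], ["G"])
        gwas = self._gwas(1, [0.3], [1e-9], ["A"], ["G"])
        sv = evaluate.polygenic_score(geno, gwas)
        assert sv.score[0] == pytest.approx(0.6)

    def test_threshold_excludes_suggestive_snp(self):
        geno = self._geno([[2.0, 1.0]], ["A", "C"], ["G", "T"])
        gwas = self._gwas(2, [0.3, 0.5], [1e-9, 1e-7], ["A", "C"], ["G", "T"])
        sv = evaluate.polygenic_score(geno, gwas, p_threshold=5e-8)
        assert sv.n_probes_used == 1
        assert sv.score[0] == pytest.approx(0.6)

    def test_allele_swap_equals_aligned_oracle(self, rng):
        n, s = 50, 5
        dosage = rng.binomial(2, 0.4, size=(n, s)).astype(float)
        geno = self._geno(dosage, ["A"] * s, ["G"] * s)
        effects = rng.normal(size=s)
        # GWAS reports the other allele as effect allele for SNPs 1 and 3
        ea = ["A", "G", "A", "G", "A"]
        oa = ["G", "A", "G", "A", "G"]
        gwas = self._gwas(s, effects, [1e-9] * s, ea, oa)
        sv = evaluate.polygenic_score(geno, gwas)
        aligned = dosage.copy()
        aligned[:, [1, 3]] = 2.0 - aligned[:, [1, 3]]
        oracle = aligned @ effects
        assert np.allclose(sv.score, oracle, atol=1e-12)

    def test_unresolvable_alleles_dropped_with_warning(self):
        geno = self._geno([[1.0, 2.0]], ["A", "C"], ["G", "T"])
        gwas = self._gwas(2, [0.5, 0.2], [1e-9, 1e-9], ["T", "C"], ["C", "T"])
        with pytest.warns(UserWarning, match="dropped"):
            sv = evaluate.polygenic_score(geno, gwas)
        assert sv.n_probes_used == 1
        assert sv.score[0] == pytest.approx(0.4)
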