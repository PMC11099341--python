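"""Predictor training, weight composition, serialization and projection."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from methylcrp import bayesr, predictors
from methylcrp.datatypes import MethylationDataset
from methylcrp.predictors import PredictorWeights


def _meth(beta, prefix="cg"):
    m = beta.shape[1]
    return MethylationDataset(
        sample_ids=np.array([f"S{i}" for i in range(beta.shape[0])]),
        probe_ids=np.array([f"{prefix}{j:05d}" for j in range(m)]),
        beta=beta,
        probe_chr=np.array(["chr1"] * m),
        probe_pos=np.arange(1, m + 1) * 10_000,
    )


@pytest.fixture(scope="module")
def toy_training(rng=None):
    gen = np.random.default_rng(33)
    n, m = 300, 40
    beta = expit(gen.normal(size=(n, m)))
    w_true = np.zeros(m)
    w_true[[3, 11, 25]] = [4.0, -3.0, 2.5]
    y = beta @ w_true  # noiseless
    return _meth(beta), y, w_true


class TestElasticNet:
    def test_noiseless_recovery_and_training_fit(self, toy_training):
        meth, y, w_true = toy_training
        w = predictors.train_elastic_net(meth, y, n_folds=5, seed=0)
        causal = {f"cg{j:05d}" for j in np.flatnonzero(w_true)}
        assert causal <= set(w.probe_ids.tolist())
        sv = predictors.project(w, meth)
        assert np.corrcoef(sv.score, y)[0, 1] > 0.99

    def test_null_training_yields_uninformative_score(self):
        gen = np.random.default_rng(5)
        n, m = 300, 50
        meth = _meth(expit(gen.normal(size=(n, m))))
        y = gen.normal(size=n)
        w = predictors.train_elastic_net(meth, y, n_folds=5, seed=0)
        # held-out data from the same (null) law
        meth2 = _meth(expit(gen.normal(size=(n, m))))
        y2 = gen.normal(size=n)
        if w.n_probes:
            sv = predictors.project(w, meth2)
            if sv.score.std() > 0:
                assert abs(np.corrcoef(sv.score, y2)[0, 1]) < 3 / np.sqrt(n)

    def test_matches_coordinate_descent_oracle(self):
        """Fixed-penalty fit on a 10x5 toy against a from-scratch
        coordinate-descent solver of the same objective."""
        gen = np.random.default_rng(11)
        X = gen.normal(size=(10, 5))
        y = gen.normal(size=10) + X[:, 0]
        lam, alpha = 0.1, 0.5
        b0, coef = predictors.elastic_net_at_lambda(X, y, lam, alpha)

        # oracle: cyclic coordinate descent on
        # 1/(2n)||y - b0 - Xb||^2 + lam(alpha||b||_1 + (1-alpha)/2 ||b||^2)
        n = len(y)
        b = np.zeros(5)
        icpt = y.mean()
        for _ in range(10_000):
            icpt = np.mean(y - X @ b)
            for j in range(5):
                r_j = y - icpt - X @ b + X[:, j] * b[j]
                rho = X[:, j] @ r_j / n
                z = X[:, j] @ X[:, j] / n + lam * (1 - alpha)
                b[j] = np.sign(rho) * max(abs(rho) - lam * alpha, 0.0) / z
        assert np.allclose(coef, b, atol=1e-6)
        assert b0 == pytest.approx(icpt, abs=1e-6)

    def test_fold_count_guard(self, toy_training):
        meth, y, _ = toy_training
        with pytest.raises(ValueError):
            predictors.train_elastic_net(meth, y, n_folds=len(y) + 1)


class TestPcaElasticNet:
    @pytest.fixture(scope="class")
    def fitted(self):
        gen = np.random.default_rng(77)
        n, m = 250, 60
        base = gen.normal(size=(n, 6))
        load = gen.normal(size=(6, m))
        beta = expit(base @ load * 0.4 + gen.normal(size=(n, m)) * 0.3)
        y = base[:, 0] * 1.2 + gen.normal(size=n) * 0.5
        meth = _meth(beta)
        ref = pd.DataFrame(
            {"probe_id": meth.probe_ids, "p": np.full(m, 1e-9)}
        )
        w = predictors.train_pca_elnet(meth, y, ref, p_threshold=1e-7, n_folds=5, seed=1)
        return meth, y, w

    def test_composed_weights_reproduce_component_model(self, fitted):
        """CpG-space composition equals the component-space fit on training
        data (algebraic identity)."""
        meth, y, w = fitted
        sv = predictors.project(w, meth)
        # refit the component model directly
        sub = meth.subset_probes(np.isin(meth.probe_ids, np.union1d(w.probe_ids, meth.probe_ids)))
        mu = sub.beta.mean(axis=0)
        Xc = sub.beta - mu
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        nz = S > S[0] * 1e-12
        scores = U[:, nz] * S[nz]
        from sklearn.linear_model import ElasticNetCV
        from sklearn.model_selection import KFold

        model = ElasticNetCV(
            l1_ratio=0.5, alphas=100, eps=1e-4,
            cv=KFold(5, shuffle=True, random_state=1),
            max_iter=5000, tol=1e-3, n_jobs=1,
        )
        model.fit(scores, y)
        pred_component_space = model.predict(scores)
        assert np.allclose(sv.score, pred_component_space, atol=1e-8)

    def test_prefilter_intersection_count(self):
        gen = np.random.default_rng(8)
        meth = _meth(expit(gen.normal(size=(100, 80))))
        # reference lists 100 significant sites; only 80 exist in training
        ref = pd.DataFrame(
            {
                "probe_id": [f"cg{j:05d}" for j in range(100)],
                "p": np.full(100, 1e-9),
            }
        )
        y = gen.normal(size=100)
        w = predictors.train_pca_elnet(meth, y, ref, p_threshold=1e-7, n_folds=5, seed=0)
        assert w.provenance["n_prefiltered"] == "80"

    def test_threshold_sweep_runs_end_to_end(self):
        gen = np.random.default_rng(9)
        n, m = 150, 30
        meth = _meth(expit(gen.normal(size=(n, m))))
        y = meth.beta[:, 0] * 3 + gen.normal(size=n) * 0.5
        ps = 10.0 ** -gen.integers(1, 12, size=m)
        ref = pd.DataFrame({"probe_id": meth.probe_ids, "p": ps})
        out = {}
        for thr in (0.05, 1e-3, 1e-7):
            if (ps < thr).sum() >= 2:
                out[thr] = predictors.train_pca_elnet(
                    meth, y, ref, p_threshold=thr, n_folds=5, seed=0
                )
        assert len(out) >= 2
        assert all(isinstance(w, PredictorWeights) for w in out.values())

    def test_empty_prefilter_rejected(self, fitted):
        meth, y, _ = fitted
        ref = pd.DataFrame({"probe_id": meth.probe_ids, "p": np.ones(meth.n_probes)})
        with pytest.raises(ValueError):
            predictors.train_pca_elnet(meth, y, ref, p_threshold=1e-7, n_folds=5)


class TestEwasWeights:
    def test_threshold_filtering(self):
        tab = pd.DataFrame(
            {
                "probe_id": [f"cg{j}" for j in range(5)],
                "effect": [0.5, -0.2, 0.1, 0.3, -0.4],
                "p": [1e-9, 0.5, 1e-10, 0.2, 0.9],
            }
        )
        w = predictors.ewas_weight_score(tab, 1e-8)
        assert w.n_probes == 2
        assert set(w.probe_ids) == {"cg0", "cg2"}
        all_in = predictors.ewas_weight_score(tab, 1.1)
        assert all_in.n_probes == 5
        with pytest.raises(ValueError):
            predictors.ewas_weight_score(tab, 1e-20)


class TestBayesWeights:
    def test_posterior_mean_back_transform(self):
        from conftest import make_posterior

        post = make_posterior(np.full((3, 1), 0.1), np.ones((3, 1)))
        w = predictors.bayes_weights(post, training_means=[0.4], training_sds=[0.05])
        assert w.weights[0] == pytest.approx(2.0)
        assert w.intercept == pytest.approx(-0.8)

    def test_zero_mean_feature_absent(self):
        from conftest import make_posterior

        betas = np.array([[0.1, 0.0], [-0.1, 0.0]])
        post = make_posterior(betas, (betas != 0).astype(np.int8))
        w = predictors.bayes_weights(post, [0.5, 0.5], [0.1, 0.1])
        assert w.n_probes == 0  # means are 0 and 0

    def test_misaligned_stats_rejected(self):
        from conftest import make_posterior

        post = make_posterior(np.full((3, 2), 0.1), np.ones((3, 2)))
        with pytest.raises(ValueError, match="align"):
            predictors.bayes_weights(post, [0.5], [0.1])


class TestProjection:
    def _weights(self, probe_ids, w):
        w = np.asarray(w, dtype=float)
        return PredictorWeights(
            method="elnet", intercept=1.5, probe_ids=np.asarray(probe_ids),
            weights=w, training_means=np.full(w.size, 0.5),
            training_sds=np.full(w.size, 0.1),
        )

    def test_empty_weights_give_intercept(self, rng):
        meth = _meth(expit(rng.normal(size=(10, 4))))
        w = self._weights(meth.probe_ids, np.zeros(4))  # all dropped
        sv = predictors.project(w, meth, min_present=0.0)
        assert np.allclose(sv.score, 1.5)

    def test_partial_sum_oracle_under_omit(self, rng):
        n, m = 50, 40
        meth = _meth(expit(rng.normal(size=(n, m))))
        weights = rng.normal(size=m)
        w = self._weights(meth.probe_ids, weights)
        # drop 7 of the 40 weight probes from the cohort
        keep = np.ones(m, dtype=bool)
        drop_idx = [1, 5, 8, 13, 21, 30, 39]
        keep[drop_idx] = False
        sub = meth.subset_probes(keep)
        sv = predictors.project(w, sub, missing_policy="omit")
        oracle = 1.5 + meth.beta[:, keep] @ weights[keep]
        assert np.allclose(sv.score, oracle, atol=1e-12)
        assert sv.frac_missing == pytest.approx(7 / 40)
        assert sv.n_probes_used == 33

    def test_mean_impute_policy(self, rng):
        n, m = 30, 10
        meth = _meth(expit(rng.normal(size=(n, m))))
        weights = rng.normal(size=m)
        w = self._weights(meth.probe_ids, weights)
        sub = meth.subset_probes(np.arange(m) != 3)
        sv = predictors.project(w, sub, missing_policy="mean_impute")
        oracle = 1.5 + meth.beta[:, np.arange(m) != 3] @ weights[np.arange(m) != 3]
        oracle = oracle + weights[3] * 0.5  # training mean
        assert np.allclose(sv.score, oracle, atol=1e-12)

    def test_presence_floor_enforced(self, rng):
        meth = _meth(expit(rng.normal(size=(10, 10))))
        w = self._weights(meth.probe_ids, rng.normal(size=10))
        sub = meth.subset_probes(np.arange(3))
        with pytest.raises(ValueError, match="floor"):
            predictors.project(w, sub)

    def test_training_projection_reproduces_fitted_values(self, toy_training):
        meth, y, _ = toy_training
        w = predictors.train_elastic_net(meth, y, n_folds=5, seed=0)
        sv = predictors.project(w, meth)
        # standardized-space fitted values computed independently
        X = (meth.beta - w_mu(meth)) / w_sd(meth)
        lookup = {p: i for i, p in enumerate(meth.probe_ids)}
        coef_std = np.zeros(meth.n_probes)
        for p, wt, sd in zip(w.probe_ids, w.weights, w.training_sds):
            coef_std[lookup[p]] = wt * sd
        fitted = (
            w.intercept
            + np.sum(w.weights * w.training_means)
            + X @ coef_std
        )
        assert np.allclose(sv.score, fitted, atol=1e-8)


def w_mu(meth):
    return meth.beta.mean(axis=0)


def w_sd(meth):
    sd = meth.beta.std(axis=0)
    return np.where(sd < 1e-12, 1.0, sd)


class TestSerialization:
    def test_round_trip_bit_exact(self, tmp_path, toy_training):
        meth, y, _ = toy_training
        w = predictors.train_elastic_net(meth, y, n_folds=5, seed=0)
        path = tmp_path / "weights.tsv"
        w.save(path)
        back = PredictorWeights.load(path)
        assert back.method == w.method
        assert back.intercept == w.intercept
        assert np.array_equal(back.probe_ids, w.probe_ids)
        assert np.array_equal(back.weights, w.weights)
        assert np.array_equal(back.training_means, w.training_means)
        assert np.array_equal(back.training_sds, w.training_sds)


def test_elnet_and_bayes_predictors_agree_out_of_sample():
    """Both feature-selection routes recover the same signal; their
    out-of-sample scores correlate strongly."""
    import methylcrp as mc

    cfg = mc.SimConfig(
        n_samples=700, n_probes=300, n_snps=10, var_dnam=0.5, var_snp=0.0,
        frac_causal_probes=0.04, confounder_effects={}, seed=31,
    )
    train = mc.generate_cohort(cfg)
    meth, _, pheno, _ = train
    y = np.log(pheno["crp_mg_per_l"].to_numpy() + 0.01)
    w_el = predictors.train_elastic_net(meth, y, n_folds=5, seed=0)
    Xs = (meth.beta - meth.beta.mean(0)) / meth.beta.std(0)
    ys = (y - y.mean()) / y.std()
    post = bayesr.gibbs_fit(
        Xs, ys, bayesr.MixtureModelConfig.desk_scale(seed=1),
        feature_ids=[meth.probe_ids],
    )
    w_b = predictors.bayes_weights(
        post, meth.beta.mean(0), meth.beta.std(0), meth.probe_ids
    )
    test = mc.derive_test_cohort(train, seed=99, n_samples=400)
    s_el = predictors.project(w_el, test[0]).score
    s_b = predictors.project(w_b, test[0]).score
    assert np.corrcoef(s_el, s_b)[0, 1] > 0.8
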