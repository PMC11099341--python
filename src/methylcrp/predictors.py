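"""Methylation risk scores for CRP: training, serialization, projection.

Five predictor styles are supported, mirroring the common families of
DNAm trait predictors:

``elnet``
    Elastic net (mixing parameter 0.5) on standardized beta-values with
    k-fold cross-validation; the penalty at minimum mean CV error is kept.
``bayes``
    Posterior-mean effects from the spike+mixture Gibbs sampler fitted to
    scaled (but otherwise unadjusted) data.
``pca_elnet``
    Probes pre-filtered by an external EWAS p-value threshold, mean-centered
    (not scaled), decomposed by PCA, elastic net on the component scores;
    the component-space model is composed back to CpG space (w = L c,
    intercept a - mu' w) so projection needs only raw beta-values.
``ewas_ref`` / ``ewas_own``
    A polygenic-score-style weighted sum using EWAS effect sizes of probes
    passing a p threshold, from an external study or one's own scan.

All weights are stored on the raw beta-value scale (standardized-scale
coefficients are divided by the training SDs and the intercept adjusted),
so projection into any cohort is a plain dot product over the probes that
cohort contains. Training means/SDs travel with the weights for
mean-imputation of absent probes and audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .datatypes import MethylationDataset

__all__ = [
    "PredictorWeights",
    "ScoreVector",
    "train_elastic_net",
    "train_pca_elnet",
    "ewas_weight_score",
    "bayes_weights",
    "project",
]


@dataclass
class PredictorWeights:
    """Portable predictor: intercept + probe -> raw-beta-scale weight map."""

    method: str
    intercept: float
    probe_ids: np.ndarray
    weights: np.ndarray
    training_means: np.ndarray
    training_sds: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.weights == 0.0):
            keep = self.weights != 0.0
            self.probe_ids = self.probe_ids[keep]
            self.weights = self.weights[keep]
            self.training_means = self.training_means[keep]
            self.training_sds = self.training_sds[keep]

    @property
    def n_probes(self) -> int:
        return self.probe_ids.size

    def save(self, path: str | Path) -> None:
        """TSV with a ``#``-prefixed header block then probe rows.

        Floats are written with ``repr`` so a load round-trips bit-exactly.
        """
        lines = [
            f"# method\t{self.method}",
            f"# intercept\t{self.intercept!r}",
            f"# n_probes\t{self.n_probes}",
        ]
        for k, v in self.provenance.items():
            lines.append(f"# {k}\t{v}")
        lines.append("probe_id\tweight\ttraining_mean\ttraining_sd")
        for p, w, mu, sd in zip(
            self.probe_ids, self.weights, self.training_means, self.training_sds
        ):
            lines.append(f"{p}\t{float(w)!r}\t{float(mu)!r}\t{float(sd)!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PredictorWeights":
        method = "unknown"
        intercept = 0.0
        provenance: dict = {}
        rows: list[tuple[str, float, float, float]] = []
        header_seen = False
        for line in Path(path).read_text().splitlines():
            if line.startswith("# "):
                key, _, val = line[2:].partition("\t")
                if key == "method":
                    method = val
                elif key == "intercept":
                    intercept = float(val)
                elif key != "n_probes":
                    provenance[key] = val
            elif not header_seen:
                header_seen = True  # column header
            elif line.strip():
                p, w, mu, sd = line.split("\t")
                rows.append((p, float(w), float(mu), float(sd)))
        return cls(
            method=method,
            intercept=intercept,
            probe_ids=np.array([r[0] for r in rows]),
            weights=np.array([r[1] for r in rows]),
            training_means=np.array([r[2] for r in rows]),
            training_sds=np.array([r[3] for r in rows]),
            provenance=provenance,
        )


@dataclass
class ScoreVector:
    """Projected scores with missing-probe bookkeeping."""

    sample_id: np.ndarray
    score: np.ndarray
    n_probes_used: int
    frac_missing: float

    def series(self) -> pd.Series:
        return pd.Series(self.score, index=self.sample_id, name="score")


def _standardize_columns(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd < 1e-12, 1.0, sd)
    return (X - mu) / sd_safe, mu, sd_safe


def _restrict(meth: MethylationDataset, probe_set) -> MethylationDataset:
    if probe_set is None:
        return meth
    probe_set = set(probe_set)
    keep = np.array([p in probe_set for p in meth.probe_ids])
    if not keep.any():
        raise ValueError("probe-set restriction leaves no probes")
    return meth.subset_probes(keep)


def elastic_net_at_lambda(
    X,
    y,
    lam: float,
    alpha: float = 0.5,
    tol: float = 1e-12,
    max_iter: int = 100_000,
):
    """Single elastic net fit at a fixed penalty (glmnet parameterization:
    objective 1/(2n) ||y - b0 - Xb||^2 + lam * (alpha ||b||_1 +
    (1-alpha)/2 ||b||^2)). Returns (intercept, coefficients)."""
    from sklearn.linear_model import ElasticNet

    model = ElasticNet(
        alpha=lam, l1_ratio=alpha, fit_intercept=True, tol=tol, max_iter=max_iter
    )
    model.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
    return float(model.intercept_), model.coef_.copy()


def train_elastic_net(
    meth: MethylationDataset,
    y,
    alpha: float = 0.5,
    n_folds: int = 20,
    seed: int = 0,
    probe_set=None,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
    tol: float = 1e-3,
    extra_features: pd.DataFrame | None = None,
) -> PredictorWeights:
    """Elastic net predictor of log CRP from standardized beta-values.

    The mixing parameter defaults to 0.5; the penalty path is 100
    log-spaced values from the data-derived maximum down by a factor of
    1e-4, and the value minimizing mean k-fold cross-validated error is
    selected (fold assignment seeded). Non-zero standardized coefficients
    are returned on the raw beta scale.

    ``probe_set`` optionally restricts training to a common-array probe
    universe. ``extra_features`` (e.g. lifestyle covariates) may be offered
    to the model alongside probes; selected extras are reported in
    provenance but only probe weights enter the portable predictor.
    """
    meth = _restrict(meth, probe_set)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < n_folds:
        raise ValueError(f"n = {n} is smaller than n_folds = {n_folds}")
    X, mu, sd = _standardize_columns(meth.beta)
    names = list(meth.probe_ids)
    if extra_features is not None:
        E, e_mu, e_sd = _standardize_columns(extra_features.to_numpy(dtype=float))
        X = np.hstack([X, E])
        names = names + list(extra_features.columns)

    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    model = ElasticNetCV(
        l1_ratio=alpha,
        alphas=n_lambda,
        eps=lambda_min_ratio,
        cv=cv,
        fit_intercept=True,
        max_iter=5000,
        tol=tol,
        n_jobs=1,
    )
    model.fit(X, y)

    m = meth.n_probes
    coef_std = model.coef_[:m]
    w_raw = coef_std / sd
    intercept = float(model.intercept_ - np.sum(w_raw * mu))
    extras_selected = [names[m + j] for j in np.flatnonzero(model.coef_[m:])]
    return PredictorWeights(
        method="elnet",
        intercept=intercept,
        probe_ids=meth.probe_ids.copy(),
        weights=w_raw,
        training_means=mu.copy(),
        training_sds=sd.copy(),
        provenance={
            "alpha": str(alpha),
            "n_folds": str(n_folds),
            "seed": str(seed),
            "lambda_min_cv": repr(float(model.alpha_)),
            "n_train": str(n),
            "extras_selected": ",".join(extras_selected),
        },
    )


def train_pca_elnet(
    meth: MethylationDataset,
    y,
    prefilter: pd.DataFrame,
    p_threshold: float = 1e-7,
    alpha: float = 0.5,
    n_folds: int = 20,
    seed: int = 0,
    tol: float = 1e-3,
    n_lambda: int = 100,
    p_col: str = "p",
) -> PredictorWeights:
    """PCA + elastic net on externally pre-filtered probes.

    Training probes are truncated to those significant in the reference
    EWAS table at ``p_threshold`` and present in the training data. The
    retained probes are mean-centered (not scaled), all non-degenerate
    principal components are kept, and the elastic net (same protocol as
    :func:`train_elastic_net`) runs on component scores. Weights are
    composed back to CpG space — ``w = L c``, ``intercept = a - mu' w`` —
    so projection uses raw beta-values only.
    """
    sig = set(prefilter.loc[prefilter[p_col].to_numpy() < p_threshold, "probe_id"])
    keep = np.array([p in sig for p in meth.probe_ids])
    if keep.sum() < 2:
        raise ValueError(
            f"pre-filter at p < {p_threshold} leaves {int(keep.sum())} probes "
            "in the training data (need >= 2)"
        )
    sub = meth.subset_probes(keep)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < n_folds:
        raise ValueError(f"n = {n} is smaller than n_folds = {n_folds}")

    mu = sub.beta.mean(axis=0)
    Xc = sub.beta - mu
    # economy SVD; retain all components of non-negligible variance
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    nz = S > S[0] * 1e-12 if S.size else np.array([], dtype=bool)
    S, Vt = S[nz], Vt[nz]
    scores = U[:, nz] * S  # = Xc @ Vt.T

    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    model = ElasticNetCV(
        l1_ratio=alpha,
        alphas=n_lambda,
        eps=1e-4,
        cv=cv,
        fit_intercept=True,
        max_iter=5000,
        tol=tol,
        n_jobs=1,
    )
    model.fit(scores, y)

    w = Vt.T @ model.coef_  # CpG-space weights
    intercept = float(model.intercept_ - mu @ w)
    sd = sub.beta.std(axis=0)
    return PredictorWeights(
        method="pca_elnet",
        intercept=intercept,
        probe_ids=sub.probe_ids.copy(),
        weights=w,
        training_means=mu.copy(),
        training_sds=np.where(sd < 1e-12, 1.0, sd),
        provenance={
            "alpha": str(alpha),
            "n_folds": str(n_folds),
            "seed": str(seed),
            "p_threshold": repr(float(p_threshold)),
            "n_prefiltered": str(int(keep.sum())),
            "n_components": str(int(nz.sum())),
            "n_train": str(n),
        },
    )


def ewas_weight_score(
    ewas: pd.DataFrame,
    p_threshold: float,
    source: str = "own",
    effect_col: str = "effect",
    p_col: str = "p",
    training_stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> PredictorWeights:
    """EWAS-weighted score: effect sizes of probes passing ``p_threshold``.

    The polygenic-score analogue for methylation — no refitting, intercept
    zero. ``training_stats`` optionally supplies (means, sds) aligned with
    the table's probe order for mean-imputation support.
    """
    pass_mask = ewas[p_col].to_numpy() < p_threshold
    if not pass_mask.any():
        raise ValueError(f"no probes pass p < {p_threshold}")
    sub = ewas.loc[pass_mask]
    m = len(sub)
    if training_stats is not None:
        means, sds = training_stats
        means = np.asarray(means, dtype=float)[pass_mask]
        sds = np.asarray(sds, dtype=float)[pass_mask]
    else:
        means, sds = np.zeros(m), np.ones(m)
    return PredictorWeights(
        method=f"ewas_{source}",
        intercept=0.0,
        probe_ids=sub["probe_id"].to_numpy(),
        weights=sub[effect_col].to_numpy(dtype=float),
        training_means=means,
        training_sds=sds,
        provenance={"p_threshold": repr(float(p_threshold)), "source": source},
    )


def bayes_weights(post, training_means, training_sds, probe_ids=None) -> PredictorWeights:
    """Posterior-mean effects back-transformed to the raw beta scale.

    ``post`` is a :class:`~methylcrp.bayesr.MixturePosterior` fitted to
    scaled-but-unadjusted data; standardized-scale posterior means are
    divided by the training SDs (w_raw = w_std / sd).
    """
    if probe_ids is None:
        probe_ids = post.feature_ids
    probe_ids = np.asarray(probe_ids)
    means = np.asarray(training_means, dtype=float)
    sds = np.asarray(training_sds, dtype=float)
    if probe_ids.size != means.size or probe_ids.size != post.n_features:
        raise ValueError(
            "posterior features and training mean/sd table do not align: "
            f"{post.n_features} features vs {means.size} stats"
        )
    w_std = post.posterior_mean_effects()
    w_raw = w_std / sds
    intercept = float(-np.sum(w_raw * means))
    return PredictorWeights(
        method="bayes",
        intercept=intercept,
        probe_ids=probe_ids.copy(),
        weights=w_raw,
        training_means=means.copy(),
        training_sds=sds.copy(),
        provenance={"n_draws": str(post.n_draws)},
    )


def project(
    weights: PredictorWeights,
    meth: MethylationDataset,
    missing_policy: str = "omit",
    min_present: float = 0.5,
) -> ScoreVector:
    """Apply a predictor to a cohort's raw beta-values.

    score_i = intercept + sum over present probes of w_j * beta_ij. Probes
    absent from the cohort are either dropped from the sum (``omit``) or
    replaced by their training means (``mean_impute``). Errors out if fewer
    than ``min_present`` of the weight probes are present.
    """
    if missing_policy not in ("omit", "mean_impute"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    lookup = {p: i for i, p in enumerate(meth.probe_ids.tolist())}
    cols = np.array([lookup.get(p, -1) for p in weights.probe_ids], dtype=np.intp)
    present = cols >= 0
    n_present = int(present.sum())
    frac_missing = 1.0 - n_present / max(weights.n_probes, 1)
    if n_present < min_present * weights.n_probes:
        raise ValueError(
            f"only {n_present}/{weights.n_probes} weight probes present "
            f"(floor {min_present:.0%})"
        )
    score = np.full(meth.n_samples, weights.intercept, dtype=float)
    score += meth.beta[:, cols[present]] @ weights.weights[present]
    if missing_policy == "mean_impute" and not present.all():
        score += float(
            np.sum(weights.weights[~present] * weights.training_means[~present])
        )
    return ScoreVector(
        sample_id=meth.sample_ids.copy(),
        score=score,
        n_probes_used=n_present,
        frac_missing=frac_missing,
    )
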