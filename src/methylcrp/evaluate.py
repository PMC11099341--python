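"""Predictor evaluation: correlation, incremental R2, temporal stability,
longitudinal mixed model, health-outcome battery and polygenic scoring.

Continuous exposures and outcomes are standardized before association
testing, so linear effects are per-SD; logistic and Cox effects are
reported as odds/hazard ratios per SD of exposure. Multiple testing is
handled by Benjamini-Hochberg within each exposure's family of outcomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from lifelines import CoxPHFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GenotypeDataset

__all__ = [
    "correlation_eval",
    "incremental_r2",
    "icc2k",
    "longitudinal_lmm",
    "outcome_battery",
    "bh_fdr",
    "polygenic_score",
    "StabilityReport",
]


def correlation_eval(scores, log_crp) -> dict:
    """Pearson correlation between a DNAm score and log CRP, with a
    Fisher-z 95% confidence interval."""
    x = np.asarray(getattr(scores, "score", scores), dtype=float)
    y = np.asarray(log_crp, dtype=float)
    if x.size != y.size or x.size < 10:
        raise ValueError("need >= 10 paired values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in scores or phenotype")
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = 1.96 / np.sqrt(n - 3)
    return {
        "r": r,
        "ci_low": float(np.tanh(z - half)),
        "ci_high": float(np.tanh(z + half)),
        "n": n,
    }


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    design = np.column_stack([np.ones(y.size), X]) if X.size else np.ones((y.size, 1))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design in incremental R2 model")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    tss = np.sum((y - y.mean()) ** 2)
    return float(1.0 - resid @ resid / tss)


def incremental_r2(y, base_covariates, addition, prior_additions=None) -> dict:
    """Variance explained by an addition beyond a covariate-only null model.

    null: y ~ base covariates (+ any prior additions, e.g. a genetic score
    already in the model); full: null + addition. Returns R2 of both and
    their difference (full minus null).
    """
    y = np.asarray(y, dtype=float)

    def as_mat(block):
        if block is None:
            return np.empty((y.size, 0))
        if isinstance(block, pd.DataFrame):
            return block.to_numpy(dtype=float)
        arr = np.asarray(getattr(block, "score", block), dtype=float)
        return arr[:, None] if arr.ndim == 1 else arr

    base = as_mat(base_covariates)
    prior = as_mat(prior_additions)
    add = as_mat(addition)
    null_X = np.hstack([base, prior])
    full_X = np.hstack([null_X, add])
    r2_null = _ols_r2(y, null_X)
    r2_full = _ols_r2(y, full_X)
    return {
        "r2_null": r2_null,
        "r2_full": r2_full,
        "incremental_r2": r2_full - r2_null,
    }


@dataclass
class StabilityReport:
    measure: str
    icc2k: float
    n_subjects: int
    n_waves: int


def icc2k(wide, measure: str = "measure") -> StabilityReport:
    """ICC(2,k): two-way random effects, absolute agreement, average measures.

    ``wide`` is a subjects x waves matrix (or DataFrame); rows with any
    missing value are dropped. Computed from the two-way ANOVA mean squares:
    ICC2k = (MSR - MSE) / (MSR + (MSC - MSE) / n).
    """
    M = wide.to_numpy(dtype=float) if isinstance(wide, pd.DataFrame) else np.asarray(wide, dtype=float)
    M = M[np.isfinite(M).all(axis=1)]
    n, k = M.shape
    if k < 2:
        raise ValueError("need >= 2 waves")
    if n < 5:
        raise ValueError(f"need >= 5 complete subjects, got {n}")
    grand = M.mean()
    row_means = M.mean(axis=1)
    col_means = M.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((M - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (msc - mse) / n)
    return StabilityReport(measure=measure, icc2k=float(icc), n_subjects=n, n_waves=k)


def longitudinal_lmm(long: pd.DataFrame, baseline: pd.Series | dict) -> dict:
    """Mixed model of repeated log CRP on baseline exposure x age.

    ``long`` needs columns sample_id, wave, log_crp, age, sex. The baseline
    exposure (assay CRP or a DNAm score at the first high-sensitivity wave)
    is standardized and interacted with chronological age; a random
    intercept per subject absorbs between-person level differences. The
    Wald test on the interaction asks whether baseline status predicts the
    trajectory of later measurements.
    """
    df = long.copy()
    base = pd.Series(baseline) if isinstance(baseline, dict) else baseline
    df["baseline"] = df["sample_id"].map(base)
    df = df.dropna(subset=["baseline", "log_crp", "age", "sex"])
    n_subj = df["sample_id"].nunique()
    if n_subj < 20 or df.groupby("sample_id").size().max() < 2:
        raise ValueError("need >= 2 waves on >= 20 subjects")
    for col in ("baseline", "age"):
        df[col] = (df[col] - df[col].mean()) / df[col].std()

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "log_crp ~ baseline * age + sex", df, groups=df["sample_id"]
            )
            fit = model.fit(reml=True)
        singular = bool(fit.cov_re.iloc[0, 0] < 1e-8)
        params = fit.params
        bse = fit.bse
        pvals = fit.pvalues
        term = "baseline:age"
        out = {
            "effect": float(params[term]),
            "se": float(bse[term]),
            "p": float(pvals[term]),
            "random_intercept_var": float(fit.cov_re.iloc[0, 0]),
            "singular": singular,
            "fallback_ols": False,
        }
        if not singular:
            return out
    except Exception:
        pass
    # singular or failed random-effects fit: report fixed-effects fallback
    X = pd.DataFrame(
        {
            "baseline": df["baseline"],
            "age": df["age"],
            "baseline_age": df["baseline"] * df["age"],
            "sex": df["sex"].astype(float),
        }
    )
    ols = sm.OLS(df["log_crp"].to_numpy(), sm.add_constant(X)).fit()
    return {
        "effect": float(ols.params["baseline_age"]),
        "se": float(ols.bse["baseline_age"]),
        "p": float(ols.pvalues["baseline_age"]),
        "random_intercept_var": 0.0,
        "singular": True,
        "fallback_ols": True,
    }


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone in p)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - np.mean(x)) / np.std(x)


def outcome_battery(
    exposures: dict,
    pheno: pd.DataFrame,
    continuous_outcomes: list[str],
    binary_outcomes: list[str],
    survival: tuple[str, str] | None = ("survival_time", "death_event"),
    covariates: list[str] = ("age", "sex"),
    height_rule: dict | None = None,
    min_events: int = 10,
) -> pd.DataFrame:
    """Association battery of CRP measures against health outcomes.

    For each exposure (standardized): linear regression per continuous
    outcome (outcome standardized; effect per SD), logistic regression per
    binary outcome (log-odds per SD), and a Cox model for survival
    (log-hazard per SD, Efron tie handling). All models adjust for
    ``covariates``; outcomes named in ``height_rule["outcomes"]``
    additionally adjust for the ``height_rule["column"]`` covariate (the
    lung-function/walk-test convention). BH-FDR runs within each exposure's
    family of outcomes. Binary outcomes with fewer than ``min_events``
    events are flagged, not fitted.
    """
    height_rule = height_rule or {}
    height_outcomes = set(height_rule.get("outcomes", ()))
    height_col = height_rule.get("column")
    records = []
    for exp_name, exp_values in exposures.items():
        x = np.asarray(getattr(exp_values, "score", exp_values), dtype=float)
        xs = _standardize(x)
        fam: list[dict] = []

        def covs(outcome_name):
            cols = [pheno[c].to_numpy(dtype=float) for c in covariates]
            if outcome_name in height_outcomes and height_col:
                cols.append(pheno[height_col].to_numpy(dtype=float))
            return np.column_stack(cols) if cols else np.empty((len(pheno), 0))

        for out in continuous_outcomes:
            yv = _standardize(pheno[out].to_numpy(dtype=float))
            X = sm.add_constant(np.column_stack([xs, covs(out)]))
            fit = sm.OLS(yv, X).fit()
            fam.append(
                dict(outcome=out, model="linear", exposure=exp_name,
                     effect=float(fit.params[1]), se=float(fit.bse[1]),
                     p=float(fit.pvalues[1]), flagged=False)
            )
        for out in binary_outcomes:
            yv = pheno[out].to_numpy(dtype=float)
            n_events = int(min(yv.sum(), (1 - yv).sum()))
            if n_events < min_events:
                fam.append(
                    dict(outcome=out, model="logistic", exposure=exp_name,
                         effect=np.nan, se=np.nan, p=np.nan, flagged=True)
                )
                continue
            X = sm.add_constant(np.column_stack([xs, covs(out)]))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(yv, X).fit(disp=0)
            fam.append(
                dict(outcome=out, model="logistic", exposure=exp_name,
                     effect=float(fit.params[1]), se=float(fit.bse[1]),
                     p=float(fit.pvalues[1]), flagged=False)
            )
        if survival is not None:
            time_col, event_col = survival
            df = pd.DataFrame(
                {
                    "time": pheno[time_col].to_numpy(dtype=float),
                    "event": pheno[event_col].to_numpy(dtype=float),
                    "exposure": xs,
                }
            )
            for c in covariates:
                df[c] = pheno[c].to_numpy(dtype=float)
            cph = CoxPHFitter()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
            fam.append(
                dict(outcome="all_cause_mortality", model="cox", exposure=exp_name,
                     effect=float(cph.params_["exposure"]),
                     se=float(cph.standard_errors_["exposure"]),
                     p=float(cph.summary.loc["exposure", "p"]), flagged=False)
            )

        fitted = [r for r in fam if not r["flagged"]]
        if fitted:
            q = bh_fdr([r["p"] for r in fitted])
            for r, qv in zip(fitted, q):
                r["q"] = float(qv)
        for r in fam:
            r.setdefault("q", np.nan)
            lo = r["effect"] - 1.96 * r["se"] if np.isfinite(r["se"]) else np.nan
            hi = r["effect"] + 1.96 * r["se"] if np.isfinite(r["se"]) else np.nan
            r["ci_low"], r["ci_high"] = lo, hi
            if r["model"] in ("logistic", "cox") and np.isfinite(r["effect"]):
                r["ratio"] = float(np.exp(r["effect"]))
            else:
                r["ratio"] = np.nan
        records.extend(fam)
    return pd.DataFrame.from_records(records)


def polygenic_score(
    geno: GenotypeDataset,
    gwas: pd.DataFrame,
    p_threshold: float = 5e-8,
    snp_col: str = "snp_id",
    effect_col: str = "effect",
    p_col: str = "p",
    effect_allele_col: str = "effect_allele",
    other_allele_col: str = "other_allele",
):
    """Additive weighted genetic score from genome-wide-significant SNPs.

    score_i = sum over passing SNPs of (aligned dosage) x effect. A SNP
    whose GWAS effect allele is the cohort's counted allele contributes
    directly; a swapped SNP (effect allele = cohort's other allele) has its
    effect negated (equivalently the dosage flipped to 2 - d); SNPs whose
    alleles cannot be reconciled are dropped with a warning.
    """
    sig = gwas.loc[gwas[p_col].to_numpy() < p_threshold]
    if len(sig) == 0:
        raise ValueError(f"no SNPs pass p < {p_threshold}")
    idx = {s: j for j, s in enumerate(geno.snp_ids.tolist())}
    score = np.zeros(geno.n_samples)
    used = 0
    dropped = []
    for _, row in sig.iterrows():
        j = idx.get(row[snp_col])
        if j is None:
            dropped.append(row[snp_col])
            continue
        eff = float(row[effect_col])
        ea, oa = row[effect_allele_col], row[other_allele_col]
        if ea == geno.allele_counted[j] and oa == geno.allele_other[j]:
            d = geno.dosage[:, j]
        elif ea == geno.allele_other[j] and oa == geno.allele_counted[j]:
            d = 2.0 - geno.dosage[:, j]
        else:
            dropped.append(row[snp_col])
            continue
        score += d * eff
        used += 1
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} SNPs with unresolvable alleles or absent "
            "from the cohort", stacklevel=2,
        )
    if used == 0:
        raise ValueError("no GWAS SNPs could be aligned to the cohort")
    from .predictors import ScoreVector

    return ScoreVector(
        sample_id=geno.sample_ids.copy(),
        score=score,
        n_probes_used=used,
        frac_missing=1.0 - used / len(sig),
    )
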