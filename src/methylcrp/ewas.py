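"""Mass-univariate EWAS of log CRP with inflation and attenuation summaries.

Each probe enters its own linear model ``log(CRP + 0.01) ~ probe + covariates``.
Per-probe statistics are computed via the Frisch-Waugh-Lovell identity —
probe and phenotype are residualized on the covariate design once, and the
per-probe simple regressions on the residuals reproduce the multiple-
regression coefficients, standard errors and t tests exactly (same degrees
of freedom as the full model).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MethylationDataset

__all__ = [
    "run_ewas",
    "genomic_inflation",
    "attenuation_stats",
    "compare_ewas",
    "EWAS_THRESHOLD",
]

#: Commonly employed epigenome-wide significance threshold.
EWAS_THRESHOLD = 3.6e-8

#: Median of the 1-df chi-square distribution.
_CHI2_1DF_MEDIAN = stats.chi2.ppf(0.5, df=1)  # 0.45493642...


def run_ewas(
    meth: MethylationDataset,
    log_crp,
    covariates=None,
    model_tag: str = "custom",
    sample_mask=None,
) -> pd.DataFrame:
    """Per-probe OLS of log CRP on each probe's beta-value plus covariates.

    Parameters
    ----------
    meth : MethylationDataset aligned row-wise with ``log_crp``.
    log_crp : vector of prepared (log-transformed) CRP values.
    covariates : optional design (DataFrame or array); an intercept is
        always added. ``None`` fits probe-only models.
    sample_mask : optional boolean mask of samples to use (e.g. the
        outlier-inclusion mask).

    Returns
    -------
    DataFrame with probe_id, chr, pos, effect, se, p, n, model_tag; one row
    per probe. Constant probes get effect 0, p 1 and ``constant_probe``
    flag.
    """
    y = np.asarray(log_crp, dtype=float)
    beta = meth.beta
    if sample_mask is not None:
        sample_mask = np.asarray(sample_mask, dtype=bool)
        y = y[sample_mask]
        beta = beta[sample_mask]
    n = y.size
    if n < 10:
        raise ValueError(f"need at least 10 complete cases, got {n}")

    if covariates is None:
        X = np.ones((n, 1))
    else:
        C = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if sample_mask is not None:
            C = C[sample_mask]
        X = np.column_stack([np.ones(n), C])

    # residualize y and all probes on the covariate design in one pass
    Q, _ = np.linalg.qr(X)
    y_res = y - Q @ (Q.T @ y)
    B_res = beta - Q @ (Q.T @ beta)

    sxx = np.einsum("ij,ij->j", B_res, B_res)
    sxy = B_res.T @ y_res
    df = n - X.shape[1] - 1
    if df <= 0:
        raise ValueError("not enough residual degrees of freedom")

    constant = sxx < 1e-12
    safe_sxx = np.where(constant, 1.0, sxx)
    effect = sxy / safe_sxx
    rss = y_res @ y_res - effect**2 * safe_sxx
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / df
    se = np.sqrt(sigma2 / safe_sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, effect / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(tstat), df=df)
    p = np.clip(p, np.nextafter(0, 1), 1.0)

    effect = np.where(constant, 0.0, effect)
    se = np.where(constant, np.nan, se)
    p = np.where(constant, 1.0, p)

    return pd.DataFrame(
        {
            "probe_id": meth.probe_ids,
            "chr": meth.probe_chr,
            "pos": meth.probe_pos,
            "effect": effect,
            "se": se,
            "p": p,
            "n": n,
            "model_tag": model_tag,
            "constant_probe": constant,
        }
    )


def genomic_inflation(p_values) -> float:
    """Genomic inflation factor: median implied 1-df chi-square over the
    null 1-df chi-square median (~0.4549)."""
    p = np.asarray(p_values, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if p.size < 100:
        import warnings

        warnings.warn(
            f"lambda computed from only {p.size} p-values; estimate unstable",
            stacklevel=2,
        )
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / _CHI2_1DF_MEDIAN)


def n_significant(ewas: pd.DataFrame, threshold: float = EWAS_THRESHOLD) -> int:
    return int((ewas["p"].to_numpy() < threshold).sum())


def attenuation_stats(
    basic: pd.DataFrame,
    adjusted: pd.DataFrame,
    threshold: float = EWAS_THRESHOLD,
) -> dict:
    """Attenuation of basic-model hits after further adjustment.

    Over probes significant in the basic model at ``threshold``: the
    percentage whose adjusted p is no longer significant, and the mean
    per-probe effect attenuation 100 * (|b_basic| - |b_adj|) / |b_basic|
    (absolute effects; positive = shrinkage toward zero).
    """
    merged = basic.merge(
        adjusted[["probe_id", "effect", "p"]],
        on="probe_id",
        suffixes=("_basic", "_adj"),
    )
    if len(merged) != len(basic):
        raise ValueError("basic and adjusted results must share a probe universe")
    hits = merged[merged["p_basic"].to_numpy() < threshold]
    if len(hits) == 0:
        return {
            "n_basic_hits": 0,
            "pct_lost": np.nan,
            "mean_effect_attenuation_pct": np.nan,
            "empty": True,
        }
    lost = (hits["p_adj"].to_numpy() >= threshold).mean() * 100.0
    b = np.abs(hits["effect_basic"].to_numpy())
    a = np.abs(hits["effect_adj"].to_numpy())
    atten = 100.0 * (b - a) / b
    return {
        "n_basic_hits": int(len(hits)),
        "pct_lost": float(lost),
        "mean_effect_attenuation_pct": float(atten.mean()),
        "empty": False,
    }


def compare_ewas(
    mine: pd.DataFrame,
    reference: pd.DataFrame,
    threshold: float = EWAS_THRESHOLD,
    effect_col: str = "effect",
    p_col: str = "p",
) -> dict:
    """Pearson correlation of effect sizes on shared significant probes.

    Restricts to probes passing ``threshold`` in the reference table and
    present in ``mine``; requires at least 3 shared probes.
    """
    ref_sig = reference[reference[p_col].to_numpy() < threshold]
    merged = mine[["probe_id", "effect"]].merge(
        ref_sig[["probe_id", effect_col]].rename(columns={effect_col: "ref_effect"}),
        on="probe_id",
    )
    if len(merged) < 3:
        raise ValueError(f"only {len(merged)} shared significant probes (need >= 3)")
    r = float(np.corrcoef(merged["effect"], merged["ref_effect"])[0, 1])
    return {"r": r, "n_shared": int(len(merged))}
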