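"""CRP and covariate preprocessing plus SNP quality control.

The CRP pipeline is: (1) low-sensitivity assay readings below the 3 mg/L
detection limit are assigned 1.5 mg/L; (2) all concentrations are mapped to
log(CRP + 0.01); (3) values outside median +/- 4 standard deviations of the
log scale are excluded. Covariate removal is plain OLS residualization with
optional scaling to mean zero / unit variance; the granulocyte fraction is
dropped from any six-column cell-proportion design because the six
fractions sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CELL_TYPES, GenotypeDataset

__all__ = [
    "PreparedPhenotype",
    "transform_crp",
    "filter_outliers",
    "residualize",
    "build_covariate_matrix",
    "qc_genotypes",
    "LOW_SENS_IMPUTE_VALUE",
    "CRP_LOG_OFFSET",
]

LOW_SENS_IMPUTE_VALUE = 1.5  # mg/L assigned to low-sensitivity readings < 3 mg/L
LOW_SENS_DETECTION_LIMIT = 3.0
CRP_LOG_OFFSET = 0.01
OUTLIER_SD_MULTIPLE = 4.0

#: Covariates of the basic EWAS model (cells minus granulocytes, plus batch
#: indicators added separately).
BASIC_CELLS = tuple(c for c in CELL_TYPES if c != "gran")


@dataclass
class PreparedPhenotype:
    """Log-transformed CRP with inclusion mask and imputation provenance."""

    sample_id: np.ndarray
    log_crp: np.ndarray
    included: np.ndarray
    imputed_low_sens: np.ndarray

    @property
    def n_excluded(self) -> int:
        return int((~self.included).sum())

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "log_crp": self.log_crp,
                "included": self.included,
                "imputed_low_sens": self.imputed_low_sens,
            }
        )


def transform_crp(
    crp_mg_per_l,
    assay,
    below_detection=None,
    sample_id=None,
    apply_outlier_filter: bool = True,
) -> PreparedPhenotype:
    """Prepare raw CRP concentrations for analysis.

    Low-sensitivity assay readings below 3 mg/L are assigned 1.5 mg/L, then
    every value is log-transformed after adding 0.01 (preventing log(0)).
    The median +/- 4 SD exclusion runs on the log scale, after imputation.

    Parameters
    ----------
    crp_mg_per_l : array of non-negative concentrations (mg/L)
    assay : array of {"high", "low", "wide"} per sample
    below_detection : optional boolean array; if omitted, low-sensitivity
        readings under 3 mg/L are treated as below detection.
    """
    crp = np.asarray(crp_mg_per_l, dtype=float)
    assay = np.asarray(assay)
    if np.any(crp < 0):
        raise ValueError("CRP concentrations must be non-negative (inputs must "
                         "be concentrations, not logs)")
    low = assay == "low"
    if below_detection is None:
        below_detection = low & (crp < LOW_SENS_DETECTION_LIMIT)
    else:
        below_detection = np.asarray(below_detection, dtype=bool) & low
    adjusted = np.where(below_detection, LOW_SENS_IMPUTE_VALUE, crp)
    log_crp = np.log(adjusted + CRP_LOG_OFFSET)
    if apply_outlier_filter:
        included = filter_outliers(log_crp)
    else:
        included = np.ones(log_crp.size, dtype=bool)
    if sample_id is None:
        sample_id = np.array([f"S{i:06d}" for i in range(crp.size)])
    return PreparedPhenotype(
        sample_id=np.asarray(sample_id),
        log_crp=log_crp,
        included=included,
        imputed_low_sens=below_detection.copy(),
    )


def filter_outliers(values, sd_multiple: float = OUTLIER_SD_MULTIPLE) -> np.ndarray:
    """Mask of values within median +/- ``sd_multiple`` * SD.

    SD is the plain sample standard deviation (ddof=1) of the full vector.
    A constant vector has SD zero, so only values equal to the median are
    retained (vacuously all of them).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to compute an outlier mask")
    med = np.median(values)
    sd = values.std(ddof=1)
    return np.abs(values - med) <= sd_multiple * sd


def build_covariate_matrix(
    pheno: pd.DataFrame,
    model: str = "basic",
    extra: list[str] | None = None,
) -> pd.DataFrame:
    """Assemble the covariate design for EWAS / adjustment models.

    ``basic`` = age, sex, five cell proportions (granulocytes dropped) and
    batch indicators. ``full`` adds alcohol, log BMI, deprivation,
    education, smoking score and 20 ancestry components. ``custom`` uses
    only ``extra`` columns.
    """
    cols: dict[str, np.ndarray] = {}
    if model in ("basic", "full"):
        cols["age"] = pheno["age"].to_numpy(dtype=float)
        cols["sex"] = pheno["sex"].to_numpy(dtype=float)
        for c in BASIC_CELLS:
            cols[c] = pheno[c].to_numpy(dtype=float)
        batch = pd.get_dummies(pheno["batch"], prefix="batch", drop_first=True)
        for c in batch.columns:
            cols[str(c)] = batch[c].to_numpy(dtype=float)
    if model == "full":
        cols["alcohol"] = pheno["alcohol"].to_numpy(dtype=float)
        cols["log_bmi"] = np.log(pheno["bmi"].to_numpy(dtype=float))
        cols["deprivation"] = pheno["deprivation"].to_numpy(dtype=float)
        cols["education"] = pheno["education"].to_numpy(dtype=float)
        cols["smoking_score"] = pheno["smoking_score"].to_numpy(dtype=float)
        for j in range(1, 21):
            cols[f"ancestry_{j}"] = pheno[f"ancestry_{j}"].to_numpy(dtype=float)
    if extra:
        for c in extra:
            if c == "bmi":
                cols["log_bmi"] = np.log(pheno["bmi"].to_numpy(dtype=float))
            else:
                cols[c] = pheno[c].to_numpy(dtype=float)
    if not cols:
        raise ValueError(f"no covariates for model {model!r}")
    return pd.DataFrame(cols, index=pheno.index)


def _drop_granulocytes(covariates: pd.DataFrame) -> pd.DataFrame:
    """Drop the granulocyte column whenever all six cell fractions appear."""
    if all(c in covariates.columns for c in CELL_TYPES):
        return covariates.drop(columns=["gran"])
    return covariates


def residualize(
    target,
    covariates,
    scale: bool = False,
) -> np.ndarray:
    """OLS residuals of ``target`` (vector or matrix columns) on covariates.

    An intercept is always included. If ``scale`` is set, each residual
    column is standardized to mean zero / unit variance (ddof=0). A design
    containing all six cell-proportion columns has the granulocyte column
    dropped automatically; any remaining rank deficiency raises with the
    names of the collinear columns.
    """
    y = np.asarray(target, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    if isinstance(covariates, pd.DataFrame):
        covariates = _drop_granulocytes(covariates)
        names = list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{j}" for j in range(X.shape[1])]
    design = np.column_stack([np.ones(X.shape[0]), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        cur = np.ones((X.shape[0], 1))
        for j in range(X.shape[1]):
            cand = np.column_stack([cur, X[:, j]])
            if np.linalg.matrix_rank(cand) == cur.shape[1]:
                bad.append(names[j])
            else:
                cur = cand
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    if scale:
        sd = resid.std(axis=0, ddof=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        resid = (resid - resid.mean(axis=0)) / sd
    return resid[:, 0] if squeeze else resid


def _hwe_chi2_p(dosage: np.ndarray) -> float:
    """One-degree chi-square test of Hardy-Weinberg proportions from hard
    genotype counts (missing values ignored)."""
    d = dosage[np.isfinite(dosage)]
    n = d.size
    if n == 0:
        return 1.0
    counts = np.array([(d == 0).sum(), (d == 1).sum(), (d == 2).sum()], dtype=float)
    p = (counts[1] + 2.0 * counts[2]) / (2.0 * n)
    if p <= 0.0 or p >= 1.0:
        return 1.0  # monomorphic: HWE is vacuous (MAF filter removes it)
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def qc_genotypes(
    geno: GenotypeDataset,
    max_missing: float = 0.02,
    hwe_p_min: float = 1e-6,
    maf_min: float = 0.01,
) -> tuple[GenotypeDataset, dict]:
    """SNP quality control: missingness, Hardy-Weinberg, allele frequency.

    SNPs are removed on missing call rate > 2%, HWE exact-proportion
    chi-square p < 1e-6, or minor allele frequency < 1%. Surviving SNPs
    have remaining missing dosages mean-imputed. Returns the filtered
    dataset plus a report of removals per criterion.
    """
    missing = np.mean(~np.isfinite(geno.dosage), axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(geno.dosage, axis=0) / 2.0
    freq = np.where(np.isfinite(freq), freq, 0.0)
    maf = np.minimum(freq, 1.0 - freq)
    hwe = np.array([_hwe_chi2_p(geno.dosage[:, j]) for j in range(geno.n_snps)])

    fail_missing = missing > max_missing
    fail_hwe = hwe < hwe_p_min
    fail_maf = maf < maf_min
    keep = ~(fail_missing | fail_hwe | fail_maf)
    report = {
        "n_input": int(geno.n_snps),
        "removed_missing": int(fail_missing.sum()),
        "removed_hwe": int(fail_hwe.sum()),
        "removed_maf": int(fail_maf.sum()),
        "n_kept": int(keep.sum()),
    }
    if report["n_kept"] == 0:
        raise ValueError(f"no SNPs survived quality control: {report}")

    out = geno.subset_snps(keep)
    out.maf = maf[keep]
    out.missing_rate = missing[keep]
    out.hwe_p = hwe[keep]
    # mean-impute remaining missing dosages
    col_mean = np.nanmean(out.dosage, axis=0)
    nan_r, nan_c = np.nonzero(~np.isfinite(out.dosage))
    out.dosage[nan_r, nan_c] = col_mean[nan_c]
    return out, report
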