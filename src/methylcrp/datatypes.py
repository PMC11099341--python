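"""Core in-memory containers shared across the analysis modules.

Methylation is carried as a dense samples x probes matrix of beta-values
(methylated fraction in [0, 1]) with per-probe genomic annotation; genotypes
as an additively coded dosage matrix in [0, 2]; phenotypes as a long-format
:class:`pandas.DataFrame` (one row per sample x wave).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "MethylationDataset",
    "GenotypeDataset",
    "SyntheticTruth",
    "VarianceEstimate",
    "CELL_TYPES",
]

#: Estimated white-blood-cell fractions carried in phenotype tables. The six
#: fractions sum to one; granulocytes are dropped from regression designs to
#: avoid collinearity.
CELL_TYPES = ("cd4t", "cd8t", "bcell", "mono", "nk", "gran")


@dataclass
class MethylationDataset:
    """Samples x probes beta-value matrix with probe genomic annotation.

    Parameters
    ----------
    sample_ids : array of str
        One id per row of ``beta``.
    probe_ids : array of str
        One id per column of ``beta``; unique.
    beta : ndarray, shape (n_samples, n_probes)
        Methylated fractions in [0, 1].
    probe_chr : array of str
        Chromosome label per probe.
    probe_pos : ndarray of int
        1-based base-pair position per probe.
    array_tag : str
        Free-text label for the measurement platform (e.g. ``"epic"``).
    """

    sample_ids: np.ndarray
    probe_ids: np.ndarray
    beta: np.ndarray
    probe_chr: np.ndarray
    probe_pos: np.ndarray
    array_tag: str = "epic"

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.probe_ids = np.asarray(self.probe_ids)
        self.beta = np.asarray(self.beta, dtype=float)
        self.probe_chr = np.asarray(self.probe_chr)
        self.probe_pos = np.asarray(self.probe_pos, dtype=np.int64)
        if self.beta.shape != (self.sample_ids.size, self.probe_ids.size):
            raise ValueError(
                f"beta shape {self.beta.shape} does not match "
                f"{self.sample_ids.size} samples x {self.probe_ids.size} probes"
            )
        if len(set(self.probe_ids.tolist())) != self.probe_ids.size:
            raise ValueError("probe_ids must be unique")
        if self.beta.size and (self.beta.min() < 0.0 or self.beta.max() > 1.0):
            raise ValueError("beta values must lie in [0, 1]")
        if self.probe_pos.size and self.probe_pos.min() < 1:
            raise ValueError("probe positions are 1-based and must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.sample_ids.size

    @property
    def n_probes(self) -> int:
        return self.probe_ids.size

    def probe_index(self, probe_ids) -> np.ndarray:
        """Column indices of ``probe_ids`` (raises KeyError if absent)."""
        lookup = {p: i for i, p in enumerate(self.probe_ids.tolist())}
        try:
            return np.array([lookup[p] for p in probe_ids], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - message formatting
            raise KeyError(f"probe {exc.args[0]!r} not in dataset") from None

    def subset_probes(self, keep: np.ndarray, array_tag: str | None = None) -> "MethylationDataset":
        """Return a copy restricted to probe columns ``keep`` (index array)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return MethylationDataset(
            sample_ids=self.sample_ids.copy(),
            probe_ids=self.probe_ids[keep].copy(),
            beta=self.beta[:, keep].copy(),
            probe_chr=self.probe_chr[keep].copy(),
            probe_pos=self.probe_pos[keep].copy(),
            array_tag=self.array_tag if array_tag is None else array_tag,
        )

    def annotation_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"probe_id": self.probe_ids, "chr": self.probe_chr, "pos": self.probe_pos}
        )


@dataclass
class GenotypeDataset:
    """Additively coded SNP dosages (0..2 copies of the counted allele).

    ``allele_counted``/``allele_other`` carry the allele labels needed to
    align external GWAS effect sizes; ``maf``, ``missing_rate`` and ``hwe_p``
    are per-SNP quality metrics. Missing dosages are NaN until imputed.
    """

    sample_ids: np.ndarray
    snp_ids: np.ndarray
    dosage: np.ndarray
    allele_counted: np.ndarray
    allele_other: np.ndarray
    maf: np.ndarray = field(default=None)  # type: ignore[assignment]
    missing_rate: np.ndarray = field(default=None)  # type: ignore[assignment]
    hwe_p: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.snp_ids = np.asarray(self.snp_ids)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (self.sample_ids.size, self.snp_ids.size):
            raise ValueError("dosage shape does not match ids")
        finite = self.dosage[np.isfinite(self.dosage)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 2.0):
            raise ValueError("dosages must lie in [0, 2]")
        if self.maf is None:
            self.maf = self._compute_maf()
        else:
            self.maf = np.asarray(self.maf, dtype=float)
        if self.missing_rate is None:
            self.missing_rate = np.mean(~np.isfinite(self.dosage), axis=0)
        else:
            self.missing_rate = np.asarray(self.missing_rate, dtype=float)
        if self.hwe_p is None:
            self.hwe_p = np.ones(self.snp_ids.size)
        else:
            self.hwe_p = np.asarray(self.hwe_p, dtype=float)

    def _compute_maf(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.dosage, axis=0) / 2.0
        freq = np.where(np.isfinite(freq), freq, 0.0)
        return np.minimum(freq, 1.0 - freq)

    @property
    def n_samples(self) -> int:
        return self.sample_ids.size

    @property
    def n_snps(self) -> int:
        return self.snp_ids.size

    def subset_snps(self, keep: np.ndarray) -> "GenotypeDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeDataset(
            sample_ids=self.sample_ids.copy(),
            snp_ids=self.snp_ids[keep].copy(),
            dosage=self.dosage[:, keep].copy(),
            allele_counted=self.allele_counted[keep].copy(),
            allele_other=self.allele_other[keep].copy(),
            maf=self.maf[keep].copy(),
            missing_rate=self.missing_rate[keep].copy(),
            hwe_p=self.hwe_p[keep].copy(),
        )


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the cohort generator.

    Holds the causal feature sets and the realized variance decomposition of
    log CRP so parameter-recovery tests can compare estimates against truth.
    ``components`` carries the per-sample standardized generative components
    (methylation, genetic, per-confounder, residual); ``architecture`` is the
    frozen generative law reused when deriving matched test cohorts.
    """

    causal_probe_ids: np.ndarray
    causal_probe_effects: np.ndarray
    causal_snp_ids: np.ndarray
    causal_snp_effects: np.ndarray
    true_var_dnam: float
    true_var_snp: float
    confounder_var: dict[str, float]
    block_of_probe: np.ndarray
    components: pd.DataFrame
    latent_log_crp: np.ndarray
    architecture: Any = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "causal_probe_ids": self.causal_probe_ids.tolist(),
            "causal_probe_effects": self.causal_probe_effects.tolist(),
            "causal_snp_ids": self.causal_snp_ids.tolist(),
            "causal_snp_effects": self.causal_snp_effects.tolist(),
            "true_var_dnam": self.true_var_dnam,
            "true_var_snp": self.true_var_snp,
            "confounder_var": self.confounder_var,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class VarianceEstimate:
    """A variance fraction with its interval and provenance.

    ``component`` is what the fraction attributes variance to (methylation,
    genetic, ...); ``method`` is ``"bayes"`` (posterior mean + credible
    interval) or ``"reml"`` (REML point estimate + Wald confidence interval);
    ``conditioning`` lists the other random components present in the model.
    """

    component: str
    estimate: float
    lower: float
    upper: float
    method: str
    conditioning: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        tol = 1e-9 * max(1.0, abs(self.estimate))
        if not (self.lower - tol <= self.estimate <= self.upper + tol):
            raise ValueError(
                f"interval ({self.lower}, {self.upper}) does not bracket "
                f"estimate {self.estimate}"
            )

    def as_dict(self) -> dict:
        return {
            "component": self.component,
            "estimate": self.estimate,
            "lower": self.lower,
            "upper": self.upper,
            "method": self.method,
            "conditioning": ",".join(self.conditioning),
        }
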