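"""Synthetic cohort generator for blood-methylation studies of CRP.

Emulates the data structures a blood EWAS of C-reactive protein consumes: a
samples x probes beta-value matrix with probes organized in short, highly
correlated genomic blocks (members within 2.5 kb); an additively coded SNP
dosage matrix in Hardy-Weinberg proportions; and a phenotype table carrying
CRP (mg/L, with high-/low-sensitivity assay behavior), age, sex, six
estimated white-blood-cell proportions, batch, lifestyle covariates, 20
ancestry components, longitudinal waves, mortality follow-up and a battery
of downstream health outcomes.

The generative model couples methylation and CRP through shared latent
factors rather than explicit causal arrows: standardized log CRP is built
from an (empirically orthogonalized) sum of a methylation-linked component,
a polygenic score, confounder paths and residual noise, so the realized
variance decomposition matches the configured fractions essentially exactly
and is recorded in :class:`~methylcrp.datatypes.SyntheticTruth`.

Methylation is generated on a logistic latent (M-value-like) scale and
mapped through the inverse logit, guaranteeing valid beta-values in (0, 1)
while keeping the effect structure additive on the latent scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .datatypes import CELL_TYPES, GenotypeDataset, MethylationDataset, SyntheticTruth

__all__ = [
    "SimConfig",
    "generate_cohort",
    "derive_test_cohort",
    "generate_longitudinal",
    "generate_wave_methylation",
    "N_CONTINUOUS_OUTCOMES",
    "N_BINARY_OUTCOMES",
]

N_CONTINUOUS_OUTCOMES = 21
N_BINARY_OUTCOMES = 4
N_ANCESTRY = 20

#: Mean white-blood-cell fractions (Dirichlet means); granulocytes dominate
#: whole blood.
_CELL_MEANS = np.array([0.15, 0.08, 0.05, 0.08, 0.04, 0.60])
_CELL_CONCENTRATION = 120.0

#: log CRP (natural scale) location/scale: exp(0.6 + 1.0 z) gives a median
#: of ~1.8 mg/L and mean ~3 mg/L, matching adult population cohorts.
_CRP_LOG_MU = 0.6
_CRP_LOG_SIGMA = 1.0

#: Low-sensitivity CRP assays cannot resolve concentrations below this.
LOW_SENSITIVITY_LIMIT = 3.0


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic study.

    Variance fractions refer to standardized log CRP. ``confounder_effects``
    are standardized path coefficients; confounder k contributes effect**2
    of the phenotypic variance. The residual fraction is whatever remains
    after methylation, genetics and confounders; a budget exceeding 1 is a
    configuration error.
    """

    n_samples: int = 1000
    n_probes: int = 2000
    n_snps: int = 500
    block_size_range: tuple[int, int] = (1, 5)
    within_block_corr: float = 0.7
    frac_causal_probes: float = 0.025
    frac_causal_snps: float = 0.01
    var_dnam: float = 0.50
    var_snp: float = 0.13
    confounder_effects: dict[str, float] = field(
        default_factory=lambda: {
            "bmi": 0.30,
            "smoking_score": 0.25,
            "alcohol": 0.08,
            "deprivation": 0.08,
            "education": -0.08,
            "age": 0.15,
            "sex": 0.10,
            "cells": 0.15,
            "batch": 0.05,
        }
    )
    n_waves: int = 1
    assay_per_wave: tuple[str, ...] = ("high",)
    probes_missing_in_test: int = 0
    mean_age: float = 50.0
    sd_age: float = 10.0
    outcome_effect: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_waves < 1:
            raise ValueError("n_waves must be >= 1")
        if not 0.0 <= self.within_block_corr < 1.0:
            raise ValueError("within_block_corr must lie in [0, 1)")
        for name, val in (("var_dnam", self.var_dnam), ("var_snp", self.var_snp)):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.var_budget() > 1.0 + 1e-9:
            raise ValueError(
                f"infeasible variance budget: dnam {self.var_dnam} + snp "
                f"{self.var_snp} + confounders {self.confounder_var():.4f} > 1"
            )
        lo, hi = self.block_size_range
        if not (1 <= lo <= hi):
            raise ValueError("block_size_range must satisfy 1 <= lo <= hi")
        bad = [a for a in self.assay_per_wave if a not in ("high", "low", "wide")]
        if bad:
            raise ValueError(f"unknown assay labels: {bad}")

    def confounder_var(self) -> float:
        return float(sum(v * v for v in self.confounder_effects.values()))

    def var_budget(self) -> float:
        return self.var_dnam + self.var_snp + self.confounder_var()

    def var_residual(self) -> float:
        return 1.0 - self.var_budget()


@dataclass
class _Architecture:
    """Frozen generative law: everything that is shared between the training
    cohort and any derived test cohort."""

    config: SimConfig
    probe_ids: np.ndarray
    probe_chr: np.ndarray
    probe_pos: np.ndarray
    block_of_probe: np.ndarray
    probe_mu: np.ndarray
    probe_scale: np.ndarray
    causal_probe_mask: np.ndarray
    causal_probe_weights: np.ndarray  # full length, zero off the causal set
    conf_loading: np.ndarray  # n_probes x n_confounder_channels
    conf_channels: tuple[str, ...]
    cell_loading: np.ndarray
    batch_offsets: np.ndarray  # n_probes x n_batches
    snp_ids: np.ndarray
    snp_freq: np.ndarray
    allele_counted: np.ndarray
    allele_other: np.ndarray
    causal_snp_mask: np.ndarray
    causal_snp_weights: np.ndarray
    outcome_slopes: np.ndarray
    outcome_logit_slopes: np.ndarray
    hazard_log_hr: float
    n_batches: int = 10


def _build_architecture(config: SimConfig, rng: np.random.Generator) -> _Architecture:
    m = config.n_probes
    lo, hi = config.block_size_range

    # --- probe blocks: sizes uniform in range, members within 2.5 kb -------
    sizes: list[int] = []
    total = 0
    while total < m:
        size = int(rng.integers(lo, hi + 1))
        size = min(size, m - total)
        sizes.append(size)
        total += size
    n_blocks = len(sizes)
    block_of_probe = np.repeat(np.arange(n_blocks), sizes)

    chrom = np.array([f"chr{(b % 22) + 1}" for b in block_of_probe])
    # each block lives in its own 1 Mb window; members within 2.5 kb of lead
    pos = np.empty(m, dtype=np.int64)
    start = 0
    for b, size in enumerate(sizes):
        base = 1 + (b // 22) * 1_000_000 + rng.integers(0, 500_000)
        offs = np.sort(rng.choice(2500, size=size, replace=False))
        pos[start : start + size] = base + offs
        start += size
    probe_ids = np.array([f"cg{i:08d}" for i in range(m)])

    probe_mu = rng.uniform(-1.5, 1.5, size=m)
    probe_scale = rng.uniform(0.5, 1.1, size=m)

    # --- causal probes ------------------------------------------------------
    # Each causal CpG carries an independent inflammation-linked signal, so
    # causal probes are drawn from singleton blocks where possible: tying
    # the signal to independent sites keeps the generative variance
    # decomposition identifiable on the probe scale (signal spread across a
    # correlated block cannot be represented by any probe-level
    # sum-of-squares without attenuation or contrast inflation). Correlated
    # blocks model the local co-methylation background.
    n_causal = max(1, int(round(config.frac_causal_probes * m))) if config.var_dnam > 0 else 0
    causal_mask = np.zeros(m, dtype=bool)
    block_sizes = np.bincount(block_of_probe, minlength=n_blocks)
    singleton_probes = np.flatnonzero(block_sizes[block_of_probe] == 1)
    if singleton_probes.size >= n_causal:
        chosen = rng.choice(singleton_probes, size=n_causal, replace=False)
        causal_mask[chosen] = True
    else:
        # not enough singletons (e.g. min block size > 1): fall back to
        # whole blocks; recovery of the variance fraction is then
        # attenuated by within-block correlation, by design
        block_order = rng.permutation(n_blocks)
        count = 0
        for b in block_order:
            if count >= n_causal:
                break
            members = np.flatnonzero(block_of_probe == b)
            causal_mask[members] = True
            count += members.size
    causal_weights = np.zeros(m)
    causal_weights[causal_mask] = rng.normal(0.0, 1.0, size=int(causal_mask.sum()))

    # --- confounder loadings on a disjoint subset of probes ---------------
    conf_channels = tuple(
        k for k in ("bmi", "smoking_score") if k in config.confounder_effects
    )
    conf_loading = np.zeros((m, len(conf_channels)))
    non_causal = np.flatnonzero(~causal_mask)
    n_conf_probes = min(non_causal.size, int(0.05 * m))
    if n_conf_probes and conf_channels:
        chosen = rng.choice(non_causal, size=n_conf_probes, replace=False)
        channel = rng.integers(0, len(conf_channels), size=n_conf_probes)
        signs = rng.choice([-1.0, 1.0], size=n_conf_probes)
        mags = rng.uniform(0.5, 1.0, size=n_conf_probes)
        conf_loading[chosen, channel] = signs * mags

    # broad technical/biological structure: cell composition and batch
    cell_loading = np.zeros(m)
    cell_probes = rng.random(m) < 0.30
    cell_probes &= ~causal_mask
    cell_loading[cell_probes] = rng.normal(0.0, 0.3, size=int(cell_probes.sum()))
    n_batches = 10
    batch_offsets = np.zeros((m, n_batches))
    batch_probes = (rng.random(m) < 0.20) & ~causal_mask
    batch_offsets[batch_probes] = rng.normal(
        0.0, 0.2, size=(int(batch_probes.sum()), n_batches)
    )

    # --- SNPs ---------------------------------------------------------------
    s = config.n_snps
    snp_freq = rng.uniform(0.05, 0.5, size=s)
    snp_ids = np.array([f"rs{i:07d}" for i in range(s)])
    alleles = np.array(list("ACGT"))
    a_idx = rng.integers(0, 4, size=s)
    b_shift = rng.integers(1, 4, size=s)
    allele_counted = alleles[a_idx]
    allele_other = alleles[(a_idx + b_shift) % 4]
    n_causal_snp = max(1, int(round(config.frac_causal_snps * s))) if config.var_snp > 0 else 0
    causal_snp_mask = np.zeros(s, dtype=bool)
    causal_snp_mask[rng.choice(s, size=n_causal_snp, replace=False)] = True
    causal_snp_weights = np.zeros(s)
    causal_snp_weights[causal_snp_mask] = rng.normal(0.0, 1.0, size=n_causal_snp)

    # --- downstream outcomes ------------------------------------------------
    eff = config.outcome_effect
    outcome_slopes = eff * rng.uniform(0.15, 0.45, size=N_CONTINUOUS_OUTCOMES)
    outcome_logit_slopes = eff * rng.uniform(0.25, 0.55, size=N_BINARY_OUTCOMES)
    hazard_log_hr = eff * 0.35

    return _Architecture(
        config=config,
        probe_ids=probe_ids,
        probe_chr=chrom,
        probe_pos=pos,
        block_of_probe=block_of_probe,
        probe_mu=probe_mu,
        probe_scale=probe_scale,
        causal_probe_mask=causal_mask,
        causal_probe_weights=causal_weights,
        conf_loading=conf_loading,
        conf_channels=conf_channels,
        cell_loading=cell_loading,
        batch_offsets=batch_offsets,
        snp_ids=snp_ids,
        snp_freq=snp_freq,
        allele_counted=allele_counted,
        allele_other=allele_other,
        causal_snp_mask=causal_snp_mask,
        causal_snp_weights=causal_snp_weights,
        outcome_slopes=outcome_slopes,
        outcome_logit_slopes=outcome_logit_slopes,
        hazard_log_hr=hazard_log_hr,
        n_batches=n_batches,
    )


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0.0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _orthonormalize(columns: list[np.ndarray]) -> list[np.ndarray]:
    """Gram-Schmidt on sample vectors: center, residualize against earlier
    columns, scale to unit sample variance. Degenerate columns become 0."""
    out: list[np.ndarray] = []
    for col in columns:
        v = np.asarray(col, dtype=float) - np.mean(col)
        for u in out:
            v = v - (v @ u) / (u @ u) * u if u.any() else v
        sd = v.std()
        if sd < 1e-12:
            out.append(np.zeros_like(v))
        else:
            out.append(v / sd)
    return out


def _sample_cohort(
    arch: _Architecture,
    n: int,
    seed_seq: np.random.SeedSequence,
    sample_prefix: str = "S",
    age_shift: float = 0.0,
    array_tag: str = "epic",
):
    """Draw one cohort from the frozen law. Returns the full tuple."""
    cfg = arch.config
    s_probe, s_geno, s_pheno, s_outcome = (
        np.random.default_rng(child) for child in seed_seq.spawn(4)
    )

    sample_ids = np.array([f"{sample_prefix}{i:06d}" for i in range(n)])

    # ---- confounders -------------------------------------------------------
    age = s_pheno.normal(cfg.mean_age + age_shift, cfg.sd_age, size=n)
    sex = s_pheno.integers(0, 2, size=n).astype(float)
    bmi = np.exp(s_pheno.normal(3.3, 0.15, size=n))  # ~27 kg/m2, right-skewed
    smoking_score = s_pheno.normal(0.0, 1.0, size=n)
    alcohol = s_pheno.gamma(2.0, 4.0, size=n)  # units/week
    deprivation = s_pheno.normal(0.0, 1.0, size=n)
    education = s_pheno.integers(0, 11, size=n).astype(float)
    cells = s_pheno.dirichlet(_CELL_MEANS * _CELL_CONCENTRATION, size=n)
    batch = s_pheno.integers(0, arch.n_batches, size=n)
    ancestry = s_pheno.normal(0.0, 1.0, size=(n, N_ANCESTRY))

    conf_std = {
        "bmi": _standardize(np.log(bmi)),
        "smoking_score": _standardize(smoking_score),
        "alcohol": _standardize(alcohol),
        "deprivation": _standardize(deprivation),
        "education": _standardize(education),
        "age": _standardize(age),
        "sex": _standardize(sex),
        "cells": _standardize(cells[:, 0]),  # CD4T fraction as the cell axis
        "batch": _standardize(
            s_pheno.normal(0.0, 1.0, size=arch.n_batches)[batch]
        ),
    }

    # ---- methylation -------------------------------------------------------
    m = cfg.n_probes
    n_blocks = int(arch.block_of_probe.max()) + 1 if m else 0
    u_block = s_probe.normal(size=(n, n_blocks))
    e_probe = s_probe.normal(size=(n, m))
    rho = cfg.within_block_corr
    core = np.sqrt(rho) * u_block[:, arch.block_of_probe] + np.sqrt(1.0 - rho) * e_probe

    latent = arch.probe_mu[None, :] + arch.probe_scale[None, :] * core
    for c, name in enumerate(arch.conf_channels):
        latent += np.outer(conf_std[name], arch.conf_loading[:, c])
    latent += np.outer(conf_std["cells"], arch.cell_loading)
    latent += arch.batch_offsets[:, batch].T
    beta = expit(latent)

    meth = MethylationDataset(
        sample_ids=sample_ids,
        probe_ids=arch.probe_ids.copy(),
        beta=beta,
        probe_chr=arch.probe_chr.copy(),
        probe_pos=arch.probe_pos.copy(),
        array_tag=array_tag,
    )

    # ---- genotypes (Hardy-Weinberg by construction) ------------------------
    dosage = s_geno.binomial(2, arch.snp_freq[None, :], size=(n, cfg.n_snps)).astype(float)
    geno = GenotypeDataset(
        sample_ids=sample_ids,
        snp_ids=arch.snp_ids.copy(),
        dosage=dosage,
        allele_counted=arch.allele_counted.copy(),
        allele_other=arch.allele_other.copy(),
    )

    # ---- phenotype: standardized log CRP from orthogonalized components ----
    c_meth_raw = core @ arch.causal_probe_weights
    p = arch.snp_freq
    z_snp = (dosage - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    c_snp_raw = z_snp @ arch.causal_snp_weights
    noise = s_pheno.normal(size=n)

    conf_names = list(cfg.confounder_effects)
    raw_cols = [c_meth_raw, c_snp_raw] + [conf_std[k] for k in conf_names] + [noise]
    ortho = _orthonormalize(raw_cols)
    c_meth, c_snp = ortho[0], ortho[1]
    conf_ortho = ortho[2:-1]
    resid = ortho[-1]

    fracs = (
        [cfg.var_dnam, cfg.var_snp]
        + [cfg.confounder_effects[k] ** 2 for k in conf_names]
        + [cfg.var_residual()]
    )
    signs = [1.0, 1.0] + [np.sign(cfg.confounder_effects[k]) or 1.0 for k in conf_names] + [1.0]
    comps = [c_meth, c_snp] + conf_ortho + [resid]
    y_std = np.zeros(n)
    for frac, sign, comp in zip(fracs, signs, comps):
        y_std += sign * np.sqrt(max(frac, 0.0)) * comp

    crp = np.exp(_CRP_LOG_MU + _CRP_LOG_SIGMA * y_std)

    assay = cfg.assay_per_wave[0]
    below = (crp < LOW_SENSITIVITY_LIMIT) & (assay == "low")

    # ---- outcomes ----------------------------------------------------------
    inflam = y_std
    cont = (
        np.outer(inflam, arch.outcome_slopes)
        + s_outcome.normal(size=(n, N_CONTINUOUS_OUTCOMES))
    )
    logits = -1.2 + np.outer(inflam, arch.outcome_logit_slopes)
    binary = (s_outcome.random((n, N_BINARY_OUTCOMES)) < expit(logits)).astype(int)
    base_hazard = 0.03  # events/year; ~60% censored at a 15-year horizon
    rate = base_hazard * np.exp(arch.hazard_log_hr * inflam)
    event_time = s_outcome.exponential(1.0 / rate)
    censor_time = 15.0
    death_event = (event_time <= censor_time).astype(int)
    survival_time = np.maximum(np.minimum(event_time, censor_time), 1e-6)

    pheno = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "wave": 1,
            "crp_mg_per_l": crp,
            "assay": assay,
            "below_detection": below,
            "age": age,
            "sex": sex.astype(int),
            "bmi": bmi,
            "smoking_score": smoking_score,
            "alcohol": alcohol,
            "deprivation": deprivation,
            "education": education,
            "batch": batch,
            "survival_time": survival_time,
            "death_event": death_event,
            "_latent": y_std,
        }
    )
    for j, cell in enumerate(CELL_TYPES):
        pheno[cell] = cells[:, j]
    for j in range(N_ANCESTRY):
        pheno[f"ancestry_{j + 1}"] = ancestry[:, j]
    for j in range(N_CONTINUOUS_OUTCOMES):
        pheno[f"outcome_{j + 1:02d}"] = cont[:, j]
    for j in range(N_BINARY_OUTCOMES):
        pheno[f"disease_{j + 1:02d}"] = binary[:, j]

    components = pd.DataFrame(
        {"meth": c_meth, "snp": c_snp, "residual": resid},
        index=sample_ids,
    )
    for k, col in zip(conf_names, conf_ortho):
        components[f"conf_{k}"] = col

    truth = SyntheticTruth(
        causal_probe_ids=arch.probe_ids[arch.causal_probe_mask].copy(),
        causal_probe_effects=arch.causal_probe_weights[arch.causal_probe_mask].copy(),
        causal_snp_ids=arch.snp_ids[arch.causal_snp_mask].copy(),
        causal_snp_effects=arch.causal_snp_weights[arch.causal_snp_mask].copy(),
        true_var_dnam=cfg.var_dnam,
        true_var_snp=cfg.var_snp,
        confounder_var={k: cfg.confounder_effects[k] ** 2 for k in conf_names},
        block_of_probe=arch.block_of_probe.copy(),
        components=components,
        latent_log_crp=y_std,
        architecture=arch,
    )
    return meth, geno, pheno, truth


def generate_cohort(config: SimConfig):
    """Generate a training cohort under ``config``.

    Returns ``(meth, geno, pheno, truth)``. The master seed fans out into
    named substreams (architecture, probes, genotypes, phenotype, outcomes),
    so the same seed yields bit-identical cohorts.
    """
    root = np.random.SeedSequence(config.seed)
    arch_seq, cohort_seq = root.spawn(2)
    arch = _build_architecture(config, np.random.default_rng(arch_seq))
    return _sample_cohort(arch, config.n_samples, cohort_seq, sample_prefix="S")


def derive_test_cohort(
    train,
    probes_missing: int = 0,
    age_shift: float = 0.0,
    seed: int = 1,
    n_samples: int | None = None,
):
    """Draw a new cohort from the training cohort's generative law.

    New samples follow the same architecture (probe blocks, causal sets,
    allele frequencies, effect sizes); exactly ``probes_missing`` randomly
    chosen probes are absent from the test methylation matrix, emulating a
    test cohort measured on a smaller array.
    """
    truth: SyntheticTruth = train[3]
    arch: _Architecture = truth.architecture
    if arch is None:
        raise ValueError("training truth does not carry its architecture")
    cfg = arch.config
    if probes_missing >= cfg.n_probes:
        raise ValueError(
            f"probes_missing={probes_missing} must be < n_probes={cfg.n_probes}"
        )
    n = cfg.n_samples if n_samples is None else n_samples
    seq = np.random.SeedSequence(entropy=seed, spawn_key=(1,))
    meth, geno, pheno, new_truth = _sample_cohort(
        arch, n, seq, sample_prefix="T", age_shift=age_shift, array_tag="test_450k"
    )
    if probes_missing > 0:
        drop_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2,)))
        drop = drop_rng.choice(cfg.n_probes, size=probes_missing, replace=False)
        keep = np.setdiff1d(np.arange(cfg.n_probes), drop)
        meth = meth.subset_probes(keep, array_tag="test_450k")
    return meth, geno, pheno, new_truth


def generate_longitudinal(
    base: pd.DataFrame,
    n_waves: int,
    tracking_corr: float,
    assay_per_wave,
    seed: int = 0,
    wave_years: float = 3.0,
) -> pd.DataFrame:
    """Expand a cross-sectional phenotype table into repeated waves.

    Each subject's latent (standardized log) inflammation follows an AR(1)
    path with wave-to-wave correlation ``tracking_corr``, starting from the
    baseline latent; each wave's CRP is re-expressed on the natural scale
    and passed through that wave's assay rule (low-sensitivity assays flag
    readings under 3 mg/L as below detection). Ages advance by
    ``wave_years`` per wave. Returns a long-format table.
    """
    if n_waves < 2:
        raise ValueError("n_waves must be >= 2 for a longitudinal design")
    if not 0.0 <= tracking_corr <= 1.0:
        raise ValueError("tracking_corr must lie in [0, 1]")
    assay_per_wave = list(assay_per_wave)
    if len(assay_per_wave) != n_waves:
        raise ValueError("assay_per_wave must have one entry per wave")

    rng = np.random.default_rng(seed)
    n = len(base)
    if "_latent" in base.columns:
        z = base["_latent"].to_numpy(dtype=float)
    else:
        z = _standardize(np.log(base["crp_mg_per_l"].to_numpy(dtype=float) + 0.01))

    rows = []
    z_w = z.copy()
    for w in range(1, n_waves + 1):
        if w > 1:
            innov = rng.normal(size=n)
            z_w = tracking_corr * z_w + np.sqrt(max(1.0 - tracking_corr**2, 0.0)) * innov
        crp = np.exp(_CRP_LOG_MU + _CRP_LOG_SIGMA * z_w)
        assay = assay_per_wave[w - 1]
        wave_tab = base.copy()
        wave_tab["wave"] = w
        wave_tab["crp_mg_per_l"] = crp
        wave_tab["assay"] = assay
        wave_tab["below_detection"] = (crp < LOW_SENSITIVITY_LIMIT) & (assay == "low")
        wave_tab["age"] = base["age"].to_numpy(dtype=float) + (w - 1) * wave_years
        wave_tab["_latent"] = z_w
        rows.append(wave_tab)
    return pd.concat(rows, ignore_index=True)


def generate_wave_methylation(
    meth: MethylationDataset,
    n_waves: int,
    stability: float = 0.98,
    seed: int = 0,
) -> list[MethylationDataset]:
    """Per-wave methylation matrices drifting slowly from a baseline.

    Models DNAm's temporal stability: each wave's latent (logit-scale)
    methylation correlates ``stability`` with the previous wave's. Used to
    contrast the persistence of methylation-derived scores with the phasic
    behavior of assay CRP.
    """
    if not 0.0 <= stability <= 1.0:
        raise ValueError("stability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    eps = 1e-6
    latent = np.log(np.clip(meth.beta, eps, 1 - eps) / (1 - np.clip(meth.beta, eps, 1 - eps)))
    sd = latent.std(axis=0, keepdims=True)
    out = []
    cur = latent
    for w in range(n_waves):
        if w > 0:
            innov = rng.normal(size=latent.shape) * sd
            cur = stability * cur + np.sqrt(max(1.0 - stability**2, 0.0)) * innov + (
                1.0 - stability
            ) * latent.mean(axis=0, keepdims=True)
        out.append(
            MethylationDataset(
                sample_ids=meth.sample_ids.copy(),
                probe_ids=meth.probe_ids.copy(),
                beta=expit(cur),
                probe_chr=meth.probe_chr.copy(),
                probe_pos=meth.probe_pos.copy(),
                array_tag=meth.array_tag,
            )
        )
    return out
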