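"""Relationship matrices and REML variance components.

The frequentist cross-check of the Bayesian variance partitioning: build an
omics (ORM) or genomic (GRM) relationship matrix A = Z Z'/m from
standardized features, then fit ``y = Xb + g + e`` with
``g ~ N(0, A sigma_g^2)`` by restricted maximum likelihood and report the
fraction ``sigma_g^2 / (sigma_g^2 + sigma_e^2)``. One or two relationship
matrices (methylation + genetics) can be fitted jointly.

Estimation uses average-information (AI) REML with EM fallback steps and
variance floors, which is robust at the sample sizes used here; the REML
log-likelihood is monitored and returned so non-monotone trajectories are
visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datatypes import GenotypeDataset, VarianceEstimate

__all__ = [
    "RelationshipMatrix",
    "build_relationship_matrix",
    "grm_from_genotypes",
    "prune_related",
    "reml_fit",
]

_VAR_FLOOR = 1e-6


@dataclass
class RelationshipMatrix:
    """Symmetric n x n sample-similarity matrix from m standardized features."""

    kind: str  # "ORM" or "GRM"
    values: np.ndarray
    n_features: int
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        A = self.values
        if A.shape[0] != A.shape[1]:
            raise ValueError("relationship matrix must be square")
        if np.max(np.abs(A - A.T)) > 1e-10:
            raise ValueError("relationship matrix must be symmetric")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def build_relationship_matrix(features, kind: str = "ORM", sample_ids=None) -> RelationshipMatrix:
    """A = Z Z' / m with Z the column-standardized feature matrix.

    Zero-variance features are dropped with a warning. For genotype
    matrices prefer :func:`grm_from_genotypes`, which standardizes by the
    binomial variance 2 MAF (1 - MAF).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("need a 2-D feature matrix with >= 1 feature")
    sd = X.std(axis=0)
    keep = sd > 1e-12
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance features", stacklevel=2
        )
        X = X[:, keep]
        sd = sd[keep]
    if X.shape[1] == 0:
        raise ValueError("no non-constant features left")
    Z = (X - X.mean(axis=0)) / sd
    m = Z.shape[1]
    A = (Z @ Z.T) / m
    if sample_ids is None:
        sample_ids = np.arange(X.shape[0])
    return RelationshipMatrix(kind=kind, values=A, n_features=m, sample_ids=np.asarray(sample_ids))


def grm_from_genotypes(geno: GenotypeDataset) -> RelationshipMatrix:
    """GRM with allele-frequency standardization (dos - 2p)/sqrt(2p(1-p))."""
    D = geno.dosage
    p = np.nanmean(D, axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} monomorphic SNPs", stacklevel=2)
    D = D[:, keep]
    p = p[keep]
    Z = (D - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    A = (Z @ Z.T) / Z.shape[1]
    return RelationshipMatrix(
        kind="GRM", values=A, n_features=Z.shape[1], sample_ids=geno.sample_ids.copy()
    )


def prune_related(grm: RelationshipMatrix, cutoff: float = 0.05) -> np.ndarray:
    """Indices of samples to keep after greedily removing relatedness.

    While any off-diagonal entry exceeds ``cutoff``, the sample involved in
    the most such pairs is removed (max-degree-first greedy cover).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    A = np.abs(grm.values.copy())
    np.fill_diagonal(A, 0.0)
    n = A.shape[0]
    alive = np.ones(n, dtype=bool)
    over = A > cutoff
    while True:
        degree = (over & alive[None, :] & alive[:, None]).sum(axis=1)
        if degree.max() == 0:
            break
        worst = int(np.argmax(degree))
        alive[worst] = False
    return np.flatnonzero(alive)


@dataclass
class RemlResult:
    estimates: list[VarianceEstimate]
    variance_components: np.ndarray  # (sigma_1^2, ..., sigma_e^2)
    se_components: np.ndarray
    loglik_path: list[float] = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0


def _reml_loglik(Vinv_logdet, XtViX_logdet, yPy) -> float:
    return -0.5 * (Vinv_logdet + XtViX_logdet + yPy)


def reml_fit(
    y,
    matrices,
    covariates=None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> RemlResult:
    """AI-REML for 1-2 relationship matrices plus an identity residual.

    Parameters
    ----------
    y : phenotype vector (residualized/standardized upstream, matching the
        Bayesian pipeline; an intercept is always included here).
    matrices : a RelationshipMatrix or list of 1-2 of them.
    covariates : optional fixed-effect design (intercept added).

    Returns
    -------
    RemlResult with per-component variance fractions and Wald 95% CIs
    (estimate +/- 1.96 SE, truncated to [0, 1]).
    """
    if isinstance(matrices, RelationshipMatrix):
        matrices = [matrices]
    if not 1 <= len(matrices) <= 2:
        raise ValueError("reml_fit supports 1 or 2 relationship matrices")
    y = np.asarray(y, dtype=float)
    n = y.size
    A_list = []
    for rm in matrices:
        A = rm.values
        if A.shape[0] != n:
            raise ValueError("relationship matrix size does not match phenotype")
        eigmin = np.linalg.eigvalsh(A)[0]
        if eigmin < -1e-6:
            raise ValueError(f"{rm.kind} matrix is not positive semi-definite "
                             f"(min eigenvalue {eigmin:.2e})")
        A_list.append(A)

    if covariates is None:
        X = np.ones((n, 1))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([np.ones(n), C])

    K = len(A_list)
    var_y = y.var(ddof=1)
    theta = np.full(K + 1, var_y / (K + 1))
    kernels = A_list + [np.eye(n)]

    def compute(theta):
        V = sum(t * Ak for t, Ak in zip(theta, kernels))
        L = np.linalg.cholesky(V)
        logdetV = 2.0 * np.sum(np.log(np.diag(L)))
        Vinv = np.linalg.inv(V)
        XtViX = X.T @ Vinv @ X
        XtViX_inv = np.linalg.inv(XtViX)
        logdetXtViX = np.linalg.slogdet(XtViX)[1]
        P = Vinv - Vinv @ X @ XtViX_inv @ X.T @ Vinv
        Py = P @ y
        ll = -0.5 * (logdetV + logdetXtViX + float(y @ Py))
        return P, Py, ll

    P, Py, ll = compute(theta)
    loglik_path = [ll]
    converged = False
    it = 0
    ai_inv = None
    for it in range(1, max_iter + 1):
        PA = [P @ Ak for Ak in kernels]
        APy = [Ak @ Py for Ak in kernels]
        score = np.array(
            [-0.5 * (np.trace(PA[k]) - Py @ APy[k]) for k in range(K + 1)]
        )
        AI = np.empty((K + 1, K + 1))
        PAPy = [P @ v for v in APy]
        for a in range(K + 1):
            for b in range(a, K + 1):
                AI[a, b] = AI[b, a] = 0.5 * float(APy[a] @ PAPy[b])
        try:
            ai_inv = np.linalg.inv(AI)
            delta = ai_inv @ score
        except np.linalg.LinAlgError:
            delta = None

        stepped = False
        if delta is not None:
            cand = np.maximum(theta + delta, _VAR_FLOOR)
            try:
                P2, Py2, ll2 = compute(cand)
                if ll2 >= ll - 1e-10:
                    theta, P, Py, ll = cand, P2, Py2, ll2
                    stepped = True
            except np.linalg.LinAlgError:
                pass
        if not stepped:
            # EM fallback: guaranteed-ascent fixed-point update
            cand = np.array(
                [
                    max(
                        theta[k]
                        + theta[k] ** 2 * (float(Py @ APy[k]) - np.trace(PA[k])) / n,
                        _VAR_FLOOR,
                    )
                    for k in range(K + 1)
                ]
            )
            P, Py, ll = compute(cand)
            theta = cand
        loglik_path.append(ll)
        if abs(loglik_path[-1] - loglik_path[-2]) < tol:
            converged = True
            break

    if not converged:
        warnings.warn(f"REML did not converge in {max_iter} iterations", stacklevel=2)
    if ai_inv is None:  # pragma: no cover - degenerate fits only
        ai_inv = np.full((K + 1, K + 1), np.nan)

    total = theta.sum()
    se_theta = np.sqrt(np.maximum(np.diag(ai_inv), 0.0))
    names = [rm.kind.lower() for rm in matrices]
    comp_names = {"orm": "methylation", "grm": "genetic"}
    estimates = []
    for k in range(K):
        frac = theta[k] / total
        # delta method for the ratio sigma_k^2 / total
        grad = np.full(K + 1, -theta[k] / total**2)
        grad[k] += 1.0 / total
        var_frac = float(grad @ ai_inv @ grad)
        se_frac = np.sqrt(max(var_frac, 0.0))
        estimates.append(
            VarianceEstimate(
                component=comp_names.get(names[k], names[k]),
                estimate=float(frac),
                lower=float(max(0.0, frac - 1.96 * se_frac)),
                upper=float(min(1.0, frac + 1.96 * se_frac)),
                method="reml",
                conditioning=tuple(
                    comp_names.get(names[j], names[j]) for j in range(K) if j != k
                ),
            )
        )
    return RemlResult(
        estimates=estimates,
        variance_components=theta,
        se_components=se_theta,
        loglik_path=loglik_path,
        converged=converged,
        n_iter=it,
    )
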