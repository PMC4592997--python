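"""Multi-trait variance-component estimation for balanced replicated trials.

The model per trait pair is the two-way random model
``y_ijq = mu_q + g_iq + e_ijq`` with genotype effects ``g_i ~ N(0, C)`` and
plot residuals ``e_ij ~ N(0, R)``.  For balanced data the MANOVA
expected-mean-squares estimator, C = (MS_G - MS_E)/nreps and R = MS_E on
mean-cross-product matrices, is the REML solution whenever it lies inside
the parameter space.  When the C estimate is indefinite an EM-REML
refinement is run, followed by eigenvalue bending, so the downstream index
algebra (b = P^-1 C w) always receives positive semi-definite matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .phenotypes import PhenotypeTable

__all__ = ["CovarianceSet", "estimate_cr", "heritability"]

log = logging.getLogger(__name__)


@dataclass
class CovarianceSet:
    """Estimated genetic (C), residual (R) and phenotypic covariances.

    The phenotypic matrix depends on the observational basis: a single plot
    has variance C + R ("plot" basis), while the mean of nreps replicates
    has variance C + R/nreps ("entry" basis).  Both are exposed; the
    experiment driver logs which one a given response estimate used.
    """

    C_hat: np.ndarray
    R_hat: np.ndarray
    n_genotypes: int
    n_reps: int
    cycle_id: int | None = None

    def phenotypic(self, basis: str = "plot") -> np.ndarray:
        if basis == "plot":
            return self.C_hat + self.R_hat
        if basis in ("entry", "entry-mean"):
            return self.C_hat + self.R_hat / self.n_reps
        raise ValueError("basis must be 'plot' or 'entry'")

    @property
    def P_hat(self) -> np.ndarray:
        """Plot-basis phenotypic covariance C + R."""
        return self.phenotypic("plot")


def _is_psd(M: np.ndarray, tol: float = 0.0) -> bool:
    return bool(np.linalg.eigvalsh(M).min() >= -abs(tol))


def bend_psd(M: np.ndarray, rel_floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue bending: raise eigenvalues below ``rel_floor * lambda_max``
    to that floor.  Returns a symmetric PSD matrix."""
    M = 0.5 * (M + M.T)
    vals, vecs = np.linalg.eigh(M)
    lmax = max(vals.max(), 0.0)
    if lmax == 0.0:
        return np.zeros_like(M)
    floor = rel_floor * lmax
    if vals.min() >= floor:
        return M
    vals = np.clip(vals, floor, None)
    return (vecs * vals) @ vecs.T


def _em_reml(
    ybar: np.ndarray,
    ssw: np.ndarray,
    n_reps: int,
    C0: np.ndarray,
    R0: np.ndarray,
    max_iter: int = 500,
    rtol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """EM-REML for the balanced one-way multivariate random model.

    Sufficient statistics are the entry means ``ybar`` (g, t) and the
    within-genotype cross-product ``ssw`` (t, t).  Convergence is declared
    on relative change of the restricted log-likelihood.
    """
    g, t = ybar.shape
    n = n_reps
    yc = ybar - ybar.mean(axis=0)
    Sb = yc.T @ yc  # (t, t), g-1 dof after mean removal
    C = bend_psd(C0, 1e-8) + 1e-8 * np.eye(t) * max(np.trace(R0) / t, 1.0)
    R = bend_psd(R0, 1e-8) + 1e-8 * np.eye(t) * max(np.trace(R0) / t, 1.0)
    prev_ll = -np.inf
    for _ in range(max_iter):
        V = C + R / n  # covariance of an entry mean
        Vi = np.linalg.inv(V)
        # restricted log-likelihood (constant dropped); g-1 effective means
        sign, logdet = np.linalg.slogdet(V)
        within_dof = g * (n - 1)
        Ri = np.linalg.inv(R)
        ll = (
            -0.5 * (g - 1) * logdet
            - 0.5 * np.trace(Vi @ Sb)
            - 0.5 * within_dof * np.linalg.slogdet(R)[1]
            - 0.5 * np.trace(Ri @ ssw)
        )
        # E-step / M-step in closed form
        B = C @ Vi  # BLUP weight for genotype effects on entry means
        # E[sum_i g_i g_i'] given data (REML: include uncertainty of the mean)
        Eg = B @ Sb @ B.T + (g - 1) * (C - B @ C)
        C_new = Eg / (g - 1)
        # residual of entry means after removing BLUPed genotype effects
        A = np.eye(t) - B  # = (R/n) Vi
        Ee_between = A @ Sb @ A.T + (g - 1) * (C - B @ C)  # E[sum (ybar_i - mu - g_i)(.)']
        R_new = (ssw + n * Ee_between) / (g * n - 1)
        C, R = C_new, R_new
        if prev_ll != -np.inf and abs(ll - prev_ll) <= rtol * (abs(prev_ll) + 1.0):
            break
        prev_ll = ll
    return C, R


def estimate_cr(phenos: PhenotypeTable, cycle_id: int | None = None) -> CovarianceSet:
    """Estimate C and R from a balanced replicated phenotype table.

    EMS estimator first; EM-REML refinement plus eigenvalue bending only
    when the EMS genetic covariance is indefinite.
    """
    y = phenos.values
    g, n, t = y.shape
    if g < 2 or n < 2:
        raise ValueError("need at least 2 genotypes and 2 replicates")
    ybar = y.mean(axis=1)
    grand = ybar.mean(axis=0)
    yc = ybar - grand
    ms_g = n * (yc.T @ yc) / (g - 1)
    resid = y - ybar[:, None, :]
    flat = resid.reshape(g * n, t)
    ssw = flat.T @ flat
    ms_e = ssw / (g * (n - 1))
    C = (ms_g - ms_e) / n
    R = ms_e
    if not _is_psd(C, tol=1e-10 * max(np.trace(ms_g), 1.0)):
        log.info("EMS genetic covariance indefinite; running EM-REML refinement")
        C, R = _em_reml(ybar, ssw, n, C, R)
        C = bend_psd(C)
        R = bend_psd(R)
    C = 0.5 * (C + C.T)
    R = 0.5 * (R + R.T)
    return CovarianceSet(C_hat=C, R_hat=R, n_genotypes=g, n_reps=n, cycle_id=cycle_id)


def heritability(cov: CovarianceSet, basis: str = "plot") -> np.ndarray:
    """Per-trait heritability on the plot or entry-mean basis."""
    c = np.diag(cov.C_hat)
    r = np.diag(cov.R_hat)
    if basis == "plot":
        denom = c + r
    elif basis in ("entry", "entry-mean"):
        denom = c + r / cov.n_reps
    else:
        raise ValueError("basis must be 'plot' or 'entry'")
    if np.any(denom <= 0):
        raise ZeroDivisionError("zero phenotypic variance for some trait")
    return c / denom
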