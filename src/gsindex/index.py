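"""Selection-index mathematics and model objects.

Both indices predict the net genetic merit H = w'a of a candidate, where a
is its vector of true breeding values and w the economic weights.  The
phenotypic index (PSI) is b'p with b = P^-1 C w (Smith-Hazel); the genomic
index (GSI) is w'gamma on genomic breeding values, whose coefficient vector
is w itself.  Selection responses take the classic form

    R = (k / L) * sqrt(v' M v)

with k the standardized selection differential, L the cycle length in
years, and (M, v) = (P, b) for the PSI or (Gamma, w) for the GSI; the
per-trait expected genetic gains are (k/L) M_num v / sqrt(v' M v).  The
efficiency of genomic over phenotypic selection is the response ratio
lambda = R_GSI / R_PSI, and the Technow inequality provides a second,
time-based criterion: genomic selection wins per unit time when
L_GSI < (rho_H,GSI / h_PSI) L_PSI.

The functional layer is wrapped by two model classes,
:class:`PhenotypicSelectionIndex` and :class:`GenomicSelectionIndex`, whose
``fit()`` returns a results object carrying coefficients, responses, gains,
accuracies and a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .markers import GEBVTable, GRM, GammaMatrix, estimate_gamma
from .phenotypes import PhenotypeTable
from .varcomp import CovarianceSet, estimate_cr

__all__ = [
    "IndexSpec",
    "CycleSummary",
    "selection_intensity",
    "psi_coefficients",
    "index_response",
    "expected_gains",
    "accuracy",
    "efficiency_ratio",
    "technow_inequality",
    "gsi_values",
    "truncate_select",
    "PhenotypicSelectionIndex",
    "GenomicSelectionIndex",
    "SelectionIndexResults",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class IndexSpec:
    """Economic weights, selection intensity and cycle length of an index."""

    w: np.ndarray
    k: float
    L: float = 1.0
    kind: str = "GSI"

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if self.k < 0 or self.L <= 0:
            raise ValueError("need k >= 0 and L > 0")
        if not np.any(w != 0):
            raise ValueError("economic weights must not all be zero")


@dataclass
class CycleSummary:
    """Per-cycle record of a recurrent-selection run.

    Responses are reported per cycle (L = 1) and per year (L = cycle
    length); ``rho_H`` is the estimated index accuracy with the true net
    merit, ``gebv_tbv_corr`` the per-trait GEBV accuracy (simulation only),
    and ``lambda_ratio`` the per-year GSI/PSI response ratio filled in when
    two runs are compared.
    """

    cycle_id: int
    kind: str
    r_est: float
    r_true: float | None = None
    r_est_year: float | None = None
    r_true_year: float | None = None
    gains_est: np.ndarray | None = None
    gains_est_year: np.ndarray | None = None
    rho_H: float | None = None
    sigma_H: float | None = None
    lambda_ratio: float | None = None
    gebv_tbv_corr: np.ndarray | None = None
    selected_ids: np.ndarray | None = None


def selection_intensity(p: float) -> float:
    """Standardized selection differential k = phi(z)/p for truncation of
    the upper proportion p of a normal population."""
    if not 0.0 < p < 1.0:
        raise ValueError("selected proportion must lie in (0, 1)")
    z = stats.norm.ppf(1.0 - p)
    return float(stats.norm.pdf(z) / p)


def psi_coefficients(P: np.ndarray, C: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Smith-Hazel coefficients b solving P b = C w (no explicit inverse).

    Among all linear functions of the phenotypes, b'p has maximal
    correlation with the net merit w'a.
    """
    P = np.asarray(P, dtype=float)
    C = np.asarray(C, dtype=float)
    w = np.asarray(w, dtype=float)
    try:
        return np.linalg.solve(P, C @ w)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("phenotypic covariance matrix is singular") from err


def index_response(spec: IndexSpec, M: np.ndarray, v: np.ndarray) -> float:
    """Selection response R = (k/L) sqrt(v' M v)."""
    v = np.asarray(v, dtype=float)
    q = float(v @ np.asarray(M, dtype=float) @ v)
    if q < 0:
        if q < -1e-8 * max(1.0, float(np.trace(M))):
            raise ValueError(f"negative quadratic form v'Mv = {q:.3e}")
        q = 0.0
    return spec.k / spec.L * np.sqrt(q)


def expected_gains(spec: IndexSpec, M_num: np.ndarray, M_quad: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Per-trait expected genetic gains E = (k/L) M_num v / sqrt(v' M_quad v).

    (M_num, M_quad, v) = (C, P, b) for the PSI and (Gamma, Gamma, w) for the
    GSI; contracting the GSI gains with w recovers the GSI response.
    """
    v = np.asarray(v, dtype=float)
    q = float(v @ np.asarray(M_quad, dtype=float) @ v)
    if q <= 0:
        raise ValueError("zero or negative quadratic form in expected gains")
    return spec.k / spec.L * (np.asarray(M_num, dtype=float) @ v) / np.sqrt(q)


def accuracy(M_hat: np.ndarray, C: np.ndarray, w: np.ndarray, kind: str = "GSI",
             b: np.ndarray | None = None, clip: bool = True) -> float:
    """Estimated index accuracy with the net merit H = w'a.

    GSI: rho = sqrt(w' Gamma_hat w / w' C w); PSI: rho = sqrt(b' P_hat b /
    w' C w).  Finite-sample estimates can exceed 1; they are clipped to
    [0, 1] with a logged warning unless ``clip`` is False.
    """
    w = np.asarray(w, dtype=float)
    denom = float(w @ np.asarray(C, dtype=float) @ w)
    if denom <= 0:
        raise ValueError("net merit has zero variance (w'Cw <= 0)")
    v = w if kind.upper() == "GSI" else np.asarray(b, dtype=float)
    if v is None:
        raise ValueError("PSI accuracy needs the index coefficients b")
    num = float(v @ np.asarray(M_hat, dtype=float) @ v)
    rho = np.sqrt(max(num, 0.0) / denom)
    if clip and rho > 1.0:
        log.warning("estimated accuracy %.3f > 1; clipping (finite-sample artifact)", rho)
        rho = 1.0
    return float(rho)


def efficiency_ratio(r_gsi: float, r_psi: float) -> float:
    """lambda = R_GSI / R_PSI; lambda > 1 means genomic selection is the
    more efficient index."""
    if r_psi <= 0:
        raise ZeroDivisionError("PSI response must be positive")
    return float(r_gsi / r_psi)


def technow_inequality(L_gsi: float, L_psi: float, rho_gsi: float, h_psi: float) -> dict:
    """Time-based genomic-vs-phenotypic criterion.

    Genomic selection is more efficient per unit time when
    L_GSI < (rho_H,GSI / h_PSI) L_PSI, where h_PSI is the square root of
    the heritability of the phenotypic selection criterion.  Returns the
    decision, the threshold cycle length L* and the echoed inputs.
    """
    if min(L_gsi, L_psi, rho_gsi, h_psi) <= 0 or max(rho_gsi, h_psi) > 1:
        raise ValueError("need L > 0 and rho, h in (0, 1]")
    threshold = rho_gsi / h_psi * L_psi
    return {
        "holds": bool(L_gsi < threshold),
        "threshold": float(threshold),
        "L_gsi": float(L_gsi),
        "L_psi": float(L_psi),
        "rho_gsi": float(rho_gsi),
        "h_psi": float(h_psi),
    }


def gsi_values(gebvs: GEBVTable | np.ndarray, w: np.ndarray) -> np.ndarray:
    """Estimated genomic index per genotype: GSI_E = sum_q w_q gamma_hat_q."""
    gamma = gebvs.gamma_hat if isinstance(gebvs, GEBVTable) else np.asarray(gebvs, dtype=float)
    return gamma @ np.asarray(w, dtype=float)


def truncate_select(values: np.ndarray, p: float) -> np.ndarray:
    """Indices of the ceil(g*p) highest values; ties broken by stable
    original order."""
    values = np.asarray(values, dtype=float)
    g = values.size
    if g == 0:
        raise ValueError("empty input")
    if not 0.0 < p < 1.0:
        raise ValueError("selected proportion must lie in (0, 1)")
    n_sel = int(np.ceil(g * p))
    if n_sel < 1:
        raise ValueError("selected fraction rounds to zero individuals")
    # stable sort on negated values keeps original order among ties
    order = np.argsort(-values, kind="stable")
    return np.sort(order[:n_sel])


# ---------------------------------------------------------------------------
# Model / Results layer


@dataclass
class SelectionIndexResults:
    """Fitted selection-index results.

    Carries the coefficient vector, per-genotype index values, the selected
    ids, per-cycle and per-year responses and expected gains, and (when a
    true genetic covariance was supplied) the estimated accuracy with H.
    """

    kind: str
    spec: IndexSpec
    coefficients: np.ndarray
    index_values: np.ndarray
    selected_ids: np.ndarray
    response: float
    response_per_year: float
    gains: np.ndarray
    gains_per_year: np.ndarray
    rho_H: float | None = None
    sigma_H: float | None = None
    covariances: CovarianceSet | None = None
    gamma: GammaMatrix | None = None
    trait_names: tuple[str, ...] = field(default_factory=tuple)

    def summary(self) -> str:
        names = self.trait_names or tuple(f"T{q+1}" for q in range(self.gains.size))
        lines = [
            f"{self.kind} selection index (k = {self.spec.k:.3f}, L = {self.spec.L:g} y)",
            "-" * 58,
            "trait      weight    coefficient   gain/cycle   gain/year",
        ]
        for q, name in enumerate(names):
            lines.append(
                f"{name:<10}{self.spec.w[q]:>8.3f}{self.coefficients[q]:>13.4f}"
                f"{self.gains[q]:>13.3f}{self.gains_per_year[q]:>12.3f}"
            )
        lines.append("-" * 58)
        lines.append(
            f"response/cycle {self.response:>9.3f}    response/year {self.response_per_year:>9.3f}"
        )
        if self.rho_H is not None:
            lines.append(f"accuracy with H (rho)  {self.rho_H:>6.3f}")
        lines.append(f"selected {self.selected_ids.size} genotypes")
        return "\n".join(lines)


class PhenotypicSelectionIndex:
    """Smith-Hazel phenotypic index fitted to replicated phenotypes.

    Parameters
    ----------
    phenos : PhenotypeTable
        balanced replicated trial used to estimate C, R and P.
    weights : array-like
        economic weights w defining the net merit H = w'a.
    proportion : float
        selected proportion; sets k via the normal truncation intensity.
    interval : float
        cycle length L_PSI in years.
    basis : str
        observational basis of the response estimator: "plot" uses
        P = C + R, "entry" uses P = C + R/nreps.
    """

    def __init__(self, phenos: PhenotypeTable, weights, proportion: float = 0.10,
                 interval: float = 4.0, basis: str = "plot"):
        self.phenos = phenos
        self.weights = np.asarray(weights, dtype=float)
        self.proportion = proportion
        self.interval = interval
        self.basis = basis

    def fit(self, true_genetic_cov: np.ndarray | None = None) -> SelectionIndexResults:
        k = selection_intensity(self.proportion)
        spec = IndexSpec(w=self.weights, k=k, L=self.interval, kind="PSI")
        cov = estimate_cr(self.phenos)
        P = cov.phenotypic(self.basis)
        log.info("PSI response estimated on the %s basis", self.basis)
        b = psi_coefficients(P, cov.C_hat, spec.w)
        values = self.phenos.entry_means @ b
        sel = truncate_select(values, self.proportion)
        per_cycle = IndexSpec(w=spec.w, k=k, L=1.0, kind="PSI")
        rho = sigma = None
        if true_genetic_cov is not None:
            rho = accuracy(P, true_genetic_cov, spec.w, kind="PSI", b=b)
            sigma = float(np.sqrt(spec.w @ true_genetic_cov @ spec.w))
        return SelectionIndexResults(
            kind="PSI",
            spec=spec,
            coefficients=b,
            index_values=values,
            selected_ids=sel,
            response=index_response(per_cycle, P, b),
            response_per_year=index_response(spec, P, b),
            gains=expected_gains(per_cycle, cov.C_hat, P, b),
            gains_per_year=expected_gains(spec, cov.C_hat, P, b),
            rho_H=rho,
            sigma_H=sigma,
            covariances=cov,
            trait_names=self.phenos.trait_names,
        )


class GenomicSelectionIndex:
    """Genomic index on GEBVs of a (possibly non-phenotyped) population.

    Needs the cycle's GEBV table and genomic relationship matrix; the
    coefficient vector is the economic weights themselves, and the response
    rests on the relationship-weighted Gamma estimator.
    """

    def __init__(self, gebvs: GEBVTable, grm: GRM, weights, proportion: float = 0.10,
                 interval: float = 1.5):
        self.gebvs = gebvs
        self.grm = grm
        self.weights = np.asarray(weights, dtype=float)
        self.proportion = proportion
        self.interval = interval

    def fit(self, true_genetic_cov: np.ndarray | None = None) -> SelectionIndexResults:
        k = selection_intensity(self.proportion)
        spec = IndexSpec(w=self.weights, k=k, L=self.interval, kind="GSI")
        gamma = estimate_gamma(self.gebvs, self.grm)
        values = gsi_values(self.gebvs, spec.w)
        sel = truncate_select(values, self.proportion)
        per_cycle = IndexSpec(w=spec.w, k=k, L=1.0, kind="GSI")
        rho = sigma = None
        if true_genetic_cov is not None:
            rho = accuracy(gamma.Gamma_hat, true_genetic_cov, spec.w, kind="GSI")
            sigma = float(np.sqrt(spec.w @ true_genetic_cov @ spec.w))
        return SelectionIndexResults(
            kind="GSI",
            spec=spec,
            coefficients=spec.w,
            index_values=values,
            selected_ids=sel,
            response=index_response(per_cycle, gamma.Gamma_hat, spec.w),
            response_per_year=index_response(spec, gamma.Gamma_hat, spec.w),
            gains=expected_gains(per_cycle, gamma.Gamma_hat, gamma.Gamma_hat, spec.w),
            gains_per_year=expected_gains(spec, gamma.Gamma_hat, gamma.Gamma_hat, spec.w),
            rho_H=rho,
            sigma_H=sigma,
            gamma=gamma,
        )
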