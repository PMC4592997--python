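"""Marker-effect estimation, genomic prediction and the Gamma estimator.

Marker effects are estimated once, in the training (base) cycle, by
single-trait ridge-regression BLUP on entry means:

    u_q = (Xc' Xc + lambda_q I)^-1 Xc' (ybar_q - mu_q 1),
    lambda_q = (sigma_e,q^2 / nreps) / (sigma_g,q^2 / c),

where Xc is the column-centered {-1,0,1} marker matrix of the training
population and c is the relationship-matrix scaling constant (per-marker
c = m by default, VanRaden's sum 2pq optionally), so that sigma_g^2 / c is
the per-marker effect variance.  GEBVs in any
later cycle are gamma_q = Xc,l u_q with Xl centered on the *training*
column means (the base-population coordinate frame).  The covariance matrix
of genomic breeding values across traits, Gamma = {sigma_gamma_qq'}, is
estimated with the genomic-relationship-weighted cross product

    sigma_gamma_qq' = (1/g) (gamma_q - mean)' G^-1 (gamma_q' - mean),

with G = Xc Xc'/c the additive genomic relationship matrix of the same
cycle.  Centered G is singular by construction (rows sum to zero), so a
small logged ridge is added before inversion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import Genome, Population
from .phenotypes import PhenotypeTable
from .varcomp import CovarianceSet

__all__ = [
    "MarkerMatrix",
    "MarkerEffects",
    "GEBVTable",
    "GRM",
    "GammaMatrix",
    "markers_from_population",
    "load_markers",
    "fit_rrblup",
    "predict_gebv",
    "compute_grm",
    "estimate_gamma",
]

log = logging.getLogger(__name__)


@dataclass
class MarkerMatrix:
    """Coded marker genotypes, one row per genotype, codes in {-1, 0, 1}."""

    X: np.ndarray
    genotype_ids: np.ndarray
    marker_ids: np.ndarray
    cycle_id: int | None = None

    def __post_init__(self) -> None:
        bad = ~np.isin(self.X, (-1, 0, 1))
        if bad.any():
            raise ValueError("marker codes must be in {-1, 0, 1}")

    @property
    def n_genotypes(self) -> int:
        return self.X.shape[0]

    @property
    def n_markers(self) -> int:
        return self.X.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Frequency of the +1-coded allele per marker."""
        return (self.X.mean(axis=0) + 1.0) / 2.0


@dataclass
class MarkerEffects:
    """Training-cycle RR-BLUP output: effects, intercepts and the centering
    frame needed to predict later cycles."""

    u_hat: np.ndarray          # (m, t)
    mu_hat: np.ndarray         # (t,)
    lambdas: np.ndarray        # (t,) ridge parameters used
    col_means: np.ndarray      # (m,) training-column means for centering
    marker_ids: np.ndarray
    trait_names: tuple[str, ...] | None = None


@dataclass
class GEBVTable:
    """Genomic estimated breeding values, gamma_hat = Xc u_hat."""

    gamma_hat: np.ndarray      # (g, t)
    genotype_ids: np.ndarray
    cycle_id: int | None = None

    @property
    def column_means(self) -> np.ndarray:
        return self.gamma_hat.mean(axis=0)


@dataclass
class GRM:
    """Additive genomic relationship matrix G = Xc Xc'/c."""

    G: np.ndarray
    c: float
    cycle_id: int | None = None


@dataclass
class GammaMatrix:
    """Estimated covariance matrix of genomic breeding values across traits."""

    Gamma_hat: np.ndarray      # (t, t)
    cycle_id: int | None = None


def markers_from_population(pop: Population, genome: Genome) -> MarkerMatrix:
    """Code a simulated population's marker dosages as {-1, 0, 1}."""
    X = pop.marker_dosage(genome).astype(np.int8) - 1
    return MarkerMatrix(
        X=X,
        genotype_ids=np.arange(pop.size),
        marker_ids=np.arange(X.shape[1]),
        cycle_id=pop.cycle_id,
    )


def load_markers(path, coding: str = "auto", sep: str = "\t", cycle_id=None) -> MarkerMatrix:
    """Read a delimited genotypes x markers table (genotype id first column).

    ``coding`` is "zero_one_two" ({0,1,2}, recoded to {-1,0,1}),
    "minus_one_one" (already {-1,0,1}) or "auto" (inferred: a table whose
    smallest code is 0 and largest is 2 is treated as {0,1,2}).
    """
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2 or df.shape[0] == 0:
        raise ValueError(f"{path}: expected a genotype-id column plus marker columns")
    ids = df.iloc[:, 0].to_numpy()
    if pd.unique(ids).size != ids.size:
        raise ValueError(f"{path}: duplicated genotype ids")
    vals = df.iloc[:, 1:]
    if vals.isna().any().any():
        raise ValueError(f"{path}: ragged rows or missing marker codes")
    X = vals.to_numpy()
    codes = np.unique(X)
    if coding == "auto":
        if np.all(np.isin(codes, (0, 1, 2))) and codes.max() == 2:
            coding = "zero_one_two"
        elif np.all(np.isin(codes, (-1, 0, 1))):
            coding = "minus_one_one"
        else:
            raise ValueError(f"{path}: non-biallelic marker codes {codes!r}")
    if coding == "zero_one_two":
        if not np.all(np.isin(codes, (0, 1, 2))):
            raise ValueError(f"{path}: codes outside {{0,1,2}}: {codes!r}")
        X = X - 1
    elif coding == "minus_one_one":
        if not np.all(np.isin(codes, (-1, 0, 1))):
            raise ValueError(f"{path}: codes outside {{-1,0,1}}: {codes!r}")
    else:
        raise ValueError(f"unknown coding dialect {coding!r}")
    mm = MarkerMatrix(
        X=X.astype(np.int8),
        genotype_ids=ids,
        marker_ids=df.columns[1:].to_numpy(),
        cycle_id=cycle_id,
    )
    log.info("loaded %d genotypes x %d markers from %s", mm.n_genotypes, mm.n_markers, path)
    return mm


def grm_scale(X: np.ndarray, scale: str = "markers") -> float:
    """Scaling constant c for G = Xc Xc'/c.

    "markers": c = m, the per-marker convention (the package default; in an
    F2 at p = 0.5 this is exactly twice the VanRaden constant).
    "vanraden": c = sum_j 2 p_j (1 - p_j) from the +1-allele frequencies,
    which makes the mean diagonal of G approach 1 under HWE.
    """
    if scale == "markers":
        return float(X.shape[1])
    if scale == "vanraden":
        p = (X.mean(axis=0) + 1.0) / 2.0
        return float(np.sum(2.0 * p * (1.0 - p)))
    raise ValueError("scale must be 'markers' or 'vanraden'")


def fit_rrblup(
    markers: MarkerMatrix,
    phenos: PhenotypeTable | np.ndarray,
    varcomp: CovarianceSet,
    *,
    lambdas=None,
    scale: str = "vanraden",
) -> MarkerEffects:
    """Single-trait RR-BLUP of marker effects on entry means.

    ``varcomp`` supplies the genetic and residual variances that fix the
    ridge parameter per trait via the canonical variance relation
    sigma_g^2 = c sigma_u^2 with c = sum 2pq (``scale``); ``lambdas``
    overrides them directly (mainly for tests and degenerate designs).
    With lambda = 0 the system is solvable only when the centered marker
    matrix has full column rank.
    """
    if isinstance(phenos, PhenotypeTable):
        ybar = phenos.entry_means
        trait_names = phenos.trait_names
    else:
        ybar = np.asarray(phenos, dtype=float)
        if ybar.ndim == 1:
            ybar = ybar[:, None]
        trait_names = None
    g, t = ybar.shape
    if g != markers.n_genotypes:
        raise ValueError("marker matrix and phenotypes disagree on the number of genotypes")
    X = markers.X.astype(float)
    col_means = X.mean(axis=0)
    Xc = X - col_means
    m = markers.n_markers
    if lambdas is None:
        c = grm_scale(markers.X, scale)
        sg2 = np.diag(varcomp.C_hat)
        se2 = np.diag(varcomp.R_hat)
        if np.any(sg2 <= 0):
            raise ValueError("nonpositive genetic variance; cannot form the ridge parameter")
        lambdas = (se2 / varcomp.n_reps) / (sg2 / c)
    lambdas = np.broadcast_to(np.asarray(lambdas, dtype=float), (t,)).copy()
    mu = ybar.mean(axis=0)
    yc = ybar - mu
    u = np.empty((m, t))
    if m <= g:
        XtX = Xc.T @ Xc
        for q in range(t):
            A = XtX + lambdas[q] * np.eye(m)
            try:
                u[:, q] = np.linalg.solve(A, Xc.T @ yc[:, q])
            except np.linalg.LinAlgError as err:
                raise np.linalg.LinAlgError(
                    "singular RR-BLUP system; use a positive ridge (lambda > 0)"
                ) from err
    else:
        if np.any(lambdas <= 0):
            raise np.linalg.LinAlgError(
                "more markers than genotypes: the system is singular at lambda = 0; "
                "use a positive ridge (lambda > 0)"
            )
        K = Xc @ Xc.T
        for q in range(t):
            alpha = np.linalg.solve(K + lambdas[q] * np.eye(g), yc[:, q])
            u[:, q] = Xc.T @ alpha
    return MarkerEffects(
        u_hat=u,
        mu_hat=mu,
        lambdas=lambdas,
        col_means=col_means,
        marker_ids=markers.marker_ids,
        trait_names=trait_names,
    )


def predict_gebv(markers: MarkerMatrix, effects: MarkerEffects) -> GEBVTable:
    """GEBVs for a (possibly later-cycle) population: gamma = Xc,l u_hat,
    with Xl centered on the training-column means."""
    if markers.n_markers != effects.marker_ids.size or not np.array_equal(
        np.asarray(markers.marker_ids), np.asarray(effects.marker_ids)
    ):
        raise ValueError("marker columns do not match the training marker set")
    Xc = markers.X.astype(float) - effects.col_means
    gamma = Xc @ effects.u_hat
    return GEBVTable(gamma_hat=gamma, genotype_ids=markers.genotype_ids, cycle_id=markers.cycle_id)


def compute_grm(markers: MarkerMatrix, scale: str = "markers") -> GRM:
    """Genomic relationship matrix of one cycle, G = Xc Xc'/c, centered on
    that same cycle's allele frequencies."""
    if markers.n_genotypes < 2:
        raise ValueError("need at least 2 genotypes")
    X = markers.X.astype(float)
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("all markers monomorphic: relationship matrix undefined")
    c = grm_scale(markers.X, scale)
    if c == 0.0:
        raise ValueError("all markers monomorphic: relationship matrix undefined (c = 0)")
    G = (Xc @ Xc.T) / c
    return GRM(G=0.5 * (G + G.T), c=c, cycle_id=markers.cycle_id)


def estimate_gamma(gebvs: GEBVTable, grm: GRM) -> GammaMatrix:
    """Gamma_hat entries (1/g) (gamma_q - mean)' G^-1 (gamma_q' - mean).

    If G's smallest eigenvalue is below 1e-8 of the largest (always true
    for a column-centered G, whose rows sum to zero), a ridge of
    1e-6 * trace(G)/g is added before inversion; the repair is logged.
    The centered GEBV columns are orthogonal to the offending constant
    eigenvector, so the repaired inverse is stable in delta.
    """
    gamma = gebvs.gamma_hat
    if not np.all(np.isfinite(gamma)):
        raise ValueError("non-finite GEBVs")
    g = gamma.shape[0]
    if grm.G.shape[0] != g:
        raise ValueError("GRM and GEBV table disagree on the number of genotypes")
    gc = gamma - gamma.mean(axis=0)
    G = grm.G
    eigvals = np.linalg.eigvalsh(G)
    Gwork = G
    if eigvals.min() < 1e-8 * eigvals.max():
        delta = 1e-6 * np.trace(G) / g
        log.debug("GRM near-singular (min eig %.3e); adding ridge %.3e", eigvals.min(), delta)
        Gwork = G + delta * np.eye(g)
    Z = np.linalg.solve(Gwork, gc)
    Gamma = (gc.T @ Z) / g
    return GammaMatrix(Gamma_hat=0.5 * (Gamma + Gamma.T), cycle_id=gebvs.cycle_id)
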