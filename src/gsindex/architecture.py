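"""QTL trait architecture: pleiotropy pattern and additive effects.

Four traits are controlled by overlapping subsets of the genome's QTL.  The
calibration problem is inverse: given target genetic correlations between
trait pairs, find (i) which QTL each trait's subset shares with the others
and (ii) signed effect magnitudes in (0, 0.5], such that the realized
genetic correlations in an F2 reference population match the targets.  A
stochastic local search (simulated-annealing flavoured) over membership
swaps, sign flips and magnitude redraws minimises the maximum absolute
deviation from the target correlations.  The F2 genetic correlations
implied by a candidate effect matrix are evaluated against the *exact*
QTL-dosage covariance of the map (cov = 0.5 prod(1-2r), which carries the
linkage disequilibrium between QTL), so the calibration target is the
expected correlation rather than a noisy Monte-Carlo estimate that the
search could overfit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import Genome, f2_qtl_dosage_covariance

__all__ = ["TraitArchitecture", "ArchitectureError", "assign_architecture"]


class ArchitectureError(RuntimeError):
    """Raised when the architecture search cannot reach its tolerance."""


@dataclass
class TraitArchitecture:
    """QTL -> trait effects plus the phenotyping parameters that go with them.

    effects
        (n_qtl, n_traits) additive allele-substitution effects; zero where a
        QTL does not affect a trait, magnitudes otherwise in (0, 0.5].
    qtl_counts
        number of QTL affecting each trait (nonzero rows per column).
    target_corr
        the genetic correlation matrix the search calibrated against.
    heritabilities
        per-plot narrow-sense h^2 per trait.
    residual_vars
        per-plot residual variances sigma_g^2 (1 - h^2)/h^2 derived from the
        reference population's genotypic variances (recalibrated against the
        actual base population by the experiment driver).
    achieved_dev
        max absolute deviation of realized from target correlations.
    """

    effects: np.ndarray
    qtl_counts: tuple[int, ...]
    target_corr: np.ndarray
    heritabilities: np.ndarray
    residual_vars: np.ndarray
    achieved_dev: float

    @property
    def n_traits(self) -> int:
        return self.effects.shape[1]

    def realized_genetic_corr(self, dosage: np.ndarray) -> np.ndarray:
        """Genetic correlation matrix of breeding values in a population
        with the given (g, n_qtl) QTL dosage matrix."""
        tbv = (dosage - dosage.mean(axis=0)) @ self.effects
        return np.corrcoef(tbv, rowvar=False)


def _corr_from_cross(M: np.ndarray) -> np.ndarray:
    sd = np.sqrt(np.clip(np.diag(M), 1e-300, None))
    return M / np.outer(sd, sd)


def _max_dev(corr: np.ndarray, target: np.ndarray, iu) -> float:
    return float(np.max(np.abs(corr[iu] - target[iu])))


def _draw_mag(rng: np.random.Generator, size=None) -> np.ndarray:
    # uniform on (0, 0.5]
    return 0.5 * (1.0 - rng.random(size))


def assign_architecture(
    genome: Genome,
    targets: np.ndarray,
    qtl_counts,
    h2,
    rng: np.random.Generator | None = None,
    *,
    tol: float = 0.05,
    max_moves: int = 10_000,
) -> TraitArchitecture:
    """Search for a trait architecture whose expected F2 genetic
    correlations hit ``targets`` to within ``tol``.

    A search stopping the moment it crosses ``tol`` would sit at the
    tolerance boundary, leaving nothing for the sampling noise of a finite
    realized population; it therefore keeps polishing toward ``tol/2``
    while the move budget lasts, and only fails (raising
    :class:`ArchitectureError` with the best deviation) if ``tol`` itself
    is unreachable within ``max_moves`` moves.
    """
    rng = np.random.default_rng() if rng is None else rng
    targets = np.asarray(targets, dtype=float)
    qtl_counts = tuple(int(c) for c in np.atleast_1d(qtl_counts))
    h2 = np.atleast_1d(np.asarray(h2, dtype=float))
    t = len(qtl_counts)
    nq = genome.n_qtl
    if any(c > nq or c < 1 for c in qtl_counts):
        raise ValueError("each trait's QTL count must be in [1, n_qtl]")
    if np.any((h2 <= 0) | (h2 > 1)):
        raise ValueError("heritabilities must lie in (0, 1]")
    if t > 1:
        if targets.shape != (t, t) or not np.allclose(targets, targets.T) or not np.allclose(np.diag(targets), 1.0):
            raise ValueError("targets must be a symmetric correlation matrix with unit diagonal")

    S = f2_qtl_dosage_covariance(genome)

    # initial architecture: random membership, random signs and magnitudes
    E = np.zeros((nq, t))
    for q in range(t):
        members = rng.choice(nq, size=qtl_counts[q], replace=False)
        E[members, q] = _draw_mag(rng, qtl_counts[q]) * rng.choice([-1.0, 1.0], qtl_counts[q])

    def genetic_var(Ecur):
        return np.diag(Ecur.T @ S @ Ecur)

    if t == 1:
        arch = TraitArchitecture(
            effects=E,
            qtl_counts=qtl_counts,
            target_corr=np.ones((1, 1)),
            heritabilities=h2,
            residual_vars=genetic_var(E) * (1.0 - h2) / h2,
            achieved_dev=0.0,
        )
        return arch

    iu = np.triu_indices(t, k=1)
    SE = S @ E
    M = E.T @ SE
    dev = _max_dev(_corr_from_cross(M), targets, iu)
    best_E, best_dev = E.copy(), dev
    # geometric cooling over the move budget; scale set by the tolerance
    t0, t1 = 0.04, 1e-3
    polish_tol = 0.5 * tol
    for move in range(max_moves):
        if best_dev <= polish_tol:
            break
        temp = t0 * (t1 / t0) ** (move / max_moves)
        q = rng.integers(t)
        col = E[:, q]
        nz = np.flatnonzero(col)
        kind = rng.integers(3)
        j = nz[rng.integers(nz.size)]
        old_j, old_val = j, col[j]
        if kind == 0:       # flip sign
            col[j] = -col[j]
        elif kind == 1:     # redraw magnitude, keep sign
            col[j] = np.sign(col[j]) * _draw_mag(rng)
        else:               # move membership to a currently unaffected QTL
            zeros = np.flatnonzero(col == 0.0)
            if zeros.size == 0:
                col[j] = -col[j]
            else:
                k2 = zeros[rng.integers(zeros.size)]
                col[k2] = _draw_mag(rng) * rng.choice([-1.0, 1.0])
                col[j] = 0.0
                j = k2
        SE_new_col = S @ col
        M_new = M.copy()
        for q2 in range(t):
            if q2 != q:
                M_new[q, q2] = M_new[q2, q] = col @ SE[:, q2]
        M_new[q, q] = col @ SE_new_col
        dev_new = _max_dev(_corr_from_cross(M_new), targets, iu)
        if dev_new <= dev or rng.random() < np.exp((dev - dev_new) / temp):
            dev = dev_new
            M = M_new
            SE[:, q] = SE_new_col
            if dev < best_dev:
                best_dev = dev
                best_E = E.copy()
        else:  # undo
            col[j] = 0.0
            col[old_j] = old_val

    if best_dev > tol:
        raise ArchitectureError(
            f"architecture search did not reach tol={tol} in {max_moves} moves "
            f"(best max deviation {best_dev:.4f})"
        )
    gvar = np.diag(best_E.T @ S @ best_E)
    return TraitArchitecture(
        effects=best_E,
        qtl_counts=qtl_counts,
        target_corr=targets,
        heritabilities=h2,
        residual_vars=gvar * (1.0 - h2) / h2,
        achieved_dev=best_dev,
    )
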