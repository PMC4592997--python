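"""Replicated phenotypic evaluation of a simulated population.

Each genotype is evaluated in ``nreps`` plots; a plot value is the true
genotypic value plus an independent normal residual whose variance is set
from the per-plot heritability, sigma_e^2 = sigma_g^2 (1 - h^2)/h^2.  By
default sigma_g^2 is the realized genotypic variance of the population
being phenotyped (so per-plot h^2 holds exactly in that population); the
experiment driver calibrates the residual variances once in the base cycle
and passes them explicitly in later cycles, so that heritability drifts as
selection erodes genetic variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Population

__all__ = ["PhenotypeTable", "simulate_phenotypes"]


@dataclass
class PhenotypeTable:
    """Plot-level phenotypes: ``values[i, j, q]`` is replicate j of genotype
    i for trait q.  ``entry_means`` are the per-genotype replicate means on
    which index selection operates."""

    values: np.ndarray            # (g, nreps, t)
    genotype_ids: np.ndarray      # (g,)
    trait_names: tuple[str, ...]
    residual_vars: np.ndarray | None = None  # per-plot variances used to simulate

    @property
    def n_genotypes(self) -> int:
        return self.values.shape[0]

    @property
    def n_reps(self) -> int:
        return self.values.shape[1]

    @property
    def n_traits(self) -> int:
        return self.values.shape[2]

    @property
    def entry_means(self) -> np.ndarray:
        return self.values.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long table: genotype, rep (1-based), one column per trait."""
        g, r, t = self.values.shape
        return pd.DataFrame(
            {
                "genotype": np.repeat(self.genotype_ids, r),
                "rep": np.tile(np.arange(1, r + 1), g),
                **{
                    name: self.values[:, :, q].reshape(-1)
                    for q, name in enumerate(self.trait_names)
                },
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, trait_names=None) -> "PhenotypeTable":
        if trait_names is None:
            trait_names = tuple(c for c in frame.columns if c not in ("genotype", "rep"))
        counts = frame.groupby("genotype", sort=False).size()
        if counts.nunique() != 1:
            raise ValueError("unbalanced replication is not supported")
        r = int(counts.iloc[0])
        ids = counts.index.to_numpy()
        g = ids.size
        ordered = frame.sort_values(["genotype", "rep"], kind="stable") if "rep" in frame else frame
        vals = ordered.set_index("genotype").loc[ids, list(trait_names)].to_numpy()
        return cls(values=vals.reshape(g, r, len(trait_names)), genotype_ids=ids,
                   trait_names=tuple(trait_names))


def simulate_phenotypes(
    pop: Population,
    nreps: int = 4,
    rng: np.random.Generator | None = None,
    *,
    heritabilities=None,
    residual_vars=None,
    trait_names: tuple[str, ...] | None = None,
) -> PhenotypeTable:
    """Phenotype ``pop`` (which must carry true breeding values).

    Exactly one of ``heritabilities`` (per-plot h^2, residual variance
    derived from this population's genotypic variance) or ``residual_vars``
    (explicit per-plot variances) must be given.
    """
    rng = np.random.default_rng() if rng is None else rng
    if pop.tbv is None:
        raise ValueError("population has no true breeding values; attach an architecture first")
    tbv = pop.tbv
    g, t = tbv.shape
    if (heritabilities is None) == (residual_vars is None):
        raise ValueError("give exactly one of heritabilities or residual_vars")
    if residual_vars is None:
        h2 = np.asarray(heritabilities, dtype=float)
        if np.any((h2 <= 0) | (h2 > 1)):
            raise ValueError("per-plot heritabilities must lie in (0, 1]")
        sg2 = tbv.var(axis=0, ddof=1)
        residual_vars = sg2 * (1.0 - h2) / h2
    residual_vars = np.asarray(residual_vars, dtype=float)
    if residual_vars.shape != (t,) or np.any(residual_vars < 0):
        raise ValueError("residual_vars must be a nonnegative vector, one entry per trait")
    noise = rng.standard_normal((g, nreps, t)) * np.sqrt(residual_vars)
    values = tbv[:, None, :] + noise
    if trait_names is None:
        trait_names = tuple(f"T{q + 1}" for q in range(t))
    return PhenotypeTable(
        values=values,
        genotype_ids=np.arange(g),
        trait_names=trait_names,
        residual_vars=residual_vars,
    )
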