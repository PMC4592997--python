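"""Recurrent-selection experiments: paired phenotypic vs genomic runs.

The simulated design mirrors a maize F2 recurrent-selection program: a
base F2 of 500 genotypes (C0) is phenotyped in 4 replicates and used both
to run phenotypic index selection and to train marker effects once.  Both
branches share C0 and the C1 population it produces under phenotypic
selection; from C1 onward the phenotypic branch keeps re-estimating C, R, P
each cycle while the genomic branch selects purely on GEBVs predicted from
the C0-trained effects, estimating its response through the
relationship-weighted Gamma matrix.  Per cycle the driver also records the
"true" responses obtained by plugging the simulator's known covariances
into the response formulas, the index accuracies with the true net merit,
and the per-trait GEBV accuracies.

Residual variances are calibrated once against the realized C0 genotypic
variances (per-plot heritabilities hold exactly in C0) and held fixed, so
heritability drifts downward as selection erodes genetic variance.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .architecture import TraitArchitecture, assign_architecture
from .genome import Genome, GenomeConfig, Population, advance_cycle, build_genome, compute_tbv, make_f2
from .index import (
    CycleSummary,
    IndexSpec,
    accuracy,
    efficiency_ratio,
    expected_gains,
    gsi_values,
    index_response,
    psi_coefficients,
    selection_intensity,
    technow_inequality,
    truncate_select,
)
from .markers import (
    MarkerEffects,
    MarkerMatrix,
    compute_grm,
    estimate_gamma,
    fit_rrblup,
    load_markers,
    markers_from_population,
    predict_gebv,
)
from .phenotypes import PhenotypeTable, simulate_phenotypes
from .varcomp import CovarianceSet, bend_psd, estimate_cr
from . import io as gio

__all__ = [
    "ExperimentConfig",
    "PairedRun",
    "run_paired_experiment",
    "run_psi_experiment",
    "run_gsi_experiment",
    "run_real_experiment",
    "compare_indices",
]

log = logging.getLogger(__name__)

DEFAULT_CORR_TARGETS = (-0.5, 0.4, 0.3, -0.3, -0.2, 0.1)


@dataclass
class ExperimentConfig:
    """Settings for a simulated or file-driven (real) experiment.

    ``corr_targets`` are the upper-triangle genetic correlation targets in
    row order (T1T2, T1T3, T1T4, T2T3, T2T4, T3T4).  In real mode,
    ``marker_paths`` lists one coded-marker table per cycle (cycle 0 first,
    the training population) and ``phenotype_path`` the cycle-0 phenotype
    table; no simulator settings are used.
    """

    mode: str = "simulate"
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    qtl_counts: tuple = (300, 100, 60, 40)
    corr_targets: tuple = DEFAULT_CORR_TARGETS
    heritabilities: tuple = (0.4, 0.6, 0.6, 0.8)
    weights: tuple = (1.0, -1.0, 1.0, 1.0)
    n_genotypes: int = 500
    n_reps: int = 4
    p_selected: float = 0.10
    l_psi: float = 4.0
    l_gsi: float = 1.5
    n_cycles: int = 7
    seed: int = 0
    arch_tol: float = 0.05
    arch_max_moves: int = 10_000
    # real mode
    marker_paths: tuple = ()
    phenotype_path: str | None = None
    coding: str = "auto"
    trait_names: tuple | None = None
    outdir: str | None = None

    def target_matrix(self) -> np.ndarray:
        t = len(self.qtl_counts)
        T = np.eye(t)
        iu = np.triu_indices(t, k=1)
        vals = np.asarray(self.corr_targets, dtype=float)
        if vals.size != iu[0].size:
            raise ValueError("corr_targets must supply one value per trait pair")
        T[iu] = vals
        T[(iu[1], iu[0])] = vals
        return T

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = gio.load_config_dict(path)
        gcfg = GenomeConfig(**raw.pop("genome", {}))
        for key in ("qtl_counts", "corr_targets", "heritabilities", "weights", "marker_paths"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(genome=gcfg, **raw)

    def to_yaml(self, path) -> None:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        gio.dump_config_dict(plain(dataclasses.asdict(self)), path)


@dataclass
class PairedRun:
    """Everything one seeded simulated experiment produced."""

    config: ExperimentConfig
    genome: Genome
    architecture: TraitArchitecture
    psi_summaries: list
    gsi_summaries: list
    c0_population: Population
    c0_covariances: CovarianceSet
    marker_effects: MarkerEffects
    comparison: pd.DataFrame | None = None


def _true_genetic_cov(pop: Population) -> np.ndarray:
    return np.cov(pop.tbv, rowvar=False, ddof=1)


def _evaluate_psi_cycle(
    pop: Population,
    cfg: ExperimentConfig,
    residual_vars: np.ndarray,
    rng: np.random.Generator,
    k: float,
) -> tuple[CycleSummary, np.ndarray, CovarianceSet, PhenotypeTable]:
    """Phenotype one cycle, estimate covariances, build the index, select.

    The estimated response follows the plot-basis phenotypic matrix
    P = C + R; the true response is the selection-theory value of an index
    applied to entry means, using the simulator's known covariances on the
    entry-mean basis.  The reported accuracy rho_H is likewise the
    entry-mean-basis estimate, since selection ranks replicate means.
    """
    w = np.asarray(cfg.weights, dtype=float)
    phenos = simulate_phenotypes(pop, cfg.n_reps, rng, residual_vars=residual_vars)
    cov = estimate_cr(phenos, cycle_id=pop.cycle_id)
    P_hat = cov.phenotypic("plot")
    b_hat = psi_coefficients(P_hat, cov.C_hat, w)
    P_entry_hat = cov.phenotypic("entry")
    b_entry_hat = psi_coefficients(P_entry_hat, cov.C_hat, w)
    values = phenos.entry_means @ b_entry_hat
    selected = truncate_select(values, cfg.p_selected)

    C_t = _true_genetic_cov(pop)
    P_t = C_t + np.diag(residual_vars) / cfg.n_reps
    b_t = psi_coefficients(P_t, C_t, w)
    spec1 = IndexSpec(w=w, k=k, L=1.0, kind="PSI")
    specL = IndexSpec(w=w, k=k, L=cfg.l_psi, kind="PSI")
    summary = CycleSummary(
        cycle_id=pop.cycle_id,
        kind="PSI",
        r_est=index_response(spec1, P_hat, b_hat),
        r_true=index_response(spec1, P_t, b_t),
        r_est_year=index_response(specL, P_hat, b_hat),
        r_true_year=index_response(specL, P_t, b_t),
        gains_est=expected_gains(spec1, cov.C_hat, P_hat, b_hat),
        gains_est_year=expected_gains(specL, cov.C_hat, P_hat, b_hat),
        rho_H=accuracy(P_entry_hat, C_t, w, kind="PSI", b=b_entry_hat),
        sigma_H=float(np.sqrt(w @ C_t @ w)),
        selected_ids=selected,
    )
    return summary, selected, cov, phenos


def _evaluate_gsi_cycle(
    pop: Population,
    cfg: ExperimentConfig,
    effects: MarkerEffects,
    genome: Genome,
    k: float,
) -> tuple[CycleSummary, np.ndarray]:
    w = np.asarray(cfg.weights, dtype=float)
    markers = markers_from_population(pop, genome)
    gebvs = predict_gebv(markers, effects)
    grm = compute_grm(markers)
    gamma = estimate_gamma(gebvs, grm)
    values = gsi_values(gebvs, w)
    selected = truncate_select(values, cfg.p_selected)

    C_t = _true_genetic_cov(pop)
    spec1 = IndexSpec(w=w, k=k, L=1.0, kind="GSI")
    specL = IndexSpec(w=w, k=k, L=cfg.l_gsi, kind="GSI")
    corr = np.array(
        [np.corrcoef(gebvs.gamma_hat[:, q], pop.tbv[:, q])[0, 1] for q in range(w.size)]
    )
    summary = CycleSummary(
        cycle_id=pop.cycle_id,
        kind="GSI",
        r_est=index_response(spec1, gamma.Gamma_hat, w),
        r_true=float(k * np.sqrt(w @ C_t @ w)),
        r_est_year=index_response(specL, gamma.Gamma_hat, w),
        r_true_year=float(k / cfg.l_gsi * np.sqrt(w @ C_t @ w)),
        gains_est=expected_gains(spec1, gamma.Gamma_hat, gamma.Gamma_hat, w),
        gains_est_year=expected_gains(specL, gamma.Gamma_hat, gamma.Gamma_hat, w),
        rho_H=accuracy(gamma.Gamma_hat, C_t, w, kind="GSI"),
        sigma_H=float(np.sqrt(w @ C_t @ w)),
        gebv_tbv_corr=corr,
        selected_ids=selected,
    )
    return summary, selected


def run_paired_experiment(cfg: ExperimentConfig, n_cycles: int | None = None) -> PairedRun:
    """Run the paired design: C0 under phenotypic selection (training
    population for the genomic branch), then ``n_cycles`` further cycles of
    each index from the shared C1 population.
    """
    if cfg.mode != "simulate":
        raise ValueError("run_paired_experiment needs a simulate-mode config")
    n_cycles = cfg.n_cycles if n_cycles is None else n_cycles
    ss = np.random.SeedSequence(cfg.seed)
    r_genome, r_arch, r_f2, r_c0, r_psi, r_gsi = [np.random.default_rng(s) for s in ss.spawn(6)]
    k = selection_intensity(cfg.p_selected)
    w = np.asarray(cfg.weights, dtype=float)

    genome = build_genome(cfg.genome, seed=r_genome)
    arch = assign_architecture(
        genome,
        cfg.target_matrix(),
        cfg.qtl_counts,
        cfg.heritabilities,
        r_arch,
        tol=cfg.arch_tol,
        max_moves=cfg.arch_max_moves,
    )
    c0 = make_f2(genome, cfg.n_genotypes, r_f2)
    compute_tbv(c0, arch.effects, genome)
    # residual variances calibrated against the realized base population
    h2 = np.asarray(cfg.heritabilities, dtype=float)
    residual_vars = c0.tbv.var(axis=0, ddof=1) * (1.0 - h2) / h2

    # cycle 0: phenotypic selection only; also the GSI training population
    c0_summary, sel0, cov0, phenos0 = _evaluate_psi_cycle(c0, cfg, residual_vars, r_c0, k)
    effects = fit_rrblup(markers_from_population(c0, genome), phenos0, cov0)
    c1 = advance_cycle(c0, sel0, genome, cfg.n_genotypes, r_c0)
    compute_tbv(c1, arch.effects, genome)

    psi_summaries = [c0_summary]
    pop = c1
    for _ in range(n_cycles):
        summary, selected, _, _ = _evaluate_psi_cycle(pop, cfg, residual_vars, r_psi, k)
        psi_summaries.append(summary)
        if summary.cycle_id < n_cycles:
            pop = advance_cycle(pop, selected, genome, cfg.n_genotypes, r_psi)
            compute_tbv(pop, arch.effects, genome)

    gsi_summaries = []
    pop = c1
    for _ in range(n_cycles):
        summary, selected = _evaluate_gsi_cycle(pop, cfg, effects, genome, k)
        gsi_summaries.append(summary)
        if summary.cycle_id < n_cycles:
            pop = advance_cycle(pop, selected, genome, cfg.n_genotypes, r_gsi)
            compute_tbv(pop, arch.effects, genome)

    run = PairedRun(
        config=cfg,
        genome=genome,
        architecture=arch,
        psi_summaries=psi_summaries,
        gsi_summaries=gsi_summaries,
        c0_population=c0,
        c0_covariances=cov0,
        marker_effects=effects,
    )
    run.comparison = compare_indices(psi_summaries, gsi_summaries, cfg)
    if cfg.outdir:
        save_run(run, cfg.outdir)
    return run


def run_psi_experiment(cfg: ExperimentConfig) -> list:
    """Phenotypic recurrent selection, cycles C0..C{n_cycles}."""
    return run_paired_experiment(cfg).psi_summaries


def run_gsi_experiment(cfg: ExperimentConfig) -> list:
    """C0-trained genomic selection, cycles C1..C{n_cycles} (simulate mode)
    or C0..C{len(marker_paths)-1} (real mode)."""
    if cfg.mode == "simulate":
        return run_paired_experiment(cfg).gsi_summaries
    return run_real_experiment(cfg)["gsi_summaries"]


def compare_indices(psi_summaries, gsi_summaries, cfg: ExperimentConfig) -> pd.DataFrame:
    """Cycle-by-cycle comparison of the two indices.

    Reports per-year and per-cycle response ratios lambda, the
    estimated/true calibration ratios of each index, and the Technow
    decision per cycle (using the estimated PSI accuracy as h_PSI).  A
    final row averages the overlapping cycles.
    """
    psi_by_cycle = {s.cycle_id: s for s in psi_summaries}
    gsi_by_cycle = {s.cycle_id: s for s in gsi_summaries}
    cycles = sorted(set(psi_by_cycle) & set(gsi_by_cycle))
    if not cycles:
        raise ValueError("no overlapping cycles between the two runs")
    rows = []
    for cyc in cycles:
        p, g = psi_by_cycle[cyc], gsi_by_cycle[cyc]
        lam_year = efficiency_ratio(g.r_est_year, p.r_est_year)
        lam_cycle = efficiency_ratio(g.r_est, p.r_est)
        g.lambda_ratio = lam_year
        tech = None
        if g.rho_H is not None and p.rho_H is not None and p.rho_H > 0:
            tech = technow_inequality(cfg.l_gsi, cfg.l_psi, max(g.rho_H, 1e-12), min(p.rho_H, 1.0))
        rows.append(
            {
                "cycle": cyc,
                "lambda_per_year": lam_year,
                "lambda_per_cycle": lam_cycle,
                "gsi_est_true_ratio": None if not g.r_true else g.r_est / g.r_true,
                "psi_est_true_ratio": None if not p.r_true else p.r_est / p.r_true,
                "technow_holds": None if tech is None else tech["holds"],
                "technow_threshold": None if tech is None else tech["threshold"],
            }
        )
    df = pd.DataFrame(rows)
    mean_row = df.drop(columns=["cycle", "technow_holds"]).mean(numeric_only=True)
    mean_row["cycle"] = -1
    df = pd.concat([df, mean_row.to_frame().T], ignore_index=True)
    return df


# ---------------------------------------------------------------------------
# Real-data workflow


def _entry_level_phenotypes(path, trait_names=None) -> tuple[np.ndarray, np.ndarray, tuple]:
    df = pd.read_csv(path, sep=None, engine="python")
    id_col = df.columns[0]
    if "rep" in df.columns:
        tab = PhenotypeTable.from_frame(df.rename(columns={id_col: "genotype"}), trait_names)
        return tab.entry_means, tab.genotype_ids, tab.trait_names
    traits = trait_names or tuple(c for c in df.columns[1:])
    return df[list(traits)].to_numpy(dtype=float), df[id_col].to_numpy(), tuple(traits)


def run_real_experiment(cfg: ExperimentConfig) -> dict:
    """File-driven workflow: phenotypic index at C0, genomic index at every
    cycle with a marker table.

    With a replicated cycle-0 phenotype table C and R come from REML as in
    simulate mode.  The deposited-style entry-level tables (one row per
    genotype) cannot separate C from R, so the phenotypic covariance is the
    sample covariance of entry means and the genetic covariance is the
    genomic Gamma estimate of the training cycle; marker effects are then
    ridge-trained with the variance ratio implied by those two matrices.
    """
    if not cfg.marker_paths or cfg.phenotype_path is None:
        raise ValueError("real mode needs marker_paths and a cycle-0 phenotype_path")
    w = np.asarray(cfg.weights, dtype=float)
    k = selection_intensity(cfg.p_selected)
    cycles = [
        load_markers(p, coding=cfg.coding, cycle_id=i) for i, p in enumerate(cfg.marker_paths)
    ]
    m0 = cycles[0]
    df_path = cfg.phenotype_path
    try:
        phen = gio.read_phenotypes(df_path, trait_names=cfg.trait_names)
        replicated = True
    except ValueError:
        replicated = False
    if replicated:
        cov0 = estimate_cr(phen, cycle_id=0)
        ybar, ids, traits = phen.entry_means, phen.genotype_ids, phen.trait_names
        C_hat, P_hat = cov0.C_hat, cov0.phenotypic("plot")
        effects = fit_rrblup(m0, phen, cov0)
    else:
        ybar, ids, traits = _entry_level_phenotypes(df_path, cfg.trait_names)
        if ybar.shape[0] != m0.n_genotypes:
            raise ValueError("cycle-0 phenotypes and markers disagree on genotype count")
        P_hat = bend_psd(np.cov(ybar, rowvar=False, ddof=1))
        # provisional unit-ratio ridge, then genomic genetic covariance
        provisional = fit_rrblup(m0, ybar, None, lambdas=np.full(ybar.shape[1], compute_grm(m0).c))
        gamma0 = estimate_gamma(predict_gebv(m0, provisional), compute_grm(m0))
        C_hat = bend_psd(gamma0.Gamma_hat)
        R_entry = bend_psd(P_hat - C_hat)
        cov0 = CovarianceSet(C_hat=C_hat, R_hat=R_entry, n_genotypes=ybar.shape[0], n_reps=1, cycle_id=0)
        effects = fit_rrblup(m0, ybar, cov0)

    b_hat = psi_coefficients(P_hat, C_hat, w)
    spec_psi = IndexSpec(w=w, k=k, L=cfg.l_psi, kind="PSI")
    psi_values = ybar @ b_hat
    psi_summary = CycleSummary(
        cycle_id=0,
        kind="PSI",
        r_est=index_response(IndexSpec(w=w, k=k, L=1.0, kind="PSI"), P_hat, b_hat),
        r_est_year=index_response(spec_psi, P_hat, b_hat),
        gains_est=expected_gains(IndexSpec(w=w, k=k, L=1.0, kind="PSI"), C_hat, P_hat, b_hat),
        gains_est_year=expected_gains(spec_psi, C_hat, P_hat, b_hat),
        selected_ids=truncate_select(psi_values, cfg.p_selected),
    )

    gsi_summaries = []
    for markers in cycles:
        gebvs = predict_gebv(markers, effects)
        gamma = estimate_gamma(gebvs, compute_grm(markers))
        values = gsi_values(gebvs, w)
        spec1 = IndexSpec(w=w, k=k, L=1.0, kind="GSI")
        specL = IndexSpec(w=w, k=k, L=cfg.l_gsi, kind="GSI")
        gsi_summaries.append(
            CycleSummary(
                cycle_id=markers.cycle_id,
                kind="GSI",
                r_est=index_response(spec1, gamma.Gamma_hat, w),
                r_est_year=index_response(specL, gamma.Gamma_hat, w),
                gains_est=expected_gains(spec1, gamma.Gamma_hat, gamma.Gamma_hat, w),
                gains_est_year=expected_gains(specL, gamma.Gamma_hat, gamma.Gamma_hat, w),
                selected_ids=truncate_select(values, cfg.p_selected),
            )
        )
    result = {
        "psi_summary": psi_summary,
        "gsi_summaries": gsi_summaries,
        "trait_names": traits,
        "lambda_c0": efficiency_ratio(gsi_summaries[0].r_est_year, psi_summary.r_est_year),
    }
    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        gio.write_summaries([psi_summary] + gsi_summaries, out / "real_summaries.tsv")
    return result


def save_run(run: PairedRun, outdir) -> None:
    """Write the per-cycle TSVs, C0 matrices, selected ids and a plain-text
    report for one paired run."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    gio.write_summaries(run.psi_summaries, out / "psi_cycles.tsv")
    gio.write_summaries(run.gsi_summaries, out / "gsi_cycles.tsv")
    labels = [f"T{q+1}" for q in range(len(run.config.weights))]
    gio.write_matrix(run.c0_covariances.C_hat, out / "C0_C_hat.tsv", labels)
    gio.write_matrix(run.c0_covariances.R_hat, out / "C0_R_hat.tsv", labels)
    gio.write_matrix(run.c0_covariances.P_hat, out / "C0_P_hat.tsv", labels)
    run.comparison.to_csv(out / "comparison.tsv", sep="\t", index=False)
    with open(out / "report.txt", "w") as fh:
        fh.write(format_report(run))


def format_report(run: PairedRun) -> str:
    """Table-2/3-shaped plain-text summary of a paired run."""
    lines = [
        "Paired phenotypic (PSI) vs genomic (GSI) recurrent selection",
        f"seed={run.config.seed}  g={run.config.n_genotypes}  "
        f"p={run.config.p_selected}  L_PSI={run.config.l_psi}  L_GSI={run.config.l_gsi}",
        "",
        "cycle  R^_GSI  R_GSI  R^_PSI  R_PSI   R^G/RG  R^P/RP   rhoG   rhoP",
    ]
    psi = {s.cycle_id: s for s in run.psi_summaries}
    for g in run.gsi_summaries:
        p = psi.get(g.cycle_id)
        if p is None:
            continue
        lines.append(
            f"{g.cycle_id:>5d} {g.r_est:>7.2f} {g.r_true:>6.2f} {p.r_est:>7.2f} "
            f"{p.r_true:>6.2f} {g.r_est / g.r_true:>8.2f} {p.r_est / p.r_true:>7.2f} "
            f"{g.rho_H:>6.2f} {p.rho_H:>6.2f}"
        )
    lines.append("")
    lines.append("comparison (last row = average over overlapping cycles):")
    lines.append(run.comparison.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
    return "\n".join(lines) + "\n"
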