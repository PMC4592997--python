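"""Delimited-text serialization of matrices, tables and configs.

Everything round-trips through plain TSV with id headers so that runs can
be inspected, diffed and replayed without binary formats: marker matrices
(genotype id first column), phenotype tables (genotype, rep, one column per
trait), labelled covariance matrices, per-cycle summary tables, and a YAML
experiment config.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .markers import MarkerMatrix
from .phenotypes import PhenotypeTable

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_markers",
    "write_phenotypes",
    "read_phenotypes",
    "write_summaries",
    "load_config_dict",
    "dump_config_dict",
]


def write_matrix(M: np.ndarray, path, labels=None) -> None:
    """Write a square labelled matrix (covariances, G, Gamma) as TSV."""
    M = np.asarray(M)
    if labels is None:
        labels = [f"V{i+1}" for i in range(M.shape[0])]
    df = pd.DataFrame(M, index=labels, columns=labels)
    df.to_csv(path, sep="\t", index_label="id")


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: matrix is not square")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_markers(markers: MarkerMatrix, path) -> None:
    df = pd.DataFrame(markers.X, columns=[str(m) for m in markers.marker_ids])
    df.insert(0, "genotype", markers.genotype_ids)
    df.to_csv(path, sep="\t", index=False)


def write_phenotypes(phenos: PhenotypeTable, path) -> None:
    phenos.to_frame().to_csv(path, sep="\t", index=False)


def read_phenotypes(path, trait_names=None) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t")
    if "rep" not in df.columns:
        raise ValueError(f"{path}: replicated phenotype table needs a 'rep' column")
    return PhenotypeTable.from_frame(df, trait_names=trait_names)


def write_summaries(summaries, path) -> None:
    """Append-style per-cycle TSV of CycleSummary records."""
    rows = []
    for s in summaries:
        row = {
            "cycle": s.cycle_id,
            "kind": s.kind,
            "r_est": s.r_est,
            "r_true": s.r_true,
            "r_est_year": s.r_est_year,
            "r_true_year": s.r_true_year,
            "rho_H": s.rho_H,
            "sigma_H": s.sigma_H,
            "lambda": s.lambda_ratio,
            "n_selected": None if s.selected_ids is None else s.selected_ids.size,
        }
        if s.gains_est is not None:
            for q, v in enumerate(s.gains_est):
                row[f"gain_T{q+1}"] = v
        if s.gebv_tbv_corr is not None:
            for q, v in enumerate(s.gebv_tbv_corr):
                row[f"gebv_corr_T{q+1}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_config_dict(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def dump_config_dict(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
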