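"""Reading pilot-data tables and writing machine-readable run records."""

from __future__ import annotations

import json
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import LabelError, PilotParseError
from .models import SpectralMatrix, as_rng
from .sizer import FDRCurve, SampleSizeEstimate, SizerConfig

RESULTS_FORMAT_VERSION = 1


def read_pilot(path, group_column: str,
               covariate_columns: Optional[Sequence[str]] = None,
               delimiter: Optional[str] = None) -> SpectralMatrix:
    """Load a delimited samples x bins intensity table as pilot data.

    Rows are samples and columns are spectral bins or targeted-MS
    metabolites; ``group_column`` must hold exactly two levels (mapped to
    groups 1 and 2 in sorted order) and any ``covariate_columns`` are
    carried along.  The delimiter is sniffed (comma/tab) unless given.
    """
    try:
        df = pd.read_csv(path, sep=delimiter, engine="python")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as err:
        raise PilotParseError(f"could not parse {path}: {err}") from err
    if group_column not in df.columns:
        raise LabelError(f"group column {group_column!r} not found in {path}")
    covariate_columns = list(covariate_columns or [])
    for col in covariate_columns:
        if col not in df.columns:
            raise PilotParseError(f"covariate column {col!r} not found")
    levels = sorted(df[group_column].dropna().unique().tolist())
    if len(levels) != 2:
        raise LabelError(
            f"group column {group_column!r} must have exactly two levels, "
            f"found {len(levels)}: {levels}"
        )
    groups = df[group_column].map({levels[0]: 1, levels[1]: 2}).to_numpy()
    bin_cols = [c for c in df.columns
                if c != group_column and c not in covariate_columns]
    bad = []
    for col in bin_cols + covariate_columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            bad.append(col)
    if bad:
        raise PilotParseError(
            f"columns with missing or non-numeric entries: {bad}"
        )
    X = df[bin_cols].to_numpy(dtype=float)
    covariates = (df[covariate_columns].to_numpy(dtype=float)
                  if covariate_columns else None)
    return SpectralMatrix(X=X, groups=groups, covariates=covariates)


def write_pilot(data: SpectralMatrix, path, delimiter: str = ",",
                group_column: str = "group",
                covariate_prefix: str = "covar") -> None:
    """Write a SpectralMatrix back to delimited text (inverse of read_pilot)."""
    cols = {group_column: data.groups}
    if data.covariates is not None:
        for k in range(data.covariates.shape[1]):
            cols[f"{covariate_prefix}{k + 1}"] = data.covariates[:, k]
    for j in range(data.p):
        cols[f"bin{j + 1}"] = data.X[:, j]
    pd.DataFrame(cols).to_csv(path, sep=delimiter, index=False)


def make_fixture(n1: int, n2: int, p: int, effect_bins: int = 0,
                 effect_size: float = 0.0, rng=None) -> SpectralMatrix:
    """Gaussian toy pilot matrix with a known group-2 mean shift.

    The first ``effect_bins`` bins get a mean shift of ``effect_size`` in
    group 2; everything else is iid standard normal.  Intended for tests
    and documentation examples only.
    """
    if effect_bins > p:
        raise ValueError("effect_bins cannot exceed p")
    rng = as_rng(rng)
    X = rng.standard_normal((n1 + n2, p))
    X[n1:, :effect_bins] += effect_size
    groups = np.repeat([1, 2], [n1, n2])
    return SpectralMatrix(X=X, groups=groups)


def _config_record(config: SizerConfig) -> dict:
    spec = config.model_spec
    hyper = spec.hyper
    return {
        "p": config.p,
        "prop_significant": config.prop_significant,
        "target_fdr": config.target_fdr,
        "min_n": config.min_n,
        "max_n": config.max_n,
        "delta": config.delta,
        "n_perms": config.n_perms,
        "n_sims": config.n_sims,
        "seed": config.seed,
        "grid": list(config.grid) if config.grid is not None else None,
        "model": {
            "model": spec.model,
            "q": spec.q,
            "n_covariates": spec.n_covariates,
            "alpha1": hyper.alpha1,
            "alpha2": hyper.alpha2,
            "coef_sd": hyper.coef_sd,
            "sv_mean": hyper.sv_mean,
            "sv_phi": hyper.sv_phi,
            "sv_innovation_sd": hyper.sv_innovation_sd,
        },
    }


def results_record(estimate: SampleSizeEstimate) -> dict:
    """Machine-readable run record: config echo, grid, FDRs, n-hat."""
    curve = estimate.curve
    return {
        "format_version": RESULTS_FORMAT_VERSION,
        "config": _config_record(estimate.config),
        "n_hat": estimate.n_hat,
        "n_per_group": list(estimate.n_per_group),
        "achieved": estimate.achieved,
        "n_grid": curve.n_grid.tolist(),
        "fdr_p10": curve.fdr_p10.tolist(),
        "fdr_p50": curve.fdr_p50.tolist(),
        "fdr_p90": curve.fdr_p90.tolist(),
        "sim_fdrs": curve.sim_fdrs.tolist(),
    }


def write_results(estimate: SampleSizeEstimate, json_path,
                  csv_path=None) -> None:
    """Write the run record as JSON plus, optionally, a flat FDR-curve CSV."""
    record = results_record(estimate)
    with open(json_path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if csv_path is not None:
        export_fdr_plot_data(estimate.curve, estimate.config).to_csv(
            csv_path, index=False
        )


def export_fdr_plot_data(curve: FDRCurve, config: SizerConfig) -> pd.DataFrame:
    """Data series for the FDR-versus-sample-size plot."""
    return pd.DataFrame({
        "n": curve.n_grid,
        "fdr_p10": curve.fdr_p10,
        "fdr_p50": curve.fdr_p50,
        "fdr_p90": curve.fdr_p90,
        "target_fdr": np.full(len(curve), config.target_fdr),
    })


def export_prop_sweep_data(records) -> pd.DataFrame:
    """Data series for the FDR-versus-expected-proportion plot."""
    return pd.DataFrame.from_records(
        records,
        columns=["n", "prop_significant", "fdr_p10", "fdr_p50", "fdr_p90"],
    )
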