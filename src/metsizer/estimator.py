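"""High-level model/results interface for sample-size estimation.

:class:`MetSizeR` is constructed from the experiment's design parameters
(and, optionally, pilot data); :meth:`MetSizeR.fit` runs the full
simulation/permutation procedure and returns a :class:`MetSizeRResults`
carrying the estimated sample size, the FDR percentile curve, and a
printable summary.

Example
-------
>>> from metsizer import MetSizeR
>>> model = MetSizeR(model="ppca", p=300, prop_significant=0.2,
...                  target_fdr=0.05, min_n=10)
>>> res = model.fit(seed=1)
>>> res.n_hat        # doctest: +SKIP
30
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence

import pandas as pd

from .exceptions import ConfigError
from .models import ModelSpec, PriorHyperparams, SpectralMatrix
from .sizer import (
    DEFAULT_DELTA,
    SampleSizeEstimate,
    SizerConfig,
    run_metsizer,
    sweep_prop_significant,
)


class MetSizeR:
    """Analysis-based sample-size estimator for a two-group omics design.

    Parameters
    ----------
    model : {"ppca", "ppcca", "dppca"}
        The statistical model the practitioner intends to use for the
        eventual analysis; pseudo-pilot data are simulated from it.
    p : int
        Number of spectral bins (or targeted metabolites); ignored when
        pilot data are supplied (their width wins).
    prop_significant : float
        Expected proportion of truly different bins (m).
    target_fdr : float
        FDR the design should achieve.
    min_n : int
        Smallest total sample size to consider (even; balanced groups).
    n_covariates : int
        PPCCA only: number of per-sample covariates.
    q : int
        Latent dimension of the simulation model.
    delta : float
        Standardized effect size of the spiked true signals.
    n_perms, n_sims : int
        Label permutations per dataset and simulated datasets per
        candidate sample size.
    pilot : SpectralMatrix, optional
        Experimental pilot data; when given, the model is fitted to it
        once and simulations reuse the fixed estimates.
    hyper : PriorHyperparams, optional
        Prior hyperparameters for the no-pilot-data route.
    grid : sequence of int, optional
        Explicit candidate total sample sizes (even, increasing).
    """

    def __init__(self, model: str = "ppca", p: int = 200,
                 prop_significant: float = 0.20, target_fdr: float = 0.05,
                 min_n: int = 4, n_covariates: int = 0, q: int = 2,
                 delta: float = DEFAULT_DELTA, n_perms: int = 20,
                 n_sims: int = 20, pilot: Optional[SpectralMatrix] = None,
                 hyper: Optional[PriorHyperparams] = None,
                 grid: Optional[Sequence[int]] = None, max_n: int = 200):
        if pilot is not None:
            p = pilot.p
        spec = ModelSpec(model=model, p=p, q=q, n_covariates=n_covariates,
                         hyper=hyper or PriorHyperparams())
        self.config = SizerConfig(
            p=p, prop_significant=prop_significant, target_fdr=target_fdr,
            min_n=min_n, delta=delta, n_perms=n_perms, n_sims=n_sims,
            model_spec=spec, grid=tuple(grid) if grid is not None else None,
            max_n=max_n,
        )
        self.pilot = pilot

    @classmethod
    def from_pilot_csv(cls, path, group_column: str,
                       covariate_columns: Optional[Sequence[str]] = None,
                       delimiter: Optional[str] = None, **kwargs) -> "MetSizeR":
        """Construct from a delimited pilot-data table (see ``io.read_pilot``)."""
        from .io import read_pilot

        pilot = read_pilot(path, group_column,
                           covariate_columns=covariate_columns,
                           delimiter=delimiter)
        if covariate_columns:
            kwargs.setdefault("model", "ppcca")
            kwargs.setdefault("n_covariates", len(list(covariate_columns)))
        return cls(pilot=pilot, **kwargs)

    def fit(self, seed: Optional[int] = None) -> "MetSizeRResults":
        """Run the full estimation; ``seed`` makes the run reproducible."""
        config = replace(self.config, seed=seed)
        estimate = run_metsizer(config, pilot=self.pilot)
        return MetSizeRResults(estimate, model=self)

    def sweep_prop_significant(self, props, n_values,
                               seed: Optional[int] = None) -> pd.DataFrame:
        """FDR percentiles versus the expected significant proportion m."""
        from .io import export_prop_sweep_data

        if self.pilot is not None:
            raise ConfigError(
                "the m-sweep is defined for the prior-simulation route; "
                "run fit() for pilot-data designs"
            )
        config = replace(self.config, seed=seed)
        return export_prop_sweep_data(
            sweep_prop_significant(config, props, n_values)
        )


class MetSizeRResults:
    """Results of one sample-size estimation run."""

    def __init__(self, estimate: SampleSizeEstimate, model: MetSizeR):
        self._estimate = estimate
        self.model = model

    @property
    def estimate(self) -> SampleSizeEstimate:
        return self._estimate

    @property
    def n_hat(self) -> int:
        """Estimated optimal total sample size."""
        return self._estimate.n_hat

    @property
    def n_per_group(self) -> tuple:
        return self._estimate.n_per_group

    @property
    def achieved(self) -> bool:
        """Whether the target FDR was bracketed by the evaluated grid."""
        return self._estimate.achieved

    @property
    def curve(self) -> pd.DataFrame:
        """FDR percentile curve as a DataFrame (n, p10, p50, p90)."""
        c = self._estimate.curve
        return pd.DataFrame({
            "n": c.n_grid, "fdr_p10": c.fdr_p10, "fdr_p50": c.fdr_p50,
            "fdr_p90": c.fdr_p90,
        })

    def to_record(self) -> dict:
        from .io import results_record

        return results_record(self._estimate)

    def save(self, json_path, csv_path=None) -> None:
        from .io import write_results

        write_results(self._estimate, json_path, csv_path)

    def plot(self, ax=None):
        """FDR percentile band versus sample size, with the target line."""
        import matplotlib.pyplot as plt

        cfg = self._estimate.config
        c = self._estimate.curve
        if ax is None:
            _, ax = plt.subplots()
        ax.fill_between(c.n_grid, c.fdr_p10, c.fdr_p90, alpha=0.25,
                        color="tab:red", label="10th-90th percentile")
        ax.plot(c.n_grid, c.fdr_p50, color="tab:red", label="median FDR")
        ax.axhline(cfg.target_fdr, color="black", linestyle="--",
                   label=f"target FDR = {cfg.target_fdr:g}")
        ax.axvline(self.n_hat, color="grey", linestyle=":",
                   label=f"n-hat = {self.n_hat}")
        ax.set_xlabel("total sample size n")
        ax.set_ylabel("estimated FDR")
        ax.legend()
        return ax

    def summary(self) -> str:
        """Printable summary table of the run and its estimate."""
        cfg = self._estimate.config
        spec = cfg.model_spec
        lines = []
        bar = "=" * 64
        lines.append(bar)
        lines.append("Sample-size estimation for a two-group omics design".center(64))
        lines.append(bar)
        pilot = "yes" if self.model.pilot is not None else "no"
        rows = [
            ("Analysis model", spec.model.upper(), "Spectral bins (p)", cfg.p),
            ("Prop. significant (m)", f"{cfg.prop_significant:g}",
             "Target FDR", f"{cfg.target_fdr:g}"),
            ("Permutations", cfg.n_perms, "Simulations", cfg.n_sims),
            ("Effect size (delta)", f"{cfg.delta:g}", "Latent dim (q)", spec.q),
            ("Pilot data", pilot, "Seed", cfg.seed),
        ]
        for l1, v1, l2, v2 in rows:
            lines.append(f"{l1 + ':':<24}{str(v1):>8}    {l2 + ':':<18}{str(v2):>8}")
        lines.append("-" * 64)
        lines.append(f"Estimated total sample size (n-hat): {self.n_hat:>16}")
        n1, n2 = self.n_per_group
        lines.append(f"Per-group allocation:                {f'{n1}/{n2}':>16}")
        lines.append(f"Target FDR bracketed by grid:        "
                     f"{'yes' if self.achieved else 'no':>16}")
        lines.append("-" * 64)
        lines.append("FDR percentiles by candidate sample size")
        lines.append(f"{'n':>6} {'p10':>9} {'median':>9} {'p90':>9}")
        c = self._estimate.curve
        for k in range(len(c)):
            lines.append(f"{int(c.n_grid[k]):>6} {c.fdr_p10[k]:>9.4f} "
                         f"{c.fdr_p50[k]:>9.4f} {c.fdr_p90[k]:>9.4f}")
        lines.append(bar)
        return "\n".join(lines)

    def __repr__(self):
        return (f"<MetSizeRResults n_hat={self.n_hat} "
                f"per_group={self.n_per_group} achieved={self.achieved}>")
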