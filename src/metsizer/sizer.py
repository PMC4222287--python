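"""Sample-size search: spiked-FDR estimation over a grid of candidate n.

The estimator asks: if the experiment were run with n samples (n/2 per
group) and analysed with the intended latent-variable model, what false
discovery rate would a moderated-t screen achieve when a fraction m of the
bins truly differ?  For each candidate n it

1. simulates pilot data from the analysis model (fresh prior draw per
   simulation, or fixed fitted parameters when real pilot data exist);
2. estimates the null law of the statistic by T label permutations;
3. spikes p0 = m * p randomly chosen statistics with an effect of size
   delta (in within-group standard-deviation units), making them truly
   significant;
4. declares the bins whose |TS| strictly exceed the p0-th largest value and
   scores the false discovery rate among them;
5. reduces the T per-permutation FDRs to their median, repeats over SIM
   simulations, and records the 10th/50th/90th percentiles.

The optimal total sample size is where the median-FDR curve crosses the
target, found by a two-point linear interpolation and rounded to the
nearest even integer (balanced groups; ties round up).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .exceptions import ConfigError, DomainError
from .models import (
    ModelParams,
    ModelSpec,
    SpectralMatrix,
    as_rng,
    draw_prior_params,
    simulate_pilot,
)
from .significance import correction_factor, permutation_null, pooled_se

#: Default effect size: the 99th quantile of the standard-Gaussian loading
#: prior, rounded to one decimal (Phi^{-1}(0.99) = 2.326... -> 2.3).
DEFAULT_DELTA = 2.3

#: Percentiles summarizing the spread of per-simulation FDR values.
FDR_PERCENTILES = (10.0, 50.0, 90.0)


def round_to_even(x: float) -> int:
    """Nearest even integer, ties (odd integers) rounding upward."""
    return int(2 * np.floor(x / 2.0 + 0.5))


@dataclass(frozen=True)
class SizerConfig:
    """Full configuration of one sample-size estimation run.

    Defaults mirror the method's standard operating point: 200 spectral
    bins, 20% of bins expected to differ, a 5% target FDR, a minimum total
    sample size of 4, effect size 2.3, and 20 permutations x 20 simulations.
    """

    p: int = 200
    prop_significant: float = 0.20
    target_fdr: float = 0.05
    min_n: int = 4
    delta: float = DEFAULT_DELTA
    n_perms: int = 20
    n_sims: int = 20
    model_spec: Optional[ModelSpec] = None
    grid: Optional[tuple] = None
    max_n: int = 200
    seed: Optional[int] = None
    baseline_groups: Optional[tuple] = None

    def __post_init__(self):
        if not 0 < self.target_fdr < 1:
            raise ConfigError(f"target_fdr must be in (0,1), got {self.target_fdr}")
        if not 0 < self.prop_significant < 1:
            raise ConfigError(
                f"prop_significant must be in (0,1), got {self.prop_significant}"
            )
        if self.min_n < 4:
            raise ConfigError(f"min_n must be >= 4, got {self.min_n}")
        if self.min_n % 2:
            raise ConfigError(
                f"min_n must be even (balanced groups), got {self.min_n}"
            )
        if self.max_n < self.min_n:
            raise ConfigError("max_n must be >= min_n")
        if self.n_perms < 1 or self.n_sims < 1:
            raise ConfigError("n_perms and n_sims must be >= 1")
        if self.delta < 0:
            raise ConfigError(f"delta must be non-negative, got {self.delta}")
        p0 = int(np.floor(self.prop_significant * self.p + 0.5))
        if p0 < 1:
            raise ConfigError(
                f"prop_significant * p = {self.prop_significant * self.p:.3g} "
                "rounds to zero spiked bins"
            )
        if p0 >= self.p:
            raise ConfigError("the number of spiked bins must be < p")
        if self.model_spec is None:
            object.__setattr__(self, "model_spec", ModelSpec(p=self.p))
        elif self.model_spec.p != self.p:
            raise ConfigError(
                f"model_spec.p={self.model_spec.p} disagrees with p={self.p}"
            )
        if self.grid is not None:
            grid = tuple(int(n) for n in self.grid)
            if len(grid) == 0:
                raise ConfigError("explicit grid must be non-empty")
            if any(n % 2 or n < self.min_n for n in grid):
                raise ConfigError(
                    "all grid sample sizes must be even and >= min_n"
                )
            if list(grid) != sorted(set(grid)):
                raise ConfigError("grid must be strictly increasing")
            object.__setattr__(self, "grid", grid)

        if self.baseline_groups is not None:
            b1, b2 = (int(v) for v in self.baseline_groups)
            if b1 < 2 or b2 < 2:
                raise ConfigError("baseline group sizes must each be >= 2")
            object.__setattr__(self, "baseline_groups", (b1, b2))

    @property
    def p0(self) -> int:
        """Number of spiked (truly significant) bins: round(m * p), >= 1."""
        return int(np.floor(self.prop_significant * self.p + 0.5))

    @property
    def baseline_factor(self) -> float:
        """sqrt(1/n1 + 1/n2) at the baseline (minimum or pilot) group sizes.

        The spiked effect is calibrated once, at the design's baseline
        sample size, and held fixed while the candidate n grows; the pooled
        SE in the statistic keeps shrinking with n, so larger experiments
        separate the spiked bins more cleanly.  This fixed calibration is
        what makes the FDR fall with sample size.
        """
        if self.baseline_groups is not None:
            b1, b2 = self.baseline_groups
        else:
            b1 = self.min_n // 2
            b2 = self.min_n - b1
        return float(np.sqrt(1.0 / b1 + 1.0 / b2))


@dataclass
class FDRCurve:
    """FDR percentile summaries across the candidate sample sizes."""

    n_grid: np.ndarray       # candidate total sample sizes
    fdr_p10: np.ndarray
    fdr_p50: np.ndarray
    fdr_p90: np.ndarray
    sim_fdrs: np.ndarray     # len(grid) x SIM per-simulation FDR values

    def __len__(self):
        return len(self.n_grid)


@dataclass
class SampleSizeEstimate:
    """Interpolated optimal sample size with its provenance."""

    n_hat: int
    n_per_group: tuple
    achieved: bool           # True when the grid brackets the target FDR
    curve: FDRCurve
    config: SizerConfig


def spike_statistics(TS_t: np.ndarray, S_t: np.ndarray, cf: float,
                     config: SizerConfig, n1: int, n2: int, rng=None):
    """Add a delta-sized true effect to p0 randomly chosen statistics.

    The injected group-mean difference is delta * rho_jt * b, where
    rho_jt = S_jt / sqrt(1/n1 + 1/n2) is the pooled within-group standard
    deviation of the permuted dataset (group sizes n1, n2) and
    b = sqrt(1/n1 + 1/n2) evaluated at the *baseline* group sizes
    (``config.baseline_factor``).  On the statistic scale the selected bins
    gain delta * rho_jt * b / (S_jt + cf): when the dataset is at the
    baseline size this is exactly delta * S_jt / (S_jt + cf), and as n
    grows beyond the baseline the same calibrated effect becomes easier to
    detect.  Returns the spiked statistic vector and the spiked index set.
    """
    rng = as_rng(rng)
    p = TS_t.shape[0]
    p0 = config.p0
    idx = rng.choice(p, size=p0, replace=False)
    spiked = TS_t.copy()
    rho = S_t[idx] / np.sqrt(1.0 / n1 + 1.0 / n2)
    denom = S_t[idx] + cf
    shift = np.divide(config.delta * rho * config.baseline_factor, denom,
                      out=np.zeros(p0), where=denom > 0)
    spiked[idx] += shift
    return spiked, idx


def fdr_one_permutation(spiked_TS: np.ndarray, spiked_idx: np.ndarray,
                        p0: int) -> float:
    """FDR of the spiked-statistic screen for one permutation.

    The cutoff is the p0-th largest |TS|; bins strictly above it are
    declared significant, and the FDR is the unspiked fraction of the
    declared set (0 when nothing is declared).
    """
    abs_ts = np.abs(spiked_TS)
    p = abs_ts.shape[0]
    if not 0 < p0 < p:
        raise DomainError(f"need 0 < p0 < p, got p0={p0}, p={p}")
    crit = np.partition(abs_ts, p - p0)[p - p0]
    declared = abs_ts > crit
    n_declared = int(declared.sum())
    is_spiked = np.zeros(p, dtype=bool)
    is_spiked[spiked_idx] = True
    n_false = int((declared & ~is_spiked).sum())
    return n_false / max(1, n_declared)


def fdr_one_simulation(X: SpectralMatrix, config: SizerConfig,
                       rng=None) -> float:
    """Median over T permutations of the spiked-screen FDR for one dataset.

    The correction factor is computed once from the unpermuted labels and
    held fixed; the pooled SEs used for spiking are the per-permutation
    ones.
    """
    rng = as_rng(rng)
    cf = correction_factor(pooled_se(X))
    null = permutation_null(X, config.n_perms, cf, rng)
    fdrs = np.empty(config.n_perms)
    for t in range(config.n_perms):
        spiked, idx = spike_statistics(null.TS_perm[t], null.S_perm[t], cf,
                                       config, X.n1, X.n2, rng)
        fdrs[t] = fdr_one_permutation(spiked, idx, config.p0)
    return float(np.median(fdrs))


def _simulate_at(n: int, config: SizerConfig, params: Optional[ModelParams],
                 rng: np.random.Generator) -> SpectralMatrix:
    n1 = n // 2
    n2 = n - n1
    spec = config.model_spec
    if params is None:
        draw = draw_prior_params(spec, n, rng)
        return simulate_pilot(draw, spec, n1, n2, rng)
    return simulate_pilot(params, spec, n1, n2, rng)


def _fdrs_at(n: int, config: SizerConfig, params, rng) -> np.ndarray:
    vals = np.empty(config.n_sims)
    for s in range(config.n_sims):
        X = _simulate_at(n, config, params, rng)
        vals[s] = fdr_one_simulation(X, config, rng)
    return vals


def fdr_curve(config: SizerConfig, params: Optional[ModelParams] = None,
              rng=None) -> FDRCurve:
    """Estimate the FDR percentile curve over candidate sample sizes.

    Without ``params`` (the no-pilot-data route) every simulation redraws
    the model parameters from their priors, so the percentile band also
    reflects parameter uncertainty; with fitted ``params`` the band only
    reflects sampling and permutation noise.  When no explicit grid is
    configured, candidate sizes start at ``min_n`` and grow in steps of 2
    until the median FDR falls below 0.8 x target (or ``max_n`` is hit).
    """
    rng = as_rng(rng if rng is not None else config.seed)
    ns, sims = [], []
    if config.grid is not None:
        for n in config.grid:
            ns.append(n)
            sims.append(_fdrs_at(n, config, params, rng))
    else:
        n = config.min_n
        while True:
            vals = _fdrs_at(n, config, params, rng)
            ns.append(n)
            sims.append(vals)
            if len(ns) >= 2 and np.median(vals) < 0.8 * config.target_fdr:
                break
            if n + 2 > config.max_n:
                break
            n += 2
    sims = np.asarray(sims)
    p10, p50, p90 = (np.percentile(sims, q, axis=1) for q in FDR_PERCENTILES)
    return FDRCurve(n_grid=np.asarray(ns), fdr_p10=p10, fdr_p50=p50,
                    fdr_p90=p90, sim_fdrs=sims)


def interpolate_n_hat(curve: FDRCurve, target_fdr: float) -> tuple:
    """Locate the target-FDR crossing of the median curve.

    An exact hit returns that grid point.  Otherwise a straight line is fit
    through the last grid point with median FDR >= target and the first
    with median FDR <= target, and n-hat is the line's prediction at the
    target, rounded to the nearest even integer (ties upward).  When the
    curve never brackets the target the nearest grid end is returned with
    ``achieved=False``.

    Returns ``(n_hat, achieved)``.
    """
    if len(curve) < 2:
        raise DomainError("need at least two grid points to interpolate")
    med = curve.fdr_p50
    ns = curve.n_grid
    exact = np.flatnonzero(med == target_fdr)
    if exact.size:
        return int(ns[exact[0]]), True
    above = np.flatnonzero(med >= target_fdr)
    below = np.flatnonzero(med <= target_fdr)
    if below.size == 0:
        warnings.warn(
            "median FDR never reached the target on the evaluated grid; "
            "returning the largest candidate sample size",
            stacklevel=2,
        )
        return int(ns[-1]), False
    if above.size == 0:
        warnings.warn(
            "median FDR is below the target already at the smallest "
            "candidate sample size; returning it",
            stacklevel=2,
        )
        return int(ns[0]), False
    i = above[-1]          # last point at or above the target
    j = below[0]           # first point at or below the target
    f_i, f_j = med[i], med[j]
    n_i, n_j = ns[i], ns[j]
    slope = (n_j - n_i) / (f_j - f_i)
    n_raw = n_i + (target_fdr - f_i) * slope
    n_hat = max(round_to_even(n_raw), int(ns.min()))
    return n_hat, True


def run_metsizer(config: SizerConfig,
                 pilot: Optional[SpectralMatrix] = None,
                 fitted_params: Optional[ModelParams] = None) -> SampleSizeEstimate:
    """End-to-end sample-size estimation, fully determined by config.seed.

    With ``pilot`` data the intended model is fitted once (PPCA closed form
    or PPCCA EM) and all simulations reuse the fixed estimates; otherwise
    every simulation draws parameters from the priors.  ``fitted_params``
    may be supplied directly instead of pilot data.
    """
    from .models import fit_ppca_mle, fit_ppcca_em  # local to avoid cycle noise

    params = fitted_params
    if pilot is not None:
        if fitted_params is not None:
            raise ConfigError("supply pilot data or fitted_params, not both")
        if pilot.p != config.p:
            config = replace(config, p=pilot.p,
                             model_spec=replace(config.model_spec, p=pilot.p))
        if config.baseline_groups is None:
            # calibrate the spiked effect at the pilot's own group sizes
            config = replace(config, baseline_groups=(pilot.n1, pilot.n2))
        spec = config.model_spec
        if spec.model == "ppca":
            params = fit_ppca_mle(pilot, spec.q)
        elif spec.model == "ppcca":
            if pilot.covariates is None:
                raise ConfigError("PPCCA pilot fitting requires covariates")
            params = fit_ppcca_em(pilot, pilot.covariates, spec.q)
        else:
            raise ConfigError(
                "DPPCA cannot be fitted to pilot data (requires MCMC); "
                "use the prior-simulation route or another model"
            )
    curve = fdr_curve(config, params=params)
    n_hat, achieved = interpolate_n_hat(curve, config.target_fdr)
    return SampleSizeEstimate(
        n_hat=n_hat,
        n_per_group=(n_hat // 2, n_hat - n_hat // 2),
        achieved=achieved,
        curve=curve,
        config=config,
    )


def sweep_prop_significant(config: SizerConfig, props, n_values,
                           params: Optional[ModelParams] = None):
    """FDR percentiles as a function of the expected significant proportion.

    For each fixed total sample size in ``n_values`` and each proportion m
    in ``props``, estimates the 10/50/90 FDR percentiles over
    ``config.n_sims`` simulations.  Returns a list of records (dicts).
    """
    rng = as_rng(config.seed)
    records = []
    for n in n_values:
        if n % 2 or n < config.min_n:
            raise ConfigError("swept sample sizes must be even and >= min_n")
        for m in props:
            cfg_m = replace(config, prop_significant=float(m))
            vals = _fdrs_at(int(n), cfg_m, params, rng)
            p10, p50, p90 = (np.percentile(vals, q) for q in FDR_PERCENTILES)
            records.append({
                "n": int(n), "prop_significant": float(m),
                "fdr_p10": float(p10), "fdr_p50": float(p50),
                "fdr_p90": float(p90),
            })
    return records
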