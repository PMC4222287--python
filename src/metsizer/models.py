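"""Gaussian latent-variable models used to simulate pseudo-pilot spectra.

Three intended-analysis models are supported, all of the form

    x_i = W u_i + mu + eps_i,        eps_i ~ MVN_p(0, sigma2 * I)

with a p x q loadings matrix W (q << p) and latent scores u_i:

* PPCA   — probabilistic PCA: u_i ~ MVN_q(0, I).
* PPCCA  — PPCA with covariates: the latent mean is a linear function of
  observed per-sample covariates, u_i ~ MVN_q(B c_i, I) where c_i includes
  an intercept.
* DPPCA  — dynamic PPCA for longitudinal designs; only its first time point
  is used here, where each latent dimension has its own variance exp(h_l)
  and the log-volatilities h_l follow the stationary law of a
  stochastic-volatility AR(1) process.

Two routes produce a parameter set: :func:`draw_prior_params` samples
(W, sigma2, u) from the priors — the no-pilot-data route — and
:func:`fit_ppca_mle` / :func:`fit_ppcca_em` estimate them from an
experimental pilot dataset.  Either way, :func:`simulate_pilot` turns a
parameter set into a synthetic two-group spectral matrix with *no* group
signal: under the null the two groups are generated identically, and any
true effects are injected later, on the test-statistic scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import (
    CollinearityWarning,
    ConvergenceError,
    DegenerateDataError,
    DimensionError,
    DomainError,
)

MODELS = ("ppca", "ppcca", "dppca")

#: Default inverse-gamma hyperparameters for the noise variance prior
#: sigma2 ~ IG(shape=3, scale=4), parameterized so the prior mean is
#: scale / (shape - 1) = 2.
DEFAULT_ALPHA1 = 3.0
DEFAULT_ALPHA2 = 4.0


def as_rng(seed_or_rng=None) -> np.random.Generator:
    """Coerce ``None``, an int seed, or a Generator into a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass(frozen=True)
class PriorHyperparams:
    """Hyperparameters of the prior distributions used for simulation.

    Parameters
    ----------
    alpha1, alpha2
        Shape and scale of the inverse-gamma prior on the noise variance
        sigma2; defaults (3, 4) give prior mean 2.
    mu_w, sigma_w
        Mean vector and covariance of the Gaussian prior on each row of the
        loadings matrix.  ``None`` means the standard choice (zero mean,
        identity covariance).
    coef_sd
        PPCCA only: standard deviation of the independent Gaussian prior on
        each latent-mean regression coefficient (covariates are standardized
        before use, so a unit scale is the natural default).
    sv_mean, sv_phi, sv_innovation_sd
        DPPCA only: level, persistence and innovation standard deviation of
        the log-volatility AR(1) process.  The first-time-point
        log-volatility of each latent dimension is drawn from the process's
        stationary law N(sv_mean, sv_innovation_sd**2 / (1 - sv_phi**2));
        the defaults make that law standard normal.
    """

    alpha1: float = DEFAULT_ALPHA1
    alpha2: float = DEFAULT_ALPHA2
    mu_w: Optional[np.ndarray] = None
    sigma_w: Optional[np.ndarray] = None
    coef_sd: float = 1.0
    sv_mean: float = 0.0
    sv_phi: float = 0.8
    sv_innovation_sd: float = 0.6

    def __post_init__(self):
        if self.alpha1 <= 0 or self.alpha2 <= 0:
            raise DomainError(
                f"inverse-gamma hyperparameters must be positive, got "
                f"alpha1={self.alpha1}, alpha2={self.alpha2}"
            )
        if self.coef_sd <= 0:
            raise DomainError("coef_sd must be positive")
        if not -1.0 < self.sv_phi < 1.0:
            raise DomainError("sv_phi must lie in (-1, 1) for stationarity")
        if self.sv_innovation_sd <= 0:
            raise DomainError("sv_innovation_sd must be positive")
        if self.mu_w is not None:
            object.__setattr__(self, "mu_w", np.asarray(self.mu_w, dtype=float))
        if self.sigma_w is not None:
            sw = np.asarray(self.sigma_w, dtype=float)
            if sw.ndim != 2 or sw.shape[0] != sw.shape[1]:
                raise DimensionError("sigma_w must be a square matrix")
            if not np.allclose(sw, sw.T):
                raise DomainError("sigma_w must be symmetric")
            # positive definiteness check via Cholesky
            try:
                np.linalg.cholesky(sw)
            except np.linalg.LinAlgError as err:
                raise DomainError("sigma_w must be positive definite") from err
            object.__setattr__(self, "sigma_w", sw)

    @property
    def sv_stationary_sd(self) -> float:
        return self.sv_innovation_sd / np.sqrt(1.0 - self.sv_phi**2)

    def loading_mean(self, q: int) -> np.ndarray:
        if self.mu_w is None:
            return np.zeros(q)
        if self.mu_w.shape != (q,):
            raise DimensionError(
                f"mu_w has shape {self.mu_w.shape}, expected ({q},)"
            )
        return self.mu_w

    def loading_cov(self, q: int) -> np.ndarray:
        if self.sigma_w is None:
            return np.eye(q)
        if self.sigma_w.shape != (q, q):
            raise DimensionError(
                f"sigma_w has shape {self.sigma_w.shape}, expected ({q}, {q})"
            )
        return self.sigma_w


@dataclass(frozen=True)
class ModelSpec:
    """Which analysis model will be used, and its dimensions."""

    model: str = "ppca"
    p: int = 200
    q: int = 2
    n_covariates: int = 0
    hyper: PriorHyperparams = field(default_factory=PriorHyperparams)

    def __post_init__(self):
        model = self.model.lower()
        if model not in MODELS:
            raise DomainError(f"unknown model {model!r}; expected one of {MODELS}")
        object.__setattr__(self, "model", model)
        if self.p < 2 or self.q < 1:
            raise DimensionError(f"need p >= 2 and q >= 1, got p={self.p}, q={self.q}")
        if self.q >= self.p:
            raise DimensionError(
                f"latent dimension q={self.q} must be smaller than the number "
                f"of bins p={self.p}"
            )
        if model == "ppcca":
            if self.n_covariates < 1:
                raise DimensionError("PPCCA requires n_covariates >= 1")
        elif self.n_covariates != 0:
            raise DimensionError(
                f"n_covariates must be 0 for model {model!r}"
            )


@dataclass
class ModelParams:
    """One realized parameter set of a latent-variable spectral model.

    ``U`` holds pre-drawn latent scores (the prior-simulation route); when it
    is ``None`` (the fitted route) fresh scores are drawn inside
    :func:`simulate_pilot` on every call.
    """

    W: np.ndarray                     # (p, q) loadings
    mu: np.ndarray                    # (p,) mean spectrum
    sigma2: float                     # isotropic noise variance
    U: Optional[np.ndarray] = None    # (n, q) latent scores, prior draws only
    coef: Optional[np.ndarray] = None  # (q, 1 + c) latent-mean coefficients
    covariates: Optional[np.ndarray] = None  # (n, c) standardized covariates
    latent_sd: Optional[np.ndarray] = None   # (q,) per-dimension sd (DPPCA)
    source: str = "prior_draw"

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        if self.W.ndim != 2:
            raise DimensionError("W must be a p x q matrix")
        if self.mu.shape != (self.W.shape[0],):
            raise DimensionError("mu must be a p-vector aligned with W")
        if not np.isfinite(self.sigma2) or self.sigma2 < 0:
            raise DomainError(f"sigma2 must be non-negative, got {self.sigma2}")
        if self.source not in ("prior_draw", "mle_fit"):
            raise DomainError(f"unknown source {self.source!r}")

    @property
    def p(self) -> int:
        return self.W.shape[0]

    @property
    def q(self) -> int:
        return self.W.shape[1]


@dataclass
class SpectralMatrix:
    """A samples x bins intensity matrix with a two-level group label.

    Rows are samples; columns are NMR spectral bins or targeted-MS
    metabolites.  Groups are coded 1 and 2, and each group must contain at
    least two samples so that a within-group variance exists.
    """

    X: np.ndarray
    groups: np.ndarray
    covariates: Optional[np.ndarray] = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.X.ndim != 2:
            raise DimensionError("X must be 2-dimensional (samples x bins)")
        if self.groups.shape != (self.X.shape[0],):
            raise DimensionError("groups must have one entry per row of X")
        if not np.isfinite(self.X).all():
            raise DegenerateDataError("X contains missing or non-finite values")
        levels = np.unique(self.groups)
        if not np.array_equal(levels, np.array([1, 2])):
            raise DomainError(
                f"groups must contain exactly the levels 1 and 2, got {levels}"
            )
        if self.n1 < 2 or self.n2 < 2:
            raise DegenerateDataError(
                "each group needs >= 2 samples to admit a variance estimate "
                f"(got n1={self.n1}, n2={self.n2})"
            )
        if self.covariates is not None:
            self.covariates = np.atleast_2d(
                np.asarray(self.covariates, dtype=float)
            )
            if self.covariates.shape[0] != self.X.shape[0]:
                raise DimensionError("covariates must be row-aligned with X")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n1(self) -> int:
        return int(np.sum(self.groups == 1))

    @property
    def n2(self) -> int:
        return int(np.sum(self.groups == 2))


def _draw_loadings(spec: ModelSpec, rng: np.random.Generator) -> np.ndarray:
    mean = spec.hyper.loading_mean(spec.q)
    cov = spec.hyper.loading_cov(spec.q)
    z = rng.standard_normal((spec.p, spec.q))
    return mean + z @ np.linalg.cholesky(cov).T


def draw_inverse_gamma(shape: float, scale: float, rng: np.random.Generator,
                       size=None) -> np.ndarray | float:
    """Inverse-gamma variate(s) with mean scale/(shape-1) for shape > 1."""
    return 1.0 / rng.gamma(shape, 1.0 / scale, size=size)


def _standardize(C: np.ndarray) -> np.ndarray:
    sd = C.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (C - C.mean(axis=0)) / sd


def draw_prior_params(spec: ModelSpec, n: int, rng=None) -> ModelParams:
    """Draw one full parameter set (and n latent scores) from the priors.

    Loadings rows are MVN_q(mu_w, sigma_w), the noise variance is
    inverse-gamma(alpha1, alpha2), latent scores are standard Gaussian
    (PPCA), Gaussian around a covariate-dependent mean (PPCCA) or Gaussian
    with stochastic-volatility per-dimension variances (DPPCA).  The mean
    spectrum is fixed at zero: the per-bin test statistic is
    location-invariant, so a common mean cannot change a sample-size
    estimate.
    """
    if n < 4:
        raise DomainError(f"need n >= 4 (two per group at minimum), got n={n}")
    rng = as_rng(rng)
    W = _draw_loadings(spec, rng)
    sigma2 = float(draw_inverse_gamma(spec.hyper.alpha1, spec.hyper.alpha2, rng))
    coef = covariates = latent_sd = None
    if spec.model == "ppca":
        U = rng.standard_normal((n, spec.q))
    elif spec.model == "ppcca":
        covariates = _standardize(rng.standard_normal((n, spec.n_covariates)))
        design = np.column_stack([np.ones(n), covariates])
        coef = rng.normal(0.0, spec.hyper.coef_sd,
                          size=(spec.q, 1 + spec.n_covariates))
        U = design @ coef.T + rng.standard_normal((n, spec.q))
    else:  # dppca, first time point only
        h = rng.normal(spec.hyper.sv_mean, spec.hyper.sv_stationary_sd,
                       size=spec.q)
        latent_sd = np.exp(h / 2.0)
        U = rng.standard_normal((n, spec.q)) * latent_sd
    return ModelParams(W=W, mu=np.zeros(spec.p), sigma2=sigma2, U=U,
                       coef=coef, covariates=covariates, latent_sd=latent_sd,
                       source="prior_draw")


def _fresh_scores(params: ModelParams, spec: ModelSpec, n: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Latent scores for a fitted parameter set (fresh randomness per call)."""
    q = params.q
    if spec.model == "ppcca" and params.coef is not None:
        if params.covariates is not None and len(params.covariates):
            # resample covariate rows from the pilot's (standardized) values
            idx = rng.integers(0, params.covariates.shape[0], size=n)
            C = params.covariates[idx]
        else:
            C = rng.standard_normal((n, params.coef.shape[1] - 1))
        design = np.column_stack([np.ones(n), C])
        return design @ params.coef.T + rng.standard_normal((n, q))
    if spec.model == "dppca" and params.latent_sd is not None:
        return rng.standard_normal((n, q)) * params.latent_sd
    return rng.standard_normal((n, q))


def simulate_pilot(params: ModelParams, spec: ModelSpec, n1: int, n2: int,
                   rng=None) -> SpectralMatrix:
    """Simulate a two-group pilot spectral matrix from one parameter set.

    Row i is MVN_p(W u_i + mu, sigma2 I).  The first n1 rows are labelled
    group 1 and the rest group 2; the labels carry no signal — both groups
    are draws from the same marginal model.
    """
    if params.p != spec.p or params.q != spec.q:
        raise DimensionError(
            f"params of shape ({params.p}, {params.q}) do not match spec "
            f"({spec.p}, {spec.q})"
        )
    n = n1 + n2
    rng = as_rng(rng)
    if params.source == "prior_draw":
        if params.U is None or params.U.shape[0] != n:
            raise DimensionError(
                f"prior-drawn params carry {0 if params.U is None else params.U.shape[0]} "
                f"latent rows but n1+n2={n} were requested"
            )
        U = params.U
    else:
        U = _fresh_scores(params, spec, n, rng)
    noise = rng.standard_normal((n, spec.p)) * np.sqrt(params.sigma2)
    X = U @ params.W.T + params.mu + noise
    groups = np.repeat([1, 2], [n1, n2])
    return SpectralMatrix(X=X, groups=groups)


def fit_ppca_mle(X, q: int) -> ModelParams:
    """Closed-form PPCA maximum-likelihood fit via the sample covariance.

    The MLE coincides with classical PCA: with eigenpairs (lambda_j, v_j) of
    the (1/n-scaled) sample covariance, sigma2-hat is the mean of the p - q
    smallest eigenvalues and the loadings are the top-q eigenvectors scaled
    by sqrt(lambda_j - sigma2-hat).
    """
    Xmat = X.X if isinstance(X, SpectralMatrix) else np.asarray(X, dtype=float)
    n, p = Xmat.shape
    if q >= min(n - 1, p):
        raise DimensionError(
            f"q={q} must be < min(n-1, p) = {min(n - 1, p)}"
        )
    mu = Xmat.mean(axis=0)
    Xc = Xmat - mu
    # SVD route: eigenvalues of the covariance are singular values**2 / n
    _, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = sv**2 / n
    total_var = eigvals.sum()
    if total_var <= 1e-12:
        raise DegenerateDataError("data have zero variance; PPCA fit undefined")
    sigma2 = float((total_var - eigvals[:q].sum()) / (p - q))
    scale = np.sqrt(np.clip(eigvals[:q] - sigma2, 0.0, None))
    W = Vt[:q].T * scale
    return ModelParams(W=W, mu=mu, sigma2=max(sigma2, 0.0), source="mle_fit")


def _ppcca_loglik(Xc, W, sigma2, latent_mean):
    """Marginal log-likelihood of centered data given latent means."""
    n, p = Xc.shape
    q = W.shape[1]
    M = W.T @ W + sigma2 * np.eye(q)
    Minv = np.linalg.inv(M)
    logdet = (p - q) * np.log(sigma2) + np.linalg.slogdet(M)[1]
    R = Xc - latent_mean @ W.T
    RW = R @ W
    quad = (np.einsum("ij,ij->", R, R)
            - np.einsum("ij,jk,ik->", RW, Minv, RW)) / sigma2
    return -0.5 * (n * p * np.log(2 * np.pi) + n * logdet + quad)


def fit_ppcca_em(X: SpectralMatrix, covariates, q: int, tol: float = 1e-6,
                 max_iter: int = 1000) -> ModelParams:
    """EM fit of the PPCCA model (latent mean regressed on covariates).

    Covariates are standardized internally; with zero covariates the model
    collapses to PPCA and the EM converges to the closed-form MLE.
    Convergence is declared when the relative change in log-likelihood falls
    below ``tol``.
    """
    Xmat = X.X if isinstance(X, SpectralMatrix) else np.asarray(X, dtype=float)
    n, p = Xmat.shape
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            raise DimensionError("covariates must be row-aligned with X")
        C = _standardize(C)
    c = C.shape[1]
    if n <= q + c:
        raise DimensionError(f"need n > q + c = {q + c}, got n={n}")
    design = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn(
            "covariate design matrix is rank deficient (collinear columns); "
            "coefficient estimates are not unique",
            CollinearityWarning,
            stacklevel=2,
        )

    init = fit_ppca_mle(Xmat, q)
    W, sigma2 = init.W.copy(), max(init.sigma2, 1e-8)
    mu = init.mu.copy()
    B = np.zeros((q, 1 + c))
    Iq = np.eye(q)
    trace = []
    ll_old = -np.inf
    for _ in range(max_iter):
        Xc = Xmat - mu
        # E-step: posterior moments of the latent scores
        M = W.T @ W + sigma2 * Iq
        Minv = np.linalg.inv(M)
        latent_prior_mean = design @ B.T
        EU = (Xc @ W + sigma2 * latent_prior_mean) @ Minv
        Suu = n * sigma2 * Minv + EU.T @ EU
        # M-step
        mu = (Xmat - EU @ W.T).mean(axis=0)
        Xc = Xmat - mu
        W = np.linalg.solve(Suu, EU.T @ Xc).T
        B = np.linalg.solve(design.T @ design, design.T @ EU).T
        resid = Xc - EU @ W.T
        sigma2 = float(
            (np.einsum("ij,ij->", resid, resid)
             + n * sigma2 * np.trace(W.T @ W @ Minv)) / (n * p)
        )
        sigma2 = max(sigma2, 1e-12)
        ll = _ppcca_loglik(Xc, W, sigma2, design @ B.T)
        trace.append(ll)
        if np.isfinite(ll_old) and abs(ll - ll_old) <= tol * abs(ll_old):
            return ModelParams(W=W, mu=mu, sigma2=sigma2, coef=B,
                               covariates=C if c else None, source="mle_fit")
        ll_old = ll
    raise ConvergenceError(
        f"PPCCA EM did not converge in {max_iter} iterations "
        f"(last log-likelihood {trace[-1]:.6f})",
        loglik_trace=trace,
    )
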