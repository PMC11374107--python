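"""Synthetic case-control data with known truth and LOD censoring.

The generator emulates the structure of a population-based case-control
study of non-Hodgkin's lymphoma with household chemical exposures measured
in carpet dust: correlated lognormal concentrations (multivariate normal on
the log scale), heavy left-censoring at per-chemical detection limits, a
binary disease outcome from a logistic model with two-way interactions, and
a handful of adjustment covariates (study site, sex, education, age).

The ``nhl_like`` preset freezes the study conditions: n = 1180 subjects
with an expected 672 cases / 508 controls, p = 14 log-scale exposures with
one pair correlated above 0.9, below-LOD fractions spanning 3%-93% with
median 61%, and 4 covariates plus intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .designs import (
    CovariateMatrix,
    DesignBlocks,
    ExposureMatrix,
    build_design,
    interaction_pairs,
)
from .robit import sample_truncnorm_lower

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_exposures",
    "apply_lod_censoring",
    "simulate_outcome",
    "impute_below_lod",
    "make_nhl_like",
    "simulate_study",
]


def _exchangeable_corr(p: int, rho: float, high_pairs: list[tuple[int, int, float]]) -> np.ndarray:
    corr = np.full((p, p), rho)
    np.fill_diagonal(corr, 1.0)
    for j, k, r in high_pairs:
        corr[j, k] = corr[k, j] = r
    return corr


@dataclass
class SimulationConfig:
    """Generator truth for one synthetic study.

    Coefficients live on the logit scale in the stated ``parameterization``
    (``linear``, ``polynomial`` or ``lod``).  ``beta``/``gamma`` are dense
    vectors over the design's main/interaction columns (chemical-major /
    lexicographic pair order).  If ``target_case_fraction`` is set the
    intercept is tuned so the expected case fraction matches it.
    """

    n: int
    p: int
    corr: np.ndarray
    lod_fractions: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    parameterization: str = "linear"
    covariate_names: list[str] = field(default_factory=list)
    target_case_fraction: float | None = None

    def __post_init__(self) -> None:
        self.corr = np.asarray(self.corr, dtype=float)
        self.lod_fractions = np.asarray(self.lod_fractions, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.corr.shape != (self.p, self.p):
            raise ValueError("correlation matrix must be p x p")
        if np.any(self.lod_fractions < 0) or np.any(self.lod_fractions >= 1):
            raise ValueError("LOD fractions must lie in [0, 1)")
        try:
            np.linalg.cholesky(self.corr)
        except np.linalg.LinAlgError as err:
            raise ValueError("correlation matrix must be positive definite") from err

    @property
    def q(self) -> int:
        return self.alpha.shape[0]


@dataclass
class SimulatedStudy:
    """One realized study: censored exposures, covariates, outcome, truth.

    ``exposures`` carries the censored values (placeholder = detection limit)
    with flags; ``exposures_true`` retains the uncensored matrix so every
    subject's linear predictor can be recomputed exactly.
    """

    exposures: ExposureMatrix
    exposures_true: np.ndarray
    covariates: CovariateMatrix
    y: np.ndarray
    config: SimulationConfig
    intercept: float
    linear_predictor: np.ndarray


def simulate_exposures(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n i.i.d. multivariate-normal log-exposure rows and set limits.

    ``C_j`` is the empirical quantile of column ``j`` at the target below-LOD
    fraction; a fraction of 0 places the limit below the column minimum so
    nothing is censored.
    """
    L = np.linalg.cholesky(config.corr)
    X = rng.standard_normal((config.n, config.p)) @ L.T
    C = np.empty(config.p)
    for j in range(config.p):
        f = config.lod_fractions[j]
        if f == 0.0:
            C[j] = X[:, j].min() - 1.0
        else:
            C[j] = np.quantile(X[:, j], f)
    return X, C


def apply_lod_censoring(X: np.ndarray, C: np.ndarray, chem_names: list[str] | None = None) -> ExposureMatrix:
    """Flag cells below their detection limit and mask their magnitudes.

    Censored cells are set to the limit itself as a placeholder; downstream
    LOD designs never read them, and imputation replaces them.
    """
    X = np.asarray(X, dtype=float)
    C = np.asarray(C, dtype=float)
    if chem_names is None:
        chem_names = [f"chem{j+1}" for j in range(X.shape[1])]
    flags = X < C[None, :]
    censored = np.where(flags, C[None, :], X)
    return ExposureMatrix(
        values=censored, chem_names=chem_names, detect_limits=C.copy(), below_lod=flags
    )


def simulate_outcome(
    D: DesignBlocks,
    U: CovariateMatrix,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Bernoulli outcomes from the logistic model implied by the truth.

    Returns ``(y, intercept, linear_predictor)``; the intercept is tuned by
    root-finding when ``config.target_case_fraction`` is set (prospective
    emulation of case-control sampling — under a logit link the non-intercept
    coefficients are unaffected by outcome-dependent sampling).
    """
    base = (
        U.values[:, 1:] @ config.alpha[1:]
        + D.main @ config.beta
        + D.interaction @ config.gamma
    )
    if config.target_case_fraction is None:
        a0 = float(config.alpha[0])
    else:
        t = config.target_case_fraction

        def gap(a0: float) -> float:
            return float(np.mean(special.expit(a0 + base)) - t)

        a0 = float(optimize.brentq(gap, -30.0, 30.0))
    eta = a0 + base
    y = (rng.uniform(size=config.n) < special.expit(eta)).astype(int)
    return y, a0, eta


def _censored_normal_mle(obs: np.ndarray, n_cens: int, C: float) -> tuple[float, float]:
    """Column mean/SD by maximum likelihood under left-censoring at ``C``."""
    mu0, sd0 = float(obs.mean()), float(max(obs.std(), 1e-3))

    def nll(par: np.ndarray) -> float:
        mu, log_sd = par
        sd = np.exp(log_sd)
        ll = np.sum(stats.norm.logpdf(obs, mu, sd))
        if n_cens:
            ll += n_cens * stats.norm.logcdf(C, mu, sd)
        return -ll

    res = optimize.minimize(nll, x0=np.array([mu0, np.log(sd0)]), method="Nelder-Mead")
    mu, sd = float(res.x[0]), float(np.exp(res.x[1]))
    return mu, sd


def impute_below_lod(X: ExposureMatrix, rng: np.random.Generator) -> ExposureMatrix:
    """Single-realization lognormal tail imputation of censored cells.

    Per column, the normal mean/SD (log scale) are estimated by
    censored-normal maximum likelihood from the observed cells and the
    censored count, then each censored cell is replaced by one draw from
    that normal truncated to ``(-inf, C_j)``.  Columns with fewer than 10
    observed values are inestimable and rejected.
    """
    if X.below_lod is None or not X.below_lod.any():
        return X
    if X.detect_limits is None:
        raise ValueError("detection limits required to impute below-LOD cells")
    values = X.values.copy()
    for j in range(X.p):
        cens = X.below_lod[:, j]
        if not cens.any():
            continue
        obs = X.values[~cens, j]
        if obs.size < 10:
            raise ValueError(
                f"column {X.chem_names[j]} has only {obs.size} observed values; "
                "censored-normal MLE is inestimable"
            )
        C = float(X.detect_limits[j])
        mu, sd = _censored_normal_mle(obs, int(cens.sum()), C)
        # upper-truncated normal draw via the lower-truncated sampler (negate)
        a = -(C - mu) / sd
        z = sample_truncnorm_lower(np.full(int(cens.sum()), a), rng)
        values[cens, j] = mu - sd * z
    return ExposureMatrix(
        values=values,
        chem_names=list(X.chem_names),
        detect_limits=X.detect_limits.copy(),
        below_lod=np.zeros_like(X.below_lod),
    )


def _default_covariates(
    n: int, rng: np.random.Generator
) -> CovariateMatrix:
    """Site / sex / education / age analogues plus intercept."""
    site = rng.integers(0, 4, size=n).astype(float)  # 4 study centres
    sex = rng.integers(0, 2, size=n).astype(float)
    edu = rng.integers(0, 3, size=n).astype(float)
    age = rng.normal(60.0, 10.0, size=n)
    U = np.column_stack([np.ones(n), site, sex, edu, (age - 60.0) / 10.0])
    return CovariateMatrix(values=U, names=["intercept", "site", "sex", "education", "age"])


def simulate_study(config: SimulationConfig, seed: int | None = None) -> SimulatedStudy:
    """Generate one full study (exposures, censoring, covariates, outcome)."""
    rng = np.random.default_rng(seed)
    X_true, C = simulate_exposures(config, rng)
    X_cens = apply_lod_censoring(X_true, C)
    U = _default_covariates(config.n, rng)
    if U.q != config.q:
        raise ValueError(
            f"truth alpha has length {config.q} but covariates have {U.q} columns"
        )
    # the outcome is generated from the TRUE exposures
    X_for_design = ExposureMatrix(
        values=X_true,
        chem_names=list(X_cens.chem_names),
        detect_limits=C.copy(),
    )
    D = build_design(X_for_design, config.parameterization)
    y, a0, eta = simulate_outcome(D, U, config, rng)
    return SimulatedStudy(
        exposures=X_cens,
        exposures_true=X_true,
        covariates=U,
        y=y,
        config=config,
        intercept=a0,
        linear_predictor=eta,
    )


#: Below-LOD target fractions for the 14-chemical preset: range 3%-93%,
#: median (average of the 7th and 8th order statistics) exactly 61%.
NHL_LOD_FRACTIONS = np.array(
    [0.03, 0.10, 0.20, 0.30, 0.40, 0.50, 0.58, 0.64, 0.68, 0.72, 0.80, 0.85, 0.90, 0.93]
)


def make_nhl_like(seed: int | None = None) -> SimulatedStudy:
    """The frozen NHL-like preset: n = 1180, p = 14, q = 4 covariates + intercept.

    Exchangeable exposure correlation 0.3 with one pair (chem1, chem2) at
    0.95 to exercise the correlation filter; below-LOD fractions
    ``NHL_LOD_FRACTIONS``; truth (logit scale, linear parameterization) has
    two nonzero main effects (chem3: +0.5, chem5: -0.5) and one nonzero
    interaction (chem3:chem5 = +0.4); intercept tuned so the expected case
    fraction is 672/1180.
    """
    p = 14
    corr = _exchangeable_corr(p, 0.3, [(0, 1, 0.95)])
    pairs = interaction_pairs(p)
    beta = np.zeros(p)
    beta[2], beta[4] = 0.5, -0.5
    gamma = np.zeros(len(pairs))
    gamma[pairs.index((2, 4))] = 0.4
    alpha = np.array([0.0, 0.05, -0.2, -0.1, 0.1])  # intercept slot tuned at run time
    config = SimulationConfig(
        n=1180,
        p=p,
        corr=corr,
        lod_fractions=NHL_LOD_FRACTIONS,
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        parameterization="linear",
        target_case_fraction=672 / 1180,
    )
    return simulate_study(config, seed=seed)
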