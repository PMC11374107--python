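"""Robit-link data augmentation for approximate Bayesian logistic regression.

A binary regression with a robit(v) link — the Student-t CDF with ``v``
degrees of freedom — admits a latent-variable representation: each subject
carries a latent utility ``xi_i`` with ``Y_i = 1`` iff ``xi_i > 0``, and the
t error is a scale mixture of normals with a Gamma(v/2, v/2) mixing weight
``lambda_i``.  Conditionally on ``lambda``, everything is Gaussian, so a
Gibbs sampler alternates truncated-normal draws of ``xi``, conjugate gamma
draws of ``lambda``, and multivariate-normal coefficient draws.

With ``v = 7`` the robit link closely approximates the logit link: the
logistic distribution is nearly a t with 7 df scaled by 1.5484, so the
robit-scale coefficients equal the logit-scale (log odds ratio)
coefficients divided by 1.5484.  Posterior draws are reported on the logit
scale by undoing that division.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "ROBIT_LOGIT_SCALE",
    "DEFAULT_DF",
    "ModelSpec",
    "LatentState",
    "linear_predictor",
    "sample_truncnorm_lower",
    "sample_xi",
    "sample_lambda",
    "init_latent_state",
    "convert_to_logit_scale",
    "robit_logit_gap",
]

#: Calibration constant relating the robit(7) and logit coefficient scales:
#: robit = logit / 1.5484, i.e. logit = 1.5484 * robit.  (The logistic CDF is
#: closely matched by the CDF of 1.5484 times a t_7 variate.)
ROBIT_LOGIT_SCALE = 1.5484

#: Degrees of freedom for which the logit calibration holds.
DEFAULT_DF = 7.0

_PARAMETERIZATIONS = ("linear", "polynomial", "lod")


@dataclass
class ModelSpec:
    """Sampler configuration: link df, exposure parameterization, MCMC plan."""

    v: float = DEFAULT_DF
    parameterization: str = "linear"
    iterations: int = 10_000
    burn_in: int = 5_000
    thin: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.v <= 0:
            raise ValueError("degrees of freedom v must be positive")
        if self.parameterization == "poly":
            self.parameterization = "polynomial"
        if self.parameterization not in _PARAMETERIZATIONS:
            raise ValueError(f"unknown parameterization: {self.parameterization!r}")
        if not self.iterations > self.burn_in >= 0:
            raise ValueError("require iterations > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    def to_dict(self) -> dict:
        return {
            "v": self.v,
            "parameterization": self.parameterization,
            "iterations": self.iterations,
            "burn_in": self.burn_in,
            "thin": self.thin,
            "seed": self.seed,
        }


@dataclass
class LatentState:
    """Per-subject augmentation: latent utility ``xi`` and mixing weight ``lam``."""

    xi: np.ndarray
    lam: np.ndarray

    def check_signs(self, y: np.ndarray) -> bool:
        """Sign invariant: ``xi_i > 0`` exactly where ``Y_i = 1``."""
        y = np.asarray(y)
        return bool(np.all((self.xi > 0) == (y == 1)) and np.all(self.lam > 0))


def linear_predictor(
    U: np.ndarray,
    D,
    alpha: np.ndarray,
    beta: np.ndarray,
    gamma: np.ndarray,
) -> np.ndarray:
    """``m_i = U_i'alpha + X_i'beta + Z_i'gamma`` for DesignBlocks ``D``."""
    U = np.asarray(U, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if U.shape[1] != alpha.shape[0]:
        raise ValueError("alpha length does not match covariate columns")
    if D.main.shape[1] != beta.shape[0]:
        raise ValueError("beta length does not match main-effect columns")
    if D.interaction.shape[1] != gamma.shape[0]:
        raise ValueError("gamma length does not match interaction columns")
    return U @ alpha + D.main @ beta + D.interaction @ gamma


def sample_truncnorm_lower(a: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Standard-normal draws truncated to ``[a_i, inf)``, robust in far tails.

    Body (``a <= 30``): inverse survival function, ``x = -ndtri(u * Phi(-a))``,
    which keeps full precision however deep the truncation because it works on
    the upper-tail probability directly.  Far tail (``a > 30``, where
    ``Phi(-a)`` underflows): Robert's exponential-proposal rejection sampler.
    """
    a = np.asarray(a, dtype=float)
    out = np.empty_like(a)
    body = a <= 30.0
    if body.any():
        ab = a[body]
        u = rng.uniform(size=ab.shape)
        out[body] = -special.ndtri(u * special.ndtr(-ab))
    tail = ~body
    if tail.any():
        at = a[tail]
        lam = 0.5 * (at + np.sqrt(at * at + 4.0))
        x = np.empty_like(at)
        todo = np.ones(at.shape, dtype=bool)
        while todo.any():
            prop = at[todo] + rng.exponential(size=int(todo.sum())) / lam[todo]
            acc = rng.uniform(size=prop.shape) <= np.exp(-0.5 * (prop - lam[todo]) ** 2)
            idx = np.flatnonzero(todo)[acc]
            x[idx] = prop[acc]
            todo[idx] = False
        out[tail] = x
    return out


def sample_xi(
    y: np.ndarray, m: np.ndarray, lam: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One draw of the latent utilities.

    ``xi_i ~ N(m_i, 1/lam_i)`` truncated to ``(0, inf)`` when ``Y_i = 1`` and
    to ``(-inf, 0]`` when ``Y_i = 0``.
    """
    y = np.asarray(y)
    m = np.asarray(m, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("non-finite linear predictor")
    if np.any(lam <= 0):
        raise ValueError("mixing weights must be positive")
    sd = 1.0 / np.sqrt(lam)
    # standardized lower bound for the side being sampled (sign-flip for Y=0)
    a = np.where(y == 1, -m, m) / sd
    z = sample_truncnorm_lower(a, rng)
    xi = np.where(y == 1, m + sd * z, m - sd * z)
    # guard the measure-zero boundary so the sign invariant is exact
    xi = np.where((y == 1) & (xi <= 0), np.finfo(float).tiny, xi)
    xi = np.where((y == 0) & (xi > 0), 0.0, xi)
    return xi


def sample_lambda(
    xi: np.ndarray, m: np.ndarray, v: float, rng: np.random.Generator
) -> np.ndarray:
    """Conjugate update of the scale-mixture weights.

    ``lam_i ~ Gamma(shape=(v+1)/2, rate=(v + (xi_i - m_i)^2)/2)``; the prior
    Gamma(v/2, v/2) has mean 1, and as ``v -> inf`` the draws concentrate at 1
    (the probit limit).
    """
    resid = np.asarray(xi, dtype=float) - np.asarray(m, dtype=float)
    shape = 0.5 * (v + 1.0)
    rate = 0.5 * (v + resid**2)
    return rng.gamma(shape, 1.0 / rate)


def init_latent_state(y: np.ndarray, rng: np.random.Generator) -> LatentState:
    """Initial state: ``lam = 1`` and one truncation-respecting xi draw at m = 0."""
    y = np.asarray(y)
    lam = np.ones(y.shape[0])
    xi = sample_xi(y, np.zeros(y.shape[0]), lam, rng)
    return LatentState(xi=xi, lam=lam)


def convert_to_logit_scale(coeffs: np.ndarray, v: float = DEFAULT_DF) -> np.ndarray:
    """Map robit(v)-scale regression coefficients to the logit scale (v = 7 only).

    The robit(7) coefficients are the logit coefficients divided by the
    calibration constant 1.5484, so the conversion multiplies by it; the
    result is interpretable as a log odds ratio.  The constant is specific
    to seven degrees of freedom; any other ``v`` raises, since no conversion
    is calibrated for it.  Shrinkage parameters are scale parameters, not
    regression coefficients, and must not be passed through this function.
    """
    if v != DEFAULT_DF:
        raise ValueError(
            f"logit-scale conversion is calibrated for v=7 only (got v={v})"
        )
    return np.asarray(coeffs, dtype=float) * ROBIT_LOGIT_SCALE


def robit_logit_gap(
    v: float = DEFAULT_DF,
    scale: float = ROBIT_LOGIT_SCALE,
    grid: np.ndarray | None = None,
) -> float:
    """Sup-norm gap between the logistic CDF and the scaled t_v CDF.

    Diagnostic for the quality of the robit(v)/logit approximation: evaluates
    ``max_x |expit(x) - F_t(x / scale; v)|`` over ``grid`` (default: a dense
    grid spanning [-10, 10]).
    """
    from scipy import stats

    if grid is None:
        grid = np.linspace(-10.0, 10.0, 4001)
    grid = np.asarray(grid, dtype=float)
    if grid.min() > -10.0 or grid.max() < 10.0:
        raise ValueError("evaluation grid must span at least [-10, 10]")
    return float(np.max(np.abs(special.expit(grid) - stats.t.cdf(grid / scale, df=v))))
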