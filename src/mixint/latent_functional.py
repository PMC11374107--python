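"""Latent-functional interaction model with separate main/interaction classes.

Each chemical's dose-response contribution is one of ``L`` shared latent
polynomial functions ``f_l(x) = beta_l1 x + ... + beta_lc x^c`` and each
pairwise interaction variable ``Z_k = X_j1 X_j2`` contributes one of ``M``
shared functions ``s_m(z)``; membership indicators ``g_j`` (over chemicals)
and ``h_k`` (over pairs) carry categorical priors with Dirichlet-distributed
mixture weights ``omega`` and ``psi``.  The binary outcome uses the robit(7)
latent-utility representation, so the sampler is fully conjugate given the
scale-mixture weights.

Complex exposure relationships can usually be captured with very few
distinct functions, so when the truth uses only a couple of classes the
extra classes end up essentially unoccupied.

Label switching: draws are stored unrelabelled.  Table-style summaries sort
within iteration (descending) before averaging, and risk curves are built
from the label-invariant effective coefficients ``delta_j = beta_{g_j}``, so
neither is affected by relabelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .designs import (
    CovariateMatrix,
    ExposureMatrix,
    ScalingRecord,
    build_linear_design,
    standardize_for_latentfun,
)
from .robit import (
    ROBIT_LOGIT_SCALE,
    init_latent_state,
    sample_lambda,
    sample_xi,
)
from .shrinkage import sample_coefficients
from .summaries import hpd_interval

__all__ = [
    "LatentClassConfig",
    "ClassAssignments",
    "ClassCoefficients",
    "LatentFunDraws",
    "sample_membership",
    "sample_weights",
    "sample_class_coefficients",
    "run_latentfun_mcmc",
    "class_probability_table",
    "risk_curves",
]


@dataclass
class LatentClassConfig:
    """Latent-class counts, polynomial order and MCMC plan.

    ``L`` main-effect classes (1 <= L <= p), ``M`` interaction classes
    (1 <= M <= K), polynomial order ``c`` (cubic by default).  Class
    coefficients and covariate effects carry independent N(0, prior_sd^2)
    priors; the weights carry symmetric Dirichlet(dirichlet_conc) priors.
    """

    L: int
    M: int
    c: int = 3
    v: float = 7.0
    prior_sd: float = 10.0
    dirichlet_conc: float = 1.0
    iterations: int = 4000
    burn_in: int = 2000
    thin: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.L < 1 or self.M < 1:
            raise ValueError("L and M must be at least 1")
        if self.c < 1:
            raise ValueError("polynomial order c must be >= 1")
        if not self.iterations > self.burn_in >= 0:
            raise ValueError("require iterations > burn_in >= 0")


@dataclass
class ClassAssignments:
    """Current labels and mixture weights."""

    g: np.ndarray  # length p, values in 0..L-1
    h: np.ndarray  # length K, values in 0..M-1
    omega: np.ndarray
    psi: np.ndarray


@dataclass
class ClassCoefficients:
    """Current class polynomial coefficients and covariate effects."""

    beta: np.ndarray  # (L, c)
    gamma: np.ndarray  # (M, c)
    alpha: np.ndarray  # (q,)


def sample_weights(
    counts: np.ndarray, rng: np.random.Generator, conc: float = 1.0
) -> np.ndarray:
    """Dirichlet(conc + counts) draw of a simplex weight vector."""
    counts = np.asarray(counts, dtype=float)
    return rng.dirichlet(conc + counts)


def sample_class_coefficients(
    member_blocks: list[np.ndarray],
    resid: np.ndarray,
    lam: np.ndarray,
    prior_sd: float,
    rng: np.random.Generator,
    c: int | None = None,
) -> np.ndarray:
    """Draw one class's polynomial coefficients from their full conditional.

    All members of a class share one coefficient vector and their
    contributions add inside each subject's latent utility, so the pooled
    design is the elementwise SUM of the members' n x c blocks.  An empty
    class draws from the prior, keeping the chain irreducible across
    assignments.
    """
    if not member_blocks:
        if c is None:
            raise ValueError("c required to draw an empty class from the prior")
        return rng.normal(0.0, prior_sd, size=c)
    S = member_blocks[0].copy()
    for blk in member_blocks[1:]:
        S = S + blk
    prior_prec = np.full(S.shape[1], 1.0 / prior_sd**2)
    return sample_coefficients(resid, lam, S, prior_prec, rng)


def sample_membership(
    unit_block: np.ndarray,
    resid: np.ndarray,
    lam: np.ndarray,
    class_coefs: np.ndarray,
    weights: np.ndarray,
    rng: np.random.Generator,
) -> int:
    """Categorical draw of one unit's class label.

    ``resid`` excludes the unit's own contribution.  The log-probabilities
    ``log w_l - 0.5 sum_i lam_i (resid_i - B_i' coef_l)^2`` are normalized by
    max-subtraction in the log domain.
    """
    G = unit_block.T @ (unit_block * lam[:, None])  # c x c weighted Gram
    cross = unit_block.T @ (lam * resid)  # length c
    # quadratic part of -0.5 * SSR_l (the resid^2 term is label-constant)
    quad = -0.5 * np.einsum("lc,cd,ld->l", class_coefs, G, class_coefs)
    with np.errstate(divide="ignore"):
        logp = np.log(weights) + class_coefs @ cross + quad
    if np.all(np.isneginf(logp)):
        raise RuntimeError("all class log-probabilities are -inf")
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    return int(rng.choice(class_coefs.shape[0], p=prob))


def _poly_blocks(cols: np.ndarray, c: int) -> np.ndarray:
    """(units, n, c) array of polynomial blocks (x, x^2, ..., x^c) per column."""
    n, u = cols.shape
    out = np.empty((u, n, c))
    for j in range(u):
        x = cols[:, j]
        out[j, :, 0] = x
        for d in range(1, c):
            out[j, :, d] = out[j, :, d - 1] * x
    return out


@dataclass
class LatentFunDraws:
    """Per-iteration draws of the latent-functional sampler, with provenance."""

    alpha: np.ndarray  # (S, q)
    beta: np.ndarray  # (S, L, c)
    gamma: np.ndarray  # (S, M, c)
    g: np.ndarray  # (S, p) int labels
    h: np.ndarray  # (S, K) int labels
    omega: np.ndarray  # (S, L)
    psi: np.ndarray  # (S, M)
    config: LatentClassConfig
    scaling: ScalingRecord
    chem_names: list[str]
    pairs: list[tuple[int, int]]
    covariate_names: list[str]
    x_range: np.ndarray  # (p, 2) observed range of raw main columns
    z_range: np.ndarray  # (K, 2) observed range of raw interaction variables

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[0]

    def effective_main_coefficients(self) -> np.ndarray:
        """(S, p, c) effective delta_j = beta_{g_j}, label-invariant."""
        return np.take_along_axis(self.beta, self.g[:, :, None], axis=1)

    def effective_interaction_coefficients(self) -> np.ndarray:
        """(S, K, c) effective delta_k = gamma_{h_k}, label-invariant."""
        return np.take_along_axis(self.gamma, self.h[:, :, None], axis=1)


def run_latentfun_mcmc(
    y: np.ndarray,
    X: ExposureMatrix,
    U: CovariateMatrix,
    config: LatentClassConfig,
) -> LatentFunDraws:
    """Full Gibbs scan of the latent-functional model.

    Scan order: xi, lambda, alpha, class coefficients (main then
    interaction), memberships g then h, weights omega then psi.  Main and
    interaction variables are standardized by their column maxima BEFORE
    powers are taken (the scaled variable is raised to 1..c); covariates are
    centred and scaled to unit SD.  Deterministic given ``config.seed``.
    """
    y = np.asarray(y)
    p = X.p
    if not 1 <= config.L <= p:
        raise ValueError("require 1 <= L <= p")
    D_lin = build_linear_design(X)
    K = D_lin.K
    if not 1 <= config.M <= max(K, 1):
        raise ValueError("require 1 <= M <= K")
    Ds, Us, scaling = standardize_for_latentfun(D_lin, U)
    x_range = np.column_stack([D_lin.main.min(axis=0), D_lin.main.max(axis=0)])
    z_range = (
        np.column_stack([D_lin.interaction.min(axis=0), D_lin.interaction.max(axis=0)])
        if K
        else np.empty((0, 2))
    )
    c = config.c
    Wx = _poly_blocks(Ds.main, c)  # (p, n, c)
    Wz = _poly_blocks(Ds.interaction, c) if K else np.empty((0, len(y), c))
    Uv = Us.values
    q = Us.q

    rng = np.random.default_rng(config.seed)
    L, M = config.L, config.M
    lat = init_latent_state(y, rng)
    coefs = ClassCoefficients(
        beta=np.zeros((L, c)), gamma=np.zeros((M, c)), alpha=np.zeros(q)
    )
    assign = ClassAssignments(
        g=rng.integers(0, L, size=p),
        h=rng.integers(0, M, size=K),
        omega=np.full(L, 1.0 / L),
        psi=np.full(M, 1.0 / M),
    )

    def main_contrib() -> np.ndarray:
        out = np.zeros(len(y))
        for j in range(p):
            out += Wx[j] @ coefs.beta[assign.g[j]]
        return out

    def inter_contrib() -> np.ndarray:
        out = np.zeros(len(y))
        for k in range(K):
            out += Wz[k] @ coefs.gamma[assign.h[k]]
        return out

    kept = (config.iterations - config.burn_in) // config.thin
    store = {
        "alpha": np.empty((kept, q)),
        "beta": np.empty((kept, L, c)),
        "gamma": np.empty((kept, M, c)),
        "g": np.empty((kept, p), dtype=int),
        "h": np.empty((kept, K), dtype=int),
        "omega": np.empty((kept, L)),
        "psi": np.empty((kept, M)),
    }
    alpha_prec = np.full(q, 1.0 / 100.0)
    s = 0
    for it in range(config.iterations):
        mc, ic = main_contrib(), inter_contrib()
        m = Uv @ coefs.alpha + mc + ic
        lat.xi = sample_xi(y, m, lat.lam, rng)
        lat.lam = sample_lambda(lat.xi, m, config.v, rng)

        coefs.alpha = sample_coefficients(lat.xi - mc - ic, lat.lam, Uv, alpha_prec, rng)
        cov_part = Uv @ coefs.alpha

        # class coefficients: residual excludes the class's own contribution
        for l in range(L):
            members = [j for j in range(p) if assign.g[j] == l]
            mc = main_contrib()
            own = np.zeros(len(y))
            for j in members:
                own += Wx[j] @ coefs.beta[l]
            resid = lat.xi - cov_part - ic - (mc - own)
            coefs.beta[l] = sample_class_coefficients(
                [Wx[j] for j in members], resid, lat.lam, config.prior_sd, rng, c=c
            )
        mc = main_contrib()
        for mcl in range(M):
            members = [k for k in range(K) if assign.h[k] == mcl]
            ic = inter_contrib()
            own = np.zeros(len(y))
            for k in members:
                own += Wz[k] @ coefs.gamma[mcl]
            resid = lat.xi - cov_part - mc - (ic - own)
            coefs.gamma[mcl] = sample_class_coefficients(
                [Wz[k] for k in members], resid, lat.lam, config.prior_sd, rng, c=c
            )
        ic = inter_contrib()

        # memberships, one unit at a time with an up-to-date residual
        for j in range(p):
            mc -= Wx[j] @ coefs.beta[assign.g[j]]
            resid = lat.xi - cov_part - ic - mc
            assign.g[j] = sample_membership(
                Wx[j], resid, lat.lam, coefs.beta, assign.omega, rng
            )
            mc += Wx[j] @ coefs.beta[assign.g[j]]
        for k in range(K):
            ic -= Wz[k] @ coefs.gamma[assign.h[k]]
            resid = lat.xi - cov_part - mc - ic
            assign.h[k] = sample_membership(
                Wz[k], resid, lat.lam, coefs.gamma, assign.psi, rng
            )
            ic += Wz[k] @ coefs.gamma[assign.h[k]]

        assign.omega = sample_weights(
            np.bincount(assign.g, minlength=L), rng, config.dirichlet_conc
        )
        if K:
            assign.psi = sample_weights(
                np.bincount(assign.h, minlength=M), rng, config.dirichlet_conc
            )

        if not (np.all(np.isfinite(coefs.beta)) and np.all(np.isfinite(coefs.alpha))):
            raise RuntimeError(f"non-finite sampler state at iteration {it}")
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            store["alpha"][s] = coefs.alpha
            store["beta"][s] = coefs.beta
            store["gamma"][s] = coefs.gamma
            store["g"][s] = assign.g
            store["h"][s] = assign.h
            store["omega"][s] = assign.omega
            store["psi"][s] = assign.psi
            s += 1

    return LatentFunDraws(
        alpha=store["alpha"][:s],
        beta=store["beta"][:s],
        gamma=store["gamma"][:s],
        g=store["g"][:s],
        h=store["h"][:s],
        omega=store["omega"][:s],
        psi=store["psi"][:s],
        config=config,
        scaling=scaling,
        chem_names=list(X.chem_names),
        pairs=list(D_lin.pairs),
        covariate_names=list(U.names),
        x_range=x_range,
        z_range=z_range,
    )


def class_probability_table(draws: LatentFunDraws) -> pd.DataFrame:
    """Posterior class-probability table (one row per class rank).

    Two label-invariant summaries per class set, both computed after sorting
    within each iteration in descending order:

    * ``omega`` / ``psi`` — mean sorted class-occupancy fractions (the share
      of chemicals / pairs assigned to each class), which go to ~0 for
      unused classes;
    * ``omega_weight`` / ``psi_weight`` — mean sorted Dirichlet mixture
      weights, whose posterior means for an unused class cannot drop below
      conc / (p + L * conc) by construction.

    Sorting a simplex biases a symmetric truth (e.g. a balanced two-class
    generator cannot show (0.5, 0.5)); this is documented behaviour.
    """
    L, M = draws.config.L, draws.config.M
    p, K = len(draws.chem_names), len(draws.pairs)
    occ_g = np.stack([np.bincount(row, minlength=L) / p for row in draws.g])
    occ_h = (
        np.stack([np.bincount(row, minlength=M) / K for row in draws.h])
        if K
        else np.zeros((draws.n_draws, M))
    )
    rows = max(L, M)
    table = pd.DataFrame({"class": np.arange(1, rows + 1)})

    def _sorted_mean(arr: np.ndarray, rows: int) -> np.ndarray:
        srt = -np.sort(-arr, axis=1)
        out = np.full(rows, np.nan)
        out[: srt.shape[1]] = srt.mean(axis=0)
        return out

    table["omega"] = _sorted_mean(occ_g, rows)
    table["psi"] = _sorted_mean(occ_h, rows)
    table["omega_weight"] = _sorted_mean(draws.omega, rows)
    table["psi_weight"] = _sorted_mean(draws.psi, rows)
    return table


def risk_curves(
    draws: LatentFunDraws,
    kind: str,
    index: int,
    grid: np.ndarray,
    level: float = 0.95,
) -> pd.DataFrame:
    """Posterior log relative risk relative to no exposure along ``grid``.

    For a main effect (``kind='main'``, chemical index ``j``) the drawn
    effective function is ``f(x) = sum_d delta_jd (x / s_j)^d`` with ``s_j``
    the stored column maximum; the curve is ``f(x) - f(0)`` per draw,
    rescaled by the robit(7)-to-logit calibration constant to land on the
    logit (log odds ratio ~ log relative risk) scale, then summarized by
    the posterior mean and HPD bounds.
    ``kind='interaction'`` does the same for the pair variable
    ``Z_k = X_j1 X_j2``.
    """
    grid = np.asarray(grid, dtype=float)
    if kind == "main":
        delta = draws.effective_main_coefficients()[:, index, :]  # (S, c)
        scale = draws.scaling.main_scale[index]
        lo, hi = draws.x_range[index]
    elif kind == "interaction":
        delta = draws.effective_interaction_coefficients()[:, index, :]
        scale = draws.scaling.interaction_scale[index]
        lo, hi = draws.z_range[index]
    else:
        raise ValueError("kind must be 'main' or 'interaction'")
    if grid.min() < lo or grid.max() > hi:
        warnings.warn(
            "grid extends outside the observed exposure range (extrapolation)",
            stacklevel=2,
        )
    xs = grid / scale
    c = delta.shape[1]
    powers = np.stack([xs**d for d in range(1, c + 1)], axis=1)  # (G, c)
    curves = (delta @ powers.T) * ROBIT_LOGIT_SCALE  # (S, G); f(0) = 0 exactly
    rows = []
    for gidx, x in enumerate(grid):
        col = curves[:, gidx]
        lo_h, hi_h = hpd_interval(col) if col.std() > 0 else (float(col[0]), float(col[0]))
        rows.append(
            {"grid": x, "mean": float(col.mean()), "lower": lo_h, "upper": hi_h}
        )
    return pd.DataFrame(rows)
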