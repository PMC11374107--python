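"""Gibbs samplers for robit regression under vague and global-local priors.

Three prior regimes over the regression coefficients (alpha, beta, gamma):

* ``vague``       — N(0, 10^2) on every coefficient; approximately maximum
  likelihood.
* ``independent`` — global-local shrinkage, beta_j ~ N(0, 1/(a eta_j)) and
  gamma_jk ~ N(0, 1/(b theta_jk)) with G(1,1) hyperpriors on every scale.
* ``shared``      — the hierarchical (heredity) variant: the interaction
  precision borrows both parents' local scales,
  gamma_jk ~ N(0, 1/(b eta_j eta_k theta_jk)), so an interaction is shrunk
  hard whenever either parent main effect is.

Covariate coefficients alpha always carry the vague N(0, 10^2) prior.  For
vector-valued blocks (polynomial and LOD parameterizations, block dimensions
2 and 4) one local scale is shared by all components of a block.

All full conditionals are conjugate: a joint multivariate-normal draw for the
coefficients and gamma draws for every shrinkage scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .designs import CovariateMatrix, DesignBlocks, ExposureMatrix, build_design
from .robit import (
    ModelSpec,
    convert_to_logit_scale,
    init_latent_state,
    sample_lambda,
    sample_xi,
)

__all__ = [
    "PriorSpec",
    "ShrinkState",
    "PosteriorDraws",
    "sample_coefficients",
    "sample_eta_independent",
    "sample_eta_shared",
    "sample_theta",
    "sample_globals",
    "eta_independent_params",
    "eta_shared_params",
    "theta_params",
    "globals_params",
    "gibbs_sweep",
    "run_mcmc",
]

_KINDS = ("vague", "independent", "shared")


@dataclass
class PriorSpec:
    """Prior regime and hyperparameters.

    ``gamma_hyper`` holds the (shape, rate) pairs of the G(1, 1) hyperpriors
    on the local scales eta/theta and globals a/b; the defaults give each a
    heavy-tailed prior with mean and variance 1.
    """

    kind: str = "shared"
    vague_sd: float = 10.0
    gamma_hyper: dict = field(
        default_factory=lambda: {
            "eta": (1.0, 1.0),
            "theta": (1.0, 1.0),
            "a": (1.0, 1.0),
            "b": (1.0, 1.0),
        }
    )

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown prior kind: {self.kind!r}")
        if self.vague_sd <= 0:
            raise ValueError("vague_sd must be positive")
        for key, (c1, c2) in self.gamma_hyper.items():
            if c1 <= 0 or c2 <= 0:
                raise ValueError(f"hyperparameters for {key} must be positive")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "vague_sd": self.vague_sd, "gamma_hyper": dict(self.gamma_hyper)}


@dataclass
class ShrinkState:
    """Current local (eta, theta) and global (a, b) shrinkage scales."""

    eta: np.ndarray
    theta: np.ndarray
    a: float = 1.0
    b: float = 1.0

    def check_positive(self) -> bool:
        return bool(np.all(self.eta > 0) and np.all(self.theta > 0) and self.a > 0 and self.b > 0)


def sample_coefficients(
    xi: np.ndarray,
    lam: np.ndarray,
    W: np.ndarray,
    prior_prec: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Joint multivariate-normal draw of all regression coefficients.

    The full conditional has precision ``Q = W' diag(lam) W + diag(prior_prec)``
    and mean ``Q^{-1} W' diag(lam) xi``.
    """
    if np.any(lam <= 0):
        raise ValueError("mixing weights must be positive")
    Wl = W * lam[:, None]
    Q = W.T @ Wl + np.diag(prior_prec)
    rhs = Wl.T @ xi
    try:
        cho = linalg.cho_factor(Q, lower=True)
    except linalg.LinAlgError as err:
        raise ValueError(
            "singular coefficient precision (collinear columns with zero prior "
            "precision)"
        ) from err
    piv = np.diag(cho[0])
    # pivot ratio ~ sqrt(cond(Q)); sqrt(eps)-scale pivots mean rank deficiency
    if piv.min() <= piv.max() * 1e-7:
        raise ValueError(
            "singular coefficient precision (collinear columns with zero prior "
            "precision)"
        )
    mean = linalg.cho_solve(cho, rhs)
    z = rng.standard_normal(W.shape[1])
    # Q = L L'  =>  draw = mean + L^{-T} z has covariance Q^{-1}
    draw = mean + linalg.solve_triangular(cho[0], z, lower=True, trans="T")
    return draw


def eta_independent_params(
    beta_j: np.ndarray, a: float, hyper: tuple[float, float] = (1.0, 1.0)
) -> tuple[float, float]:
    """(shape, rate) of the eta_j full conditional under a per-block prior."""
    beta_j = np.atleast_1d(beta_j)
    c1, c2 = hyper
    return c1 + beta_j.size / 2.0, c2 + 0.5 * a * float(beta_j @ beta_j)


def sample_eta_independent(
    beta_j: np.ndarray,
    a: float,
    rng: np.random.Generator,
    hyper: tuple[float, float] = (1.0, 1.0),
) -> float:
    """Conjugate update of a main-effect local scale under either shrinkage prior.

    eta_j | beta_j, a ~ Gamma(c1 + d/2, c2 + a ||beta_j||^2 / 2) where d is
    the block dimension.  Larger eta means stronger shrinkage, so big
    coefficients pull eta (and hence shrinkage) down.
    """
    shape, rate = eta_independent_params(beta_j, a, hyper)
    return float(rng.gamma(shape, 1.0 / rate))


def sample_theta(
    gamma_jk: np.ndarray,
    b: float,
    eta_j: float,
    eta_k: float,
    kind: str,
    rng: np.random.Generator,
    hyper: tuple[float, float] = (1.0, 1.0),
) -> float:
    """Conjugate update of an interaction local scale.

    theta_jk ~ Gamma(c1 + d/2, c2 + b s ||gamma_jk||^2 / 2) with s = 1 under
    the independent prior and s = eta_j eta_k under the shared prior.
    """
    shape, rate = theta_params(gamma_jk, b, eta_j, eta_k, kind, hyper)
    return float(rng.gamma(shape, 1.0 / rate))


def theta_params(
    gamma_jk: np.ndarray,
    b: float,
    eta_j: float,
    eta_k: float,
    kind: str,
    hyper: tuple[float, float] = (1.0, 1.0),
) -> tuple[float, float]:
    """(shape, rate) of the theta_jk full conditional."""
    gamma_jk = np.atleast_1d(gamma_jk)
    s = eta_j * eta_k if kind == "shared" else 1.0
    c1, c2 = hyper
    return c1 + gamma_jk.size / 2.0, c2 + 0.5 * b * s * float(gamma_jk @ gamma_jk)


def sample_eta_shared(
    j: int,
    beta_j: np.ndarray,
    gammas_j: list[np.ndarray],
    partner_etas: np.ndarray,
    thetas_j: np.ndarray,
    a: float,
    b: float,
    rng: np.random.Generator,
    hyper: tuple[float, float] = (1.0, 1.0),
) -> float:
    """Update of eta_j under the shared (heredity) prior.

    eta_j enters its own main-effect block and all p-1 interaction blocks
    containing chemical j, so the gamma update pools all of them:
    shape = c1 + (d_beta + (p-1) d_gamma)/2,
    rate  = c2 + a ||beta_j||^2/2 + (b/2) sum_k eta_k theta_jk ||gamma_jk||^2.
    """
    shape, rate = eta_shared_params(
        beta_j, gammas_j, partner_etas, thetas_j, a, b, hyper
    )
    return float(rng.gamma(shape, 1.0 / rate))


def eta_shared_params(
    beta_j: np.ndarray,
    gammas_j: list[np.ndarray],
    partner_etas: np.ndarray,
    thetas_j: np.ndarray,
    a: float,
    b: float,
    hyper: tuple[float, float] = (1.0, 1.0),
) -> tuple[float, float]:
    """(shape, rate) of the eta_j full conditional under the shared prior."""
    beta_j = np.atleast_1d(beta_j)
    c1, c2 = hyper
    dims = beta_j.size + sum(g.size for g in gammas_j)
    rate = c2 + 0.5 * a * float(beta_j @ beta_j)
    for g, eta_k, th in zip(gammas_j, partner_etas, thetas_j):
        rate += 0.5 * b * eta_k * th * float(g @ g)
    return c1 + dims / 2.0, rate


def sample_globals(
    beta_blocks: list[np.ndarray],
    gamma_blocks: list[np.ndarray],
    eta: np.ndarray,
    theta: np.ndarray,
    pairs: list[tuple[int, int]],
    kind: str,
    rng: np.random.Generator,
    hyper_a: tuple[float, float] = (1.0, 1.0),
    hyper_b: tuple[float, float] = (1.0, 1.0),
) -> tuple[float, float]:
    """Conjugate updates of the global shrinkage scales.

    a ~ Gamma(c1 + p d_beta/2, c2 + sum_j eta_j ||beta_j||^2 / 2);
    b ~ Gamma(c1 + K d_gamma/2, c2 + sum_jk s_jk theta_jk ||gamma_jk||^2 / 2)
    with s_jk = eta_j eta_k under the shared prior, 1 otherwise.
    """
    (shape_a, rate_a), (shape_b, rate_b) = globals_params(
        beta_blocks, gamma_blocks, eta, theta, pairs, kind, hyper_a, hyper_b
    )
    a = float(rng.gamma(shape_a, 1.0 / rate_a))
    b = float(rng.gamma(shape_b, 1.0 / rate_b))
    return a, b


def globals_params(
    beta_blocks: list[np.ndarray],
    gamma_blocks: list[np.ndarray],
    eta: np.ndarray,
    theta: np.ndarray,
    pairs: list[tuple[int, int]],
    kind: str,
    hyper_a: tuple[float, float] = (1.0, 1.0),
    hyper_b: tuple[float, float] = (1.0, 1.0),
) -> tuple[tuple[float, float], tuple[float, float]]:
    """((shape_a, rate_a), (shape_b, rate_b)) of the global full conditionals."""
    c1a, c2a = hyper_a
    shape_a = c1a + sum(bj.size for bj in beta_blocks) / 2.0
    rate_a = c2a + 0.5 * sum(
        eta[j] * float(bj @ bj) for j, bj in enumerate(beta_blocks)
    )
    c1b, c2b = hyper_b
    shape_b = c1b + sum(g.size for g in gamma_blocks) / 2.0
    rate_b = c2b
    for k, (gj, gk) in enumerate(pairs):
        s = eta[gj] * eta[gk] if kind == "shared" else 1.0
        rate_b += 0.5 * s * theta[k] * float(gamma_blocks[k] @ gamma_blocks[k])
    return (shape_a, rate_a), (shape_b, rate_b)


# ---------------------------------------------------------------------------
# Full sampler


class _Partition:
    """Column bookkeeping for W = [U | main | interaction]."""

    def __init__(self, q: int, D: DesignBlocks):
        self.q = q
        self.D = D
        self.n_main = D.main.shape[1]
        self.n_inter = D.interaction.shape[1]
        self.alpha = slice(0, q)
        self.beta = slice(q, q + self.n_main)
        self.gamma = slice(q + self.n_main, q + self.n_main + self.n_inter)
        self.size = q + self.n_main + self.n_inter

    def beta_block(self, coef: np.ndarray, j: int) -> np.ndarray:
        base = self.q + j * self.D.d_beta
        return coef[base : base + self.D.d_beta]

    def gamma_block(self, coef: np.ndarray, k: int) -> np.ndarray:
        base = self.q + self.n_main + k * self.D.d_gamma
        return coef[base : base + self.D.d_gamma]


def _prior_precision(
    part: _Partition, prior: PriorSpec, shrink: ShrinkState
) -> np.ndarray:
    """Assemble the diagonal prior precision for the joint coefficient draw."""
    P = np.empty(part.size)
    P[part.alpha] = 1.0 / 100.0  # alpha ~ N(0, 10^2) in every regime
    if prior.kind == "vague":
        P[part.beta] = 1.0 / prior.vague_sd**2
        P[part.gamma] = 1.0 / prior.vague_sd**2
        return P
    D = part.D
    P[part.beta] = shrink.a * np.repeat(shrink.eta, D.d_beta)
    if prior.kind == "independent":
        scale = shrink.b * shrink.theta
    else:
        eta_prod = np.array([shrink.eta[j] * shrink.eta[k] for (j, k) in D.pairs])
        scale = shrink.b * eta_prod * shrink.theta
    P[part.gamma] = np.repeat(scale, D.d_gamma)
    return P


def gibbs_sweep(
    y: np.ndarray,
    W: np.ndarray,
    part: _Partition,
    coef: np.ndarray,
    lat,
    shrink: ShrinkState,
    model: ModelSpec,
    prior: PriorSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """One systematic scan: xi -> lambda -> coefficients -> eta -> theta -> a, b.

    Mutates ``lat`` and ``shrink`` in place and returns the new coefficient
    vector.  The fixed scan order makes runs reproducible given the seed.
    """
    D = part.D
    m = W @ coef
    lat.xi = sample_xi(y, m, lat.lam, rng)
    lat.lam = sample_lambda(lat.xi, m, model.v, rng)
    P = _prior_precision(part, prior, shrink)
    coef = sample_coefficients(lat.xi, lat.lam, W, P, rng)
    if prior.kind == "vague":
        return coef

    beta_blocks = [part.beta_block(coef, j) for j in range(D.p)]
    gamma_blocks = [part.gamma_block(coef, k) for k in range(D.K)]
    h = prior.gamma_hyper
    if prior.kind == "independent":
        for j in range(D.p):
            shrink.eta[j] = sample_eta_independent(
                beta_blocks[j], shrink.a, rng, h["eta"]
            )
    else:
        pair_of = {frozenset(pr): k for k, pr in enumerate(D.pairs)}
        for j in range(D.p):
            partners = [k for k in range(D.p) if k != j]
            ks = [pair_of[frozenset((j, k))] for k in partners]
            shrink.eta[j] = sample_eta_shared(
                j,
                beta_blocks[j],
                [gamma_blocks[k] for k in ks],
                shrink.eta[partners],
                shrink.theta[ks],
                shrink.a,
                shrink.b,
                rng,
                h["eta"],
            )
    for k, (gj, gk) in enumerate(D.pairs):
        shrink.theta[k] = sample_theta(
            gamma_blocks[k],
            shrink.b,
            shrink.eta[gj],
            shrink.eta[gk],
            prior.kind,
            rng,
            h["theta"],
        )
    shrink.a, shrink.b = sample_globals(
        beta_blocks,
        gamma_blocks,
        shrink.eta,
        shrink.theta,
        D.pairs,
        prior.kind,
        rng,
        h["a"],
        h["b"],
    )
    return coef


@dataclass
class PosteriorDraws:
    """Thinned post-burn-in draws with provenance.

    Coefficient arrays are stored on the robit scale; matching logit-scale
    arrays (every coefficient divided by 1.5484) are populated when ``v = 7``.
    """

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    eta: np.ndarray | None
    theta: np.ndarray | None
    a: np.ndarray | None
    b: np.ndarray | None
    model: ModelSpec
    prior: PriorSpec
    covariate_names: list[str]
    main_names: list[str]
    interaction_names: list[str]
    pairs: list[tuple[int, int]]
    d_beta: int
    d_gamma: int
    alpha_logit: np.ndarray = field(init=False)
    beta_logit: np.ndarray = field(init=False)
    gamma_logit: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.model.v == 7:
            self.alpha_logit = convert_to_logit_scale(self.alpha)
            self.beta_logit = convert_to_logit_scale(self.beta)
            self.gamma_logit = convert_to_logit_scale(self.gamma)
        else:  # no calibrated conversion; summaries must use robit scale
            self.alpha_logit = np.full_like(self.alpha, np.nan)
            self.beta_logit = np.full_like(self.beta, np.nan)
            self.gamma_logit = np.full_like(self.gamma, np.nan)

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format draws: iteration, parameter, value, scale."""
        frames = []
        groups = [
            ("alpha", self.alpha, self.alpha_logit, self.covariate_names),
            ("beta", self.beta, self.beta_logit, self.main_names),
            ("gamma", self.gamma, self.gamma_logit, self.interaction_names),
        ]
        iters = np.arange(self.n_draws)
        for group, robit_arr, logit_arr, names in groups:
            for scale, arr in (("robit", robit_arr), ("logit", logit_arr)):
                if np.all(np.isnan(arr)):
                    continue
                df = pd.DataFrame(arr, columns=names)
                df.insert(0, "iteration", iters)
                long = df.melt(id_vars="iteration", var_name="parameter", value_name="value")
                long["group"] = group
                long["scale"] = scale
                frames.append(long)
        shrink_groups = [("eta", self.eta), ("theta", self.theta)]
        for group, arr in shrink_groups:
            if arr is None:
                continue
            if group == "eta":
                names = [f"eta[{j}]" for j in range(arr.shape[1])]
            else:
                names = [f"theta[{j},{k}]" for (j, k) in self.pairs]
            df = pd.DataFrame(arr, columns=names)
            df.insert(0, "iteration", iters)
            long = df.melt(id_vars="iteration", var_name="parameter", value_name="value")
            long["group"] = group
            long["scale"] = "shrinkage"
            frames.append(long)
        for group, arr in (("a", self.a), ("b", self.b)):
            if arr is None:
                continue
            frames.append(
                pd.DataFrame(
                    {
                        "iteration": iters,
                        "parameter": group,
                        "value": arr,
                        "group": group,
                        "scale": "shrinkage",
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def run_mcmc(
    y: np.ndarray,
    X: ExposureMatrix,
    U: CovariateMatrix,
    model: ModelSpec,
    prior: PriorSpec,
    D: DesignBlocks | None = None,
) -> PosteriorDraws:
    """Run the full Gibbs sampler and return thinned post-burn-in draws.

    The design is built from ``X`` per ``model.parameterization`` unless a
    prebuilt ``D`` is passed.  Deterministic given ``model.seed``.
    """
    y = np.asarray(y)
    if D is None:
        D = build_design(X, model.parameterization)
    if D.n != U.n or D.n != y.shape[0]:
        raise ValueError("outcome, exposures and covariates disagree on n")
    rng = np.random.default_rng(model.seed)
    part = _Partition(U.q, D)
    W = np.hstack([U.values, D.main, D.interaction])

    coef = np.zeros(part.size)
    lat = init_latent_state(y, rng)
    shrink = ShrinkState(eta=np.ones(D.p), theta=np.ones(D.K), a=1.0, b=1.0)

    kept = (model.iterations - model.burn_in) // model.thin
    q, nb, ng = U.q, part.n_main, part.n_inter
    store = {
        "alpha": np.empty((kept, q)),
        "beta": np.empty((kept, nb)),
        "gamma": np.empty((kept, ng)),
    }
    track_shrink = prior.kind != "vague"
    if track_shrink:
        store.update(
            eta=np.empty((kept, D.p)),
            theta=np.empty((kept, D.K)),
            a=np.empty(kept),
            b=np.empty(kept),
        )
    s = 0
    for it in range(model.iterations):
        coef = gibbs_sweep(y, W, part, coef, lat, shrink, model, prior, rng)
        if not np.all(np.isfinite(coef)):
            raise RuntimeError(f"non-finite sampler state at iteration {it}")
        if it >= model.burn_in and (it - model.burn_in) % model.thin == 0:
            store["alpha"][s] = coef[part.alpha]
            store["beta"][s] = coef[part.beta]
            store["gamma"][s] = coef[part.gamma]
            if track_shrink:
                store["eta"][s] = shrink.eta
                store["theta"][s] = shrink.theta
                store["a"][s] = shrink.a
                store["b"][s] = shrink.b
            s += 1
    return PosteriorDraws(
        alpha=store["alpha"][:s],
        beta=store["beta"][:s],
        gamma=store["gamma"][:s],
        eta=store["eta"][:s] if track_shrink else None,
        theta=store["theta"][:s] if track_shrink else None,
        a=store["a"][:s] if track_shrink else None,
        b=store["b"][:s] if track_shrink else None,
        model=model,
        prior=prior,
        covariate_names=list(U.names),
        main_names=D.main_names,
        interaction_names=D.interaction_names,
        pairs=list(D.pairs),
        d_beta=D.d_beta,
        d_gamma=D.d_gamma,
    )
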