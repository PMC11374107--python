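"""Exposure preprocessing and design-matrix construction.

Three parameterizations of a chemical-mixture design are supported, each
producing a main-effect block and a two-way-interaction block:

* ``linear``     — one column per chemical (the log exposure itself) and one
  product column per pair.
* ``polynomial`` — quadratic per-chemical blocks ``(x, x^2)`` and the four
  cross monomials ``(x_j x_k, x_j^2 x_k, x_j x_k^2, x_j^2 x_k^2)`` per pair.
* ``lod``        — a two-parameter-per-exposure form for left-censored
  (below limit-of-detection) measurements: an indicator of detection and a
  linear excess above the limit, ``(1{x >= C}, 1{x >= C}(x - C))``, with the
  four pairwise products as the interaction block.  The magnitude of a
  censored cell is never read.

All builders are pure functions of their inputs, so regenerating blocks from
the same :class:`ExposureMatrix` is bit-identical.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ExposureMatrix",
    "CovariateMatrix",
    "DesignBlocks",
    "ScalingRecord",
    "interaction_pairs",
    "filter_correlated",
    "build_linear_design",
    "build_polynomial_design",
    "build_lod_design",
    "build_design",
    "standardize_for_latentfun",
]


@dataclass
class ExposureMatrix:
    """n x p log-scale exposure values with optional LOD metadata.

    Parameters
    ----------
    values
        Log-transformed exposure measurements, one row per subject.  Censored
        cells hold a placeholder (conventionally the detection limit); the
        LOD parameterization never reads their magnitude.
    chem_names
        Length-``p`` chemical labels.
    detect_limits
        Per-chemical detection limits ``C_j`` on the same (log) scale.
    below_lod
        n x p boolean flags marking left-censored cells.
    """

    values: np.ndarray
    chem_names: list[str]
    detect_limits: np.ndarray | None = None
    below_lod: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d array")
        if len(self.chem_names) != self.values.shape[1]:
            raise ValueError("chem_names length must match number of columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite (impute or flag censored cells)")
        if self.detect_limits is not None:
            self.detect_limits = np.asarray(self.detect_limits, dtype=float)
            if self.detect_limits.shape != (self.p,):
                raise ValueError("detect_limits must have one entry per chemical")
        if self.below_lod is not None:
            self.below_lod = np.asarray(self.below_lod, dtype=bool)
            if self.below_lod.shape != self.values.shape:
                raise ValueError("below_lod must match values' shape")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def select(self, keep: list[int]) -> "ExposureMatrix":
        """Return a copy restricted to the chemicals at positions ``keep``."""
        return ExposureMatrix(
            values=self.values[:, keep].copy(),
            chem_names=[self.chem_names[j] for j in keep],
            detect_limits=None if self.detect_limits is None else self.detect_limits[keep].copy(),
            below_lod=None if self.below_lod is None else self.below_lod[:, keep].copy(),
        )


@dataclass
class CovariateMatrix:
    """n x q adjustment-covariate matrix whose first column is the intercept."""

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d array")
        if len(self.names) != self.values.shape[1]:
            raise ValueError("names length must match number of columns")
        if not np.allclose(self.values[:, 0], 1.0):
            raise ValueError("first covariate column must be the intercept (all ones)")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def q(self) -> int:
        return self.values.shape[1]


def interaction_pairs(p: int) -> list[tuple[int, int]]:
    """All ``(j, k)`` with ``j < k`` in lexicographic order; ``K = p(p-1)/2``."""
    return [(j, k) for j in range(p) for k in range(j + 1, p)]


@dataclass
class DesignBlocks:
    """Main-effect and interaction column blocks with full column provenance.

    ``main`` has ``p * d_beta`` columns (chemical-major, within-block order
    second); ``interaction`` has ``K * d_gamma`` columns in lexicographic pair
    order.  ``block_index`` maps every column of the concatenated
    ``[main | interaction]`` matrix to its chemical (or pair) and within-block
    position.
    """

    main: np.ndarray
    interaction: np.ndarray
    d_beta: int
    d_gamma: int
    chem_names: list[str]
    pairs: list[tuple[int, int]]
    parameterization: str
    detect_limits: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.main.shape[0]

    @property
    def p(self) -> int:
        return len(self.chem_names)

    @property
    def K(self) -> int:
        return len(self.pairs)

    def main_slice(self, j: int) -> slice:
        """Column slice of ``main`` belonging to chemical ``j``."""
        return slice(j * self.d_beta, (j + 1) * self.d_beta)

    def interaction_slice(self, k: int) -> slice:
        """Column slice of ``interaction`` belonging to pair index ``k``."""
        return slice(k * self.d_gamma, (k + 1) * self.d_gamma)

    def pair_index(self, j: int, k: int) -> int:
        """Position of pair ``(min(j,k), max(j,k))`` in ``pairs``."""
        return self.pairs.index((min(j, k), max(j, k)))

    @property
    def block_index(self) -> list[tuple[str, object, int]]:
        """Per-column provenance: ``(kind, chemical-or-pair, within-block pos)``."""
        idx: list[tuple[str, object, int]] = []
        for j in range(self.p):
            for d in range(self.d_beta):
                idx.append(("main", self.chem_names[j], d))
        for (j, k) in self.pairs:
            for d in range(self.d_gamma):
                idx.append(("interaction", (self.chem_names[j], self.chem_names[k]), d))
        return idx

    @property
    def main_names(self) -> list[str]:
        if self.d_beta == 1:
            return list(self.chem_names)
        return [f"{c}[{d}]" for c in self.chem_names for d in range(self.d_beta)]

    @property
    def interaction_names(self) -> list[str]:
        if self.d_gamma == 1:
            return [f"{self.chem_names[j]}:{self.chem_names[k]}" for (j, k) in self.pairs]
        return [
            f"{self.chem_names[j]}:{self.chem_names[k]}[{d}]"
            for (j, k) in self.pairs
            for d in range(self.d_gamma)
        ]


def filter_correlated(
    X: ExposureMatrix, threshold: float = 0.9, seed: int | None = None
) -> ExposureMatrix:
    """Drop one member of every highly correlated exposure pair.

    Pairs with Pearson ``|r| > threshold`` (log scale) are resolved by
    removing one member chosen by a seeded RNG, repeated until no violating
    pair remains.  The retained set is reproducible given ``seed``; removals
    are emitted through the module logger.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if X.p < 2:
        raise ValueError("need at least two chemicals to filter")
    sds = X.values.std(axis=0)
    if np.any(sds == 0.0):
        bad = [X.chem_names[j] for j in np.flatnonzero(sds == 0.0)]
        raise ValueError(
            f"correlation undefined for constant column(s): {', '.join(bad)}"
        )
    rng = np.random.default_rng(seed)
    keep = list(range(X.p))
    while True:
        corr = np.corrcoef(X.values[:, keep], rowvar=False)
        viol = [
            (a, b)
            for a in range(len(keep))
            for b in range(a + 1, len(keep))
            if abs(corr[a, b]) > threshold
        ]
        if not viol:
            break
        a, b = viol[0]
        drop_local = a if rng.random() < 0.5 else b
        dropped = keep.pop(drop_local)
        other = keep[b - 1] if drop_local == a else keep[a]
        logger.info(
            "filter_correlated: dropping %s (|r|=%.3f with %s)",
            X.chem_names[dropped],
            abs(corr[a, b]),
            X.chem_names[other],
        )
    if len(keep) == X.p:
        return X
    return X.select(keep)


def build_linear_design(X: ExposureMatrix) -> DesignBlocks:
    """Linear parameterization: main columns are the exposures, interaction
    column ``(j, k)`` is the elementwise product of columns ``j`` and ``k``."""
    v = X.values
    p = X.p
    if p < 2:
        warnings.warn("fewer than 2 chemicals: no interaction block", stacklevel=2)
        pairs: list[tuple[int, int]] = []
        inter = np.empty((X.n, 0))
    else:
        pairs = interaction_pairs(p)
        inter = np.column_stack([v[:, j] * v[:, k] for (j, k) in pairs])
    return DesignBlocks(
        main=v.copy(),
        interaction=inter,
        d_beta=1,
        d_gamma=1,
        chem_names=list(X.chem_names),
        pairs=pairs,
        parameterization="linear",
    )


def build_polynomial_design(X: ExposureMatrix) -> DesignBlocks:
    """Quadratic parameterization: per-chemical block ``(x, x^2)``, per-pair
    block ``(x_j x_k, x_j^2 x_k, x_j x_k^2, x_j^2 x_k^2)``."""
    v = X.values
    p = X.p
    main = np.empty((X.n, 2 * p))
    main[:, 0::2] = v
    main[:, 1::2] = v**2
    if p < 2:
        warnings.warn("fewer than 2 chemicals: no interaction block", stacklevel=2)
        pairs: list[tuple[int, int]] = []
        inter = np.empty((X.n, 0))
    else:
        pairs = interaction_pairs(p)
        cols = []
        for (j, k) in pairs:
            xj, xk = v[:, j], v[:, k]
            cols += [xj * xk, xj**2 * xk, xj * xk**2, xj**2 * xk**2]
        inter = np.column_stack(cols)
    return DesignBlocks(
        main=main,
        interaction=inter,
        d_beta=2,
        d_gamma=4,
        chem_names=list(X.chem_names),
        pairs=pairs,
        parameterization="polynomial",
    )


def build_lod_design(X: ExposureMatrix, C: np.ndarray | None = None) -> DesignBlocks:
    """Two-parameter LOD parameterization.

    Per chemical: ``(1{x >= C}, 1{x >= C}(x - C))`` — the first coefficient is
    the log odds at the detection limit relative to below it, the second the
    slope above the limit.  Per pair, the four pairwise products of the two
    chemicals' columns.  Subjects flagged below the LOD contribute exact zeros
    in every column involving that chemical; censored magnitudes are never
    read.  The boundary ``x == C`` counts as detected.
    """
    if C is None:
        C = X.detect_limits
    if C is None:
        raise ValueError("detection limits required for the LOD parameterization")
    C = np.asarray(C, dtype=float)
    if C.shape != (X.p,) or not np.all(np.isfinite(C)):
        raise ValueError("one finite detection limit per chemical is required")
    v = X.values
    detected = v >= C[None, :]
    if X.below_lod is not None:
        detected &= ~X.below_lod
    for j in range(X.p):
        if detected[:, j].all():
            warnings.warn(
                f"detection limit for {X.chem_names[j]} lies below every "
                "observation; its indicator column is constant 1",
                stacklevel=2,
            )
    ind = detected.astype(float)
    excess = ind * (v - C[None, :])  # exactly 0 wherever not detected
    p = X.p
    main = np.empty((X.n, 2 * p))
    main[:, 0::2] = ind
    main[:, 1::2] = excess
    if p < 2:
        warnings.warn("fewer than 2 chemicals: no interaction block", stacklevel=2)
        pairs: list[tuple[int, int]] = []
        inter = np.empty((X.n, 0))
    else:
        pairs = interaction_pairs(p)
        cols = []
        for (j, k) in pairs:
            both = ind[:, j] * ind[:, k]
            cols += [
                both,
                excess[:, j] * ind[:, k],
                ind[:, j] * excess[:, k],
                excess[:, j] * excess[:, k],
            ]
        inter = np.column_stack(cols)
    return DesignBlocks(
        main=main,
        interaction=inter,
        d_beta=2,
        d_gamma=4,
        chem_names=list(X.chem_names),
        pairs=pairs,
        parameterization="lod",
        detect_limits=C.copy(),
    )


_BUILDERS = {
    "linear": build_linear_design,
    "polynomial": build_polynomial_design,
    "poly": build_polynomial_design,
    "lod": build_lod_design,
}


def build_design(X: ExposureMatrix, parameterization: str) -> DesignBlocks:
    """Dispatch to the builder for ``parameterization``."""
    try:
        builder = _BUILDERS[parameterization]
    except KeyError:
        raise ValueError(f"unknown parameterization: {parameterization!r}") from None
    return builder(X)


@dataclass
class ScalingRecord:
    """Scale factors applied by :func:`standardize_for_latentfun`.

    Needed to place risk-curve grids back on the original exposure scale.
    """

    main_scale: np.ndarray
    interaction_scale: np.ndarray
    cov_means: np.ndarray
    cov_sds: np.ndarray
    cov_names: list[str] = field(default_factory=list)


def standardize_for_latentfun(
    D: DesignBlocks, U: CovariateMatrix
) -> tuple[DesignBlocks, CovariateMatrix, ScalingRecord]:
    """Standardize blocks for the latent-functional sampler.

    Every main-effect and interaction column is divided by its own maximum
    absolute value (applied to the already-formed columns); non-intercept
    covariates are centred and scaled to unit SD (denominator ``n``).  The
    returned :class:`ScalingRecord` allows back-transformation.
    """
    def _scale_block(block: np.ndarray, names: list[str]) -> tuple[np.ndarray, np.ndarray]:
        scale = np.max(np.abs(block), axis=0) if block.size else np.empty(0)
        out = block.copy()
        for c in range(block.shape[1]):
            if scale[c] == 0.0:
                warnings.warn(
                    f"all-zero design column {names[c]} left unscaled", stacklevel=3
                )
                scale[c] = 1.0
            else:
                out[:, c] /= scale[c]
        return out, scale

    main_s, main_scale = _scale_block(D.main, D.main_names)
    inter_s, inter_scale = _scale_block(D.interaction, D.interaction_names)

    means = U.values.mean(axis=0)
    sds = U.values.std(axis=0)  # denominator n
    zero_sd = [U.names[c] for c in range(1, U.q) if sds[c] == 0.0]
    if zero_sd:
        raise ValueError(f"zero-SD covariate(s): {', '.join(zero_sd)}")
    Uv = U.values.copy()
    for c in range(1, U.q):
        Uv[:, c] = (Uv[:, c] - means[c]) / sds[c]
    means[0], sds[0] = 0.0, 1.0  # intercept untouched

    Ds = replace(D, main=main_s, interaction=inter_s)
    Us = CovariateMatrix(values=Uv, names=list(U.names))
    rec = ScalingRecord(
        main_scale=main_scale,
        interaction_scale=inter_scale,
        cov_means=means,
        cov_sds=sds,
        cov_names=list(U.names),
    )
    return Ds, Us, rec
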