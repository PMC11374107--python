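"""CSV round-tripping for study tables, detection limits and truth records.

Input convention: one row per subject with a binary ``y`` column, covariate
columns, and exposure columns (log scale).  Censored exposure cells are
either empty (``NA``) with a companion detection-limit CSV (``chem,limit``),
or marked by explicit ``<chem>_blod`` flag columns.  Censored cells are
stored internally with the detection limit as a placeholder; LOD designs
never read that magnitude.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .designs import CovariateMatrix, ExposureMatrix
from .simulate import SimulatedStudy

__all__ = ["read_limits_csv", "read_study_csv", "write_study_csv", "write_truth_json"]


def read_limits_csv(path: str | Path) -> pd.Series:
    """Detection limits from a two-column ``chem,limit`` CSV."""
    df = pd.read_csv(path)
    if not {"chem", "limit"} <= set(df.columns):
        raise ValueError("limits CSV must have columns 'chem' and 'limit'")
    return df.set_index("chem")["limit"]


def read_study_csv(
    data_path: str | Path,
    limits_path: str | Path | None = None,
    exposure_cols: list[str] | None = None,
    covariate_cols: list[str] | None = None,
    outcome_col: str = "y",
) -> tuple[np.ndarray, ExposureMatrix, CovariateMatrix]:
    """Load a case-control table into package containers.

    Exposure columns default to those named in the limits file (or, failing
    that, every non-outcome, non-flag column not named as a covariate).
    An intercept column is prepended to the covariates.
    """
    df = pd.read_csv(data_path)
    if outcome_col not in df.columns:
        raise ValueError(f"outcome column {outcome_col!r} missing")
    limits = read_limits_csv(limits_path) if limits_path is not None else None
    flag_cols = [c for c in df.columns if c.endswith("_blod")]
    if exposure_cols is None:
        if limits is not None:
            exposure_cols = [c for c in limits.index if c in df.columns]
        else:
            exposure_cols = [
                c
                for c in df.columns
                if c != outcome_col
                and c not in (covariate_cols or [])
                and not c.endswith("_blod")
            ]
    if covariate_cols is None:
        covariate_cols = [
            c
            for c in df.columns
            if c != outcome_col and c not in exposure_cols and not c.endswith("_blod")
        ]
    y = df[outcome_col].to_numpy(dtype=int)

    values = df[exposure_cols].to_numpy(dtype=float)
    C = None
    if limits is not None:
        missing = [c for c in exposure_cols if c not in limits.index]
        if missing:
            raise ValueError(f"no detection limit for: {', '.join(missing)}")
        C = limits.loc[exposure_cols].to_numpy(dtype=float)
    below = np.isnan(values)
    for c in exposure_cols:
        flag = f"{c}_blod"
        if flag in flag_cols:
            below[:, exposure_cols.index(c)] |= df[flag].to_numpy(dtype=bool)
    if below.any():
        if C is None:
            raise ValueError("censored cells present but no detection limits given")
        values = np.where(below, C[None, :], values)
    X = ExposureMatrix(
        values=values,
        chem_names=list(exposure_cols),
        detect_limits=C,
        below_lod=below if below.any() else None,
    )
    n = len(df)
    Uv = np.column_stack([np.ones(n)] + [df[c].to_numpy(dtype=float) for c in covariate_cols])
    U = CovariateMatrix(values=Uv, names=["intercept"] + list(covariate_cols))
    return y, X, U


def write_study_csv(study: SimulatedStudy, prefix: str | Path) -> dict[str, Path]:
    """Write a simulated study as ``<prefix>_data.csv`` + limits + truth files.

    Censored exposure cells are written as NA; the limits file carries C_j.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    X, U = study.exposures, study.covariates
    data = pd.DataFrame({"y": study.y})
    for c in range(1, U.q):
        data[U.names[c]] = U.values[:, c]
    for j, name in enumerate(X.chem_names):
        col = X.values[:, j].astype(object)
        if X.below_lod is not None:
            col = np.where(X.below_lod[:, j], np.nan, X.values[:, j])
        data[name] = col
    paths = {
        "data": prefix.parent / f"{prefix.name}_data.csv",
        "limits": prefix.parent / f"{prefix.name}_limits.csv",
        "truth": prefix.parent / f"{prefix.name}_truth.json",
    }
    data.to_csv(paths["data"], index=False)
    pd.DataFrame({"chem": X.chem_names, "limit": X.detect_limits}).to_csv(
        paths["limits"], index=False
    )
    write_truth_json(study, paths["truth"])
    return paths


def write_truth_json(study: SimulatedStudy, path: str | Path) -> None:
    cfg = study.config
    truth = {
        "n": cfg.n,
        "p": cfg.p,
        "parameterization": cfg.parameterization,
        "alpha": cfg.alpha.tolist(),
        "intercept_realized": study.intercept,
        "beta": cfg.beta.tolist(),
        "gamma": cfg.gamma.tolist(),
        "lod_fractions": cfg.lod_fractions.tolist(),
        "target_case_fraction": cfg.target_case_fraction,
        "coefficient_scale": "logit",
    }
    Path(path).write_text(json.dumps(truth, indent=2))
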