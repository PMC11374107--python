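import numpy as np
import pytest

from mixint.designs import CovariateMatrix, ExposureMatrix, interaction_pairs
from mixint.simulate import SimulationConfig, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_exposures(rng):
    """5 subjects x 4 chemicals, no censoring."""
    vals = rng.normal(size=(5, 4))
    return ExposureMatrix(values=vals, chem_names=[f"chem{j+1}" for j in range(4)])


@pytest.fixture
def intercept_only():
    def make(n):
        return CovariateMatrix(values=np.ones((n, 1)), names=["intercept"])

    return make


def make_linear_truth(
    n,
    p,
    nonzero_main=(),
    nonzero_inter=(),
    alpha=None,
    lod_fractions=None,
    corr=None,
    target_case_fraction=None,
):
    """SimulationConfig with a linear logit truth; coefficients given as
    {index: value} for mains and {(j, k): value} for interactions."""
    pairs = interaction_pairs(p)
    beta = np.zeros(p)
    for j, v in dict(nonzero_main).items():
        beta[j] = v
    gamma = np.zeros(len(pairs))
    for (j, k), v in dict(nonzero_inter).items():
        gamma[pairs.index((min(j, k), max(j, k)))] = v
    if alpha is None:
        alpha = np.array([0.0, 0.1, -0.1, 0.0, 0.0])
    return SimulationConfig(
        n=n,
        p=p,
        corr=np.eye(p) if corr is None else corr,
        lod_fractions=np.zeros(p) if lod_fractions is None else np.asarray(lod_fractions),
        alpha=np.asarray(alpha, dtype=float),
        beta=beta,
        gamma=gamma,
        parameterization="linear",
        target_case_fraction=target_case_fraction,
    )


@pytest.fixture
def linear_truth_factory():
    return make_linear_truth


@pytest.fixture
def small_study():
    """n=500, p=2 linear study with strong truth, uncensored."""
    cfg = make_linear_truth(500, 2, nonzero_main={0: 1.0, 1: -0.8})
    return simulate_study(cfg, seed=7)
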