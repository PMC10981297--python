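import numpy as np
import pandas as pd
import pytest

from esmnet.mlvar import NodewiseFit
from esmnet.synthetic import VarParameters, simulate_dataset


def make_params(
    p=3,
    diag=0.15,
    cross=None,
    slope_sd=0.0,
    mean_sd=0.0,
    innov=None,
    means=None,
    bounds=(1, 7),
):
    """Convenience VarParameters constructor for tests."""
    B = np.eye(p) * diag
    if cross:
        for (i, j), w in cross.items():
            B[i, j] = w
    return VarParameters(
        fixed_temporal=B,
        fixed_means=np.full(p, 4.0) if means is None else np.asarray(means, float),
        random_slope_sd=np.full((p, p), float(slope_sd)),
        random_mean_sd=np.full(p, float(mean_sd)),
        innovation_cov=np.eye(p) if innov is None else np.asarray(innov, float),
        likert_bounds=bounds,
    )


def make_fake_fit(target, names, coefs, pvals, residuals=None, random_variances=None, n_persons=2):
    """Hand-built NodewiseFit for network/centrality tests."""
    p = len(names)
    n = 4 if residuals is None else len(residuals)
    resid = np.zeros(n) if residuals is None else np.asarray(residuals, float)
    row_index = pd.DataFrame({"person_id": [1] * n, "day": np.arange(2, n + 2)})
    return NodewiseFit(
        target=target,
        target_name=names[target],
        intercept=0.0,
        intercept_se=1.0,
        intercept_p=1.0,
        fixed_coefs=np.asarray(coefs, float),
        std_errors=np.ones(p),
        p_values=np.asarray(pvals, float),
        random_variances=np.zeros(p + 1) if random_variances is None else np.asarray(random_variances, float),
        residuals=resid,
        row_index=row_index,
        n_rows=n,
        n_persons=n_persons,
        converged=True,
        method="test",
    )


@pytest.fixture(scope="session")
def small_params():
    return make_params(p=3, diag=0.2, cross={(0, 1): 0.15}, slope_sd=0.05, mean_sd=0.5)


@pytest.fixture(scope="session")
def small_dataset(small_params):
    return simulate_dataset(small_params, n_persons=20, n_days=30, seed=7)


@pytest.fixture(scope="session")
def continuous_dataset(small_params):
    return simulate_dataset(small_params, n_persons=20, n_days=30, seed=7, discretize=False)
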