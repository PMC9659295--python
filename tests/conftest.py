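import numpy as np
import pandas as pd
import pytest

from healthlit import GeneratorConfig, generate, shift_to_irt_codes
from healthlit.instrument import ResponseMatrix, hls19_q12
from healthlit.irt import estimate_persons, fit_pcm_mml


def make_rm(rows, weights=None, covariates=None):
    """ResponseMatrix from a list of 12-item response rows (None = missing)."""
    arr = np.array([[np.nan if v is None else float(v) for v in row] for row in rows])
    cov = pd.DataFrame(covariates) if covariates is not None else None
    return ResponseMatrix(arr, hls19_q12(), weights, cov)


def profile_row(n_vd, n_d, n_e, n_ve):
    """A complete 12-item response row with the given category counts."""
    assert n_vd + n_d + n_e + n_ve == 12
    return [1] * n_vd + [2] * n_d + [3] * n_e + [4] * n_ve


def two_block_responses(n=2000, seed=21):
    """Orthogonal two-factor data: items 1-6 driven by one latent trait,
    items 7-12 by an independent one."""
    ds1 = generate(GeneratorConfig(n_persons=n, seed=seed))
    ds2 = generate(GeneratorConfig(n_persons=n, seed=seed + 1000))
    resp = np.column_stack([ds1.rm.responses[:, :6], ds2.rm.responses[:, 6:]])
    return ResponseMatrix(resp, ds1.rm.instrument, ds1.rm.weights,
                          ds1.rm.covariates.copy())


@pytest.fixture(scope="session")
def clean_ds():
    """Unidimensional PCM population with the default social gradient."""
    cfg = GeneratorConfig(n_persons=2000, seed=3,
                          special_scores=[("special_digital", 0.6),
                                          ("special_nav", 0.55)])
    return generate(cfg)


@pytest.fixture(scope="session")
def clean_model(clean_ds):
    return fit_pcm_mml(shift_to_irt_codes(clean_ds.rm))


@pytest.fixture(scope="session")
def clean_wle(clean_model):
    return estimate_persons(clean_model, method="WLE")


@pytest.fixture(scope="session")
def two_block_rm():
    return two_block_responses(n=2000, seed=21)


@pytest.fixture(scope="session")
def two_block_model(two_block_rm):
    return fit_pcm_mml(shift_to_irt_codes(two_block_rm))
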