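"""Synthetic respondent generator.

Emulates the statistical structure the validation battery assumes: partial
credit model (PCM) responses on 12 four-category items, a social gradient on
the latent trait, correlated special-health-literacy scores and an ordinal
self-perceived-health outcome — plus injectable violations (differential
item functioning, local dependence via response copying, extreme response
styles, MCAR missingness) so every diagnostic has both a null and an
alternative test bed.

Draws for the different blocks (covariates, latent trait, responses,
copying, missingness, ...) come from independent child streams of the seed,
so switching one block on or off never perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError
from .instrument import InstrumentSpec, ResponseMatrix, hls19_q12

# stream indices for the independent child generators
_STREAMS = {
    "covariates": 0, "theta": 1, "responses": 2, "local_dep": 3,
    "style": 4, "missing": 5, "special": 6, "health": 7,
}


def _default_item_params() -> np.ndarray:
    """12 items x 3 step parameters: locations spread over [-1, 1] logits
    with steps at location +/- 0.7."""
    loc = np.linspace(-1.0, 1.0, 12)
    return loc[:, None] + np.array([-0.7, 0.0, 0.7])[None, :]


@dataclass
class GradientConfig:
    """Linear social gradient on the latent trait (standardized covariates)."""

    b_sex: float = 0.0
    b_age: float = -0.10
    b_edu: float = 0.25
    b_status: float = 0.20
    b_findep: float = -0.30
    residual_sd: float | None = None  # None: derived so marginal sd = latent_sd

    def coefficients(self) -> np.ndarray:
        return np.array([self.b_sex, self.b_age, self.b_edu, self.b_status, self.b_findep])


@dataclass
class HealthModelConfig:
    """Ordinal self-perceived health 1 (very good) .. 5 (very bad):
    latent h* = c_theta * theta + c_age * z(age) + noise, cut at thresholds."""

    c_theta: float = -0.5
    c_age: float = 0.3
    noise_sd: float = 1.0
    thresholds: tuple = (-1.5, -0.5, 0.5, 1.5)


@dataclass
class GeneratorConfig:
    n_persons: int = 1000
    item_params: np.ndarray = field(default_factory=_default_item_params)
    latent_sd: float = 1.0
    gradient: GradientConfig = field(default_factory=GradientConfig)
    dif: list = field(default_factory=list)          # (item_id, covariate, offset_logits)
    local_dep: list = field(default_factory=list)    # (item_id_a, item_id_b, kappa)
    response_style_sd: float = 0.0
    missing_rate: float = 0.0
    special_scores: list = field(default_factory=lambda: [])  # (name, rho)
    health_model: HealthModelConfig = field(default_factory=HealthModelConfig)
    seed: int = 0
    instrument: InstrumentSpec = field(default_factory=hls19_q12)

    def __post_init__(self):
        self.item_params = np.asarray(self.item_params, dtype=float)
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigError("missing_rate must be in [0, 1]")
        if self.latent_sd <= 0:
            raise ConfigError("latent_sd must be positive")
        if self.response_style_sd < 0:
            raise ConfigError("response_style_sd must be non-negative")
        for name, rho in self.special_scores:
            if not -1.0 < rho < 1.0:
                raise ConfigError(f"special score {name!r}: rho must be in (-1, 1)")
        for _, _, kappa in self.local_dep:
            if not 0.0 <= kappa <= 1.0:
                raise ConfigError("copy probability kappa must be in [0, 1]")


@dataclass
class SyntheticDataset:
    rm: ResponseMatrix
    theta: np.ndarray
    item_params: np.ndarray
    special: pd.DataFrame
    config: GeneratorConfig


def _rng(cfg_seed: int, block: str) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=cfg_seed, spawn_key=(_STREAMS[block],))
    return np.random.default_rng(ss)


def sample_covariates(cfg: GeneratorConfig) -> pd.DataFrame:
    """Sex ~ Bernoulli(0.5), age ~ Uniform(18, 80) rounded, education ~
    ISCED 0-8, status ~ 1-10, financial deprivation ~ 1-4."""
    if cfg.n_persons < 1:
        raise ConfigError("n_persons must be >= 1")
    rng = _rng(cfg.seed, "covariates")
    n = cfg.n_persons
    edu_p = np.array([0.01, 0.03, 0.10, 0.30, 0.22, 0.06, 0.14, 0.10, 0.04])
    findep_p = np.array([0.45, 0.30, 0.17, 0.08])
    return pd.DataFrame({
        "sex": np.where(rng.random(n) < 0.5, "female", "male"),
        "age": np.round(rng.uniform(18, 80, n)).astype(int),
        "education": rng.choice(9, n, p=edu_p),
        "status": rng.integers(1, 11, n),
        "findep": rng.choice(np.arange(1, 5), n, p=findep_p),
        "mode": "CAWI",
        "country": "SYN",
    })


def _standardized_design(cov: pd.DataFrame) -> np.ndarray:
    x = np.column_stack([
        (cov["sex"] == "female").astype(float),
        cov["age"].astype(float),
        cov["education"].astype(float),
        cov["status"].astype(float),
        cov["findep"].astype(float),
    ])
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (x - x.mean(axis=0)) / sd


def sample_theta(cov: pd.DataFrame, cfg: GeneratorConfig) -> np.ndarray:
    """theta = b . z(covariates) + eps; the residual sd defaults to the value
    that makes the marginal sd equal cfg.latent_sd (covariates are close to
    independent by construction)."""
    rng = _rng(cfg.seed, "theta")
    b = cfg.gradient.coefficients()
    systematic = _standardized_design(cov) @ b
    res_sd = cfg.gradient.residual_sd
    if res_sd is None:
        res_sd = float(np.sqrt(max(cfg.latent_sd**2 - float(b @ b), 1e-4)))
    return systematic + rng.normal(0.0, res_sd, len(cov))


def pcm_category_probs(theta, delta) -> np.ndarray:
    """Exact PCM category probabilities.

    P(X = x | theta) prop. to exp(sum_{k<=x} (theta - delta_k)), delta_0 = 0.
    ``theta``: (n,), ``delta``: (k_items, m-1).  Returns (n, k_items, m).
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    delta = np.asarray(delta, dtype=float)
    m = delta.shape[1] + 1
    # cumulative linear predictor: psi_x = x*theta - sum_{k<=x} delta_k
    cumdelta = np.concatenate([np.zeros((delta.shape[0], 1)), np.cumsum(delta, axis=1)], axis=1)
    psi = theta[:, None, None] * np.arange(m)[None, None, :] - cumdelta[None, :, :]
    psi -= psi.max(axis=2, keepdims=True)
    ex = np.exp(psi)
    return ex / ex.sum(axis=2, keepdims=True)


def sample_pcm_responses(theta, cfg: GeneratorConfig) -> np.ndarray:
    """Draw raw 1..4 responses from the PCM, then apply (in order) local
    dependence copying, response-style shifts, and MCAR missingness."""
    rng = _rng(cfg.seed, "responses")
    n = len(theta)
    delta = cfg.item_params
    item_ids = cfg.instrument.item_ids

    if cfg.response_style_sd > 0:
        style = _rng(cfg.seed, "style").normal(0.0, cfg.response_style_sd, n)
    else:
        style = np.zeros(n)

    # per-person step parameters: DIF offsets and style shifts
    cov = getattr(cfg, "_covariates", None)
    group_offsets = np.zeros((n, delta.shape[0]))
    for item_id, covariate, offset in cfg.dif:
        j = item_ids.index(item_id)
        flag = _dif_group(cov, covariate)
        group_offsets[flag, j] += offset

    m = delta.shape[1] + 1
    out = np.empty((n, delta.shape[0]))
    u = rng.random((n, delta.shape[0]))
    # build per-person deltas; vectorized over items
    d = np.broadcast_to(delta, (n,) + delta.shape).copy()
    d += group_offsets[:, :, None]
    d[:, :, 0] += style[:, None]   # outer step 1 harder -> category 1 more used
    d[:, :, -1] -= style[:, None]  # outer step m-1 easier -> top category more used
    cumdelta = np.concatenate([np.zeros(d.shape[:2] + (1,)), np.cumsum(d, axis=2)], axis=2)
    psi = theta[:, None, None] * np.arange(m)[None, None, :] - cumdelta
    psi -= psi.max(axis=2, keepdims=True)
    p = np.exp(psi)
    p /= p.sum(axis=2, keepdims=True)
    cdf = np.cumsum(p, axis=2)
    out = (u[:, :, None] > cdf[:, :, :-1]).sum(axis=2).astype(float) + 1.0  # raw 1..m

    if cfg.local_dep:
        rng_ld = _rng(cfg.seed, "local_dep")
        for a, b_, kappa in cfg.local_dep:
            ja, jb = item_ids.index(a), item_ids.index(b_)
            copy = rng_ld.random(n) < kappa
            out[copy, jb] = out[copy, ja]

    if cfg.missing_rate > 0:
        mask = _rng(cfg.seed, "missing").random(out.shape) < cfg.missing_rate
        out[mask] = np.nan
    return out


def _dif_group(cov, covariate) -> np.ndarray:
    if cov is None:
        raise ConfigError("DIF injection requires sampled covariates")
    v = cov[covariate]
    if covariate == "sex":
        return (v == "female").to_numpy()
    vals = v.astype(float).to_numpy()
    return vals > np.median(vals)


def attach_special_scores(theta, cfg: GeneratorConfig) -> pd.DataFrame:
    """0-100 scores with target latent correlation rho:
    s* = rho z(theta) + sqrt(1-rho^2) noise, mapped to 50 + 15 s*, clipped."""
    rng = _rng(cfg.seed, "special")
    z = (theta - theta.mean()) / theta.std(ddof=0)
    cols = {}
    for name, rho in cfg.special_scores:
        s = rho * z + np.sqrt(1 - rho**2) * rng.normal(size=len(theta))
        cols[name] = np.clip(50 + 15 * s, 0, 100)
    return pd.DataFrame(cols, index=range(len(theta)))


def attach_health(theta, cov: pd.DataFrame, cfg: GeneratorConfig) -> np.ndarray:
    """Ordinal self-perceived health in 1..5 (1 = very good).  With the
    default negative c_theta, higher literacy implies better (lower) health
    categories."""
    hm = cfg.health_model
    thr = np.asarray(hm.thresholds, dtype=float)
    if not np.all(np.diff(thr) > 0):
        raise ConfigError("health thresholds must be strictly increasing")
    rng = _rng(cfg.seed, "health")
    z_age = (cov["age"].astype(float) - cov["age"].astype(float).mean())
    sd = z_age.std(ddof=0)
    z_age = z_age / (sd if sd > 0 else 1.0)
    hstar = hm.c_theta * theta + hm.c_age * z_age.to_numpy() + rng.normal(0, hm.noise_sd, len(theta))
    return 1.0 + (hstar[:, None] > thr[None, :]).sum(axis=1)


def generate(cfg: GeneratorConfig) -> SyntheticDataset:
    """Full generation pass: covariates, latent trait, responses, special
    scores, health outcome.  Deterministic under (config, seed)."""
    cov = sample_covariates(cfg)
    theta = sample_theta(cov, cfg)
    cfg._covariates = cov
    resp = sample_pcm_responses(theta, cfg)
    special = attach_special_scores(theta, cfg)
    cov = cov.copy()
    cov["health"] = attach_health(theta, cov, cfg)
    for c in special.columns:
        cov[c] = special[c].to_numpy()
    rm = ResponseMatrix(resp, cfg.instrument, None, cov)
    return SyntheticDataset(rm, theta, cfg.item_params.copy(), special, cfg)
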