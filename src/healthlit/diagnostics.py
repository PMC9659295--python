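"""Model-fit and invariance diagnostics for fitted PCM / Rasch models.

The battery mirrors the standard Rasch validation workflow for the
instrument: information-weighted item fit (infit) with Wilson-Hilferty
t-statistics, the residual-correlation family Q3 / aQ3 / MADaQ3 with
Holm-adjusted tests, a model-implied-correlation SRMSR, the combined
PCA-of-residuals + paired-t-test unidimensionality procedure with an
Agresti-Coull interval, Andersen conditional likelihood-ratio tests and
per-item Wald z-statistics across person splits, graphical-model-test
data, a facets (item x group) DIF analysis for the PCM, Fischer's
well-conditioned-data check, and a margin-preserving resampling test of
global local independence.

Because the battery runs many tests, decisions default to alpha = 0.001;
reporting thresholds are infit 0.8 / 1.2 (screening note at 1.3), SRMSR
0.08 (conservative 0.05) and the 5% criterion for the t-test proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numba
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import EstimationError, IllConditionedError
from .irt import (
    PartialCreditModel,
    PersonEstimates,
    esf,
    esf_leave_one_out,
    estimate_persons,
    fit_rm_cml,
    pcm_moments,
)

ALPHA = 0.001
INFIT_UNDER = 1.2
INFIT_OVER = 0.8
INFIT_SCREEN = 1.3
SRMSR_CUT = 0.08
SRMSR_CONSERVATIVE = 0.05
T_CRIT = 1.96
PROP_CRIT = 0.05


# ---------------------------------------------------------------------------
# Residual machinery


def _expected_and_variance(model: PartialCreditModel, theta: np.ndarray):
    """Per-person conditional item mean/variance/mu3/mu4 at given thetas."""
    p_all = None
    e, w, mu3 = pcm_moments(theta, model.delta_)
    # fourth central moment for the infit t
    from .irt import pcm_probs
    p = pcm_probs(theta, model.delta_)
    x = np.arange(p.shape[2])
    mu4 = (p * (x[None, None, :] - e[:, :, None]) ** 4).sum(axis=2)
    return e, w, mu3, mu4


def standardized_residuals(model: PartialCreditModel, X=None,
                           persons: PersonEstimates | None = None):
    """(x - E)/sqrt(W) at the WLE person estimates; NaN where unobserved."""
    X = model._X if X is None else np.asarray(X, dtype=float)
    if persons is None:
        persons = estimate_persons(model, X, method="WLE")
    ok = ~np.isnan(persons.theta)
    e, w, _, _ = _expected_and_variance(model, np.where(ok, persons.theta, 0.0))
    z = (X - e) / np.sqrt(np.clip(w, 1e-12, None))
    z[~ok, :] = np.nan
    return z, e, w


@dataclass
class InfitResult:
    infit: np.ndarray
    t: np.ndarray
    underfit: np.ndarray     # infit > 1.2
    overfit: np.ndarray      # infit < 0.8
    screen_note: np.ndarray  # infit > 1.3


def infit(model: PartialCreditModel, X=None,
          persons: PersonEstimates | None = None) -> InfitResult:
    """Information-weighted mean-square item fit.

    v_i = sum_v (x_vi - E_vi)^2 / sum_v W_vi at the WLE estimates;
    t_i via the Wilson-Hilferty cube-root standardization.
    """
    X = model._X if X is None else np.asarray(X, dtype=float)
    if persons is None:
        persons = estimate_persons(model, X, method="WLE")
    ok = ~np.isnan(persons.theta)
    e, w, _, mu4 = _expected_and_variance(model, np.where(ok, persons.theta, 0.0))
    obs = ~np.isnan(X) & ok[:, None]
    num = np.where(obs, (X - e) ** 2, 0.0).sum(axis=0)
    den = np.where(obs, w, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = num / den
    # variance of the infit statistic (Wright-Masters): sum(mu4 - W^2)/ (sum W)^2
    qsq = np.where(obs, mu4 - w**2, 0.0).sum(axis=0) / np.clip(den, 1e-12, None) ** 2
    q = np.sqrt(np.clip(qsq, 1e-12, None))
    t = (np.cbrt(v) - 1.0) * (3.0 / q) + q / 3.0
    v = np.where(den > 0, v, np.nan)
    return InfitResult(v, t, v > INFIT_UNDER, v < INFIT_OVER, v > INFIT_SCREEN)


@dataclass
class Q3Result:
    q3: np.ndarray
    aq3: np.ndarray
    mad_aq3: float
    p_holm: np.ndarray           # (k, k), NaN on diagonal/excluded
    significant: np.ndarray      # Holm p < alpha
    excluded_pairs: list = field(default_factory=list)


def q3_family(model: PartialCreditModel, X=None,
              persons: PersonEstimates | None = None,
              alpha: float = ALPHA, min_joint: int = 10) -> Q3Result:
    """Yen's Q3 residual correlations, the pair-mean-centred aQ3, the
    MADaQ3 effect size, and Holm-adjusted Fisher-z p-values per pair."""
    X = model._X if X is None else np.asarray(X, dtype=float)
    z, _, _ = standardized_residuals(model, X, persons)
    k = z.shape[1]
    if k < 3:
        raise EstimationError("Q3 needs at least 3 items")
    q3 = np.full((k, k), np.nan)
    nn = np.zeros((k, k), dtype=int)
    excluded = []
    for i in range(k):
        q3[i, i] = 1.0
        for j in range(i + 1, k):
            ok = ~np.isnan(z[:, i]) & ~np.isnan(z[:, j])
            nn[i, j] = nn[j, i] = int(ok.sum())
            if nn[i, j] < min_joint:
                excluded.append((i, j))
                continue
            r = np.corrcoef(z[ok, i], z[ok, j])[0, 1]
            q3[i, j] = q3[j, i] = r
    iu = np.triu_indices(k, 1)
    vals = q3[iu]
    mean_q3 = np.nanmean(vals)
    aq3 = q3 - mean_q3
    np.fill_diagonal(aq3, 0.0)
    mad = float(np.nanmean(np.abs(aq3[iu])))

    # Fisher-z test of aQ3 against 0, Holm over pairs
    pvals = np.full(len(vals), np.nan)
    use = ~np.isnan(vals)
    zf = np.arctanh(np.clip(aq3[iu][use], -0.999999, 0.999999))
    sez = 1.0 / np.sqrt(np.maximum(nn[iu][use] - 3, 1))
    pvals[use] = 2 * stats.norm.sf(np.abs(zf / sez))
    p_holm_flat = np.full(len(vals), np.nan)
    if use.any():
        p_holm_flat[use] = multipletests(pvals[use], method="holm")[1]
    p_holm = np.full((k, k), np.nan)
    p_holm[iu] = p_holm_flat
    p_holm.T[iu] = p_holm_flat
    sig = p_holm < alpha
    return Q3Result(q3, aq3, mad, p_holm, sig, excluded)


def model_implied_correlations(model: PartialCreditModel) -> np.ndarray:
    """Item-score correlation matrix implied by the fitted PCM, obtained by
    integrating the conditional item moments over the estimated latent
    distribution at the quadrature nodes."""
    nodes, w = model.nodes_, model.prior_weights_
    e, v, _ = pcm_moments(nodes, model.delta_)
    m1 = w @ e                                        # marginal means
    var = w @ (v + e**2) - m1**2
    cov = (e.T * w) @ e - np.outer(m1, m1)
    cov[np.diag_indices_from(cov)] = var
    with np.errstate(invalid="ignore"):
        return cov / np.sqrt(np.outer(var, var))


def srmsr_irt(model: PartialCreditModel, X=None) -> float:
    """SRMSR over item pairs: RMS difference between observed item-score
    correlations and the correlations implied by the fitted PCM."""
    X = model._X if X is None else np.asarray(X, dtype=float)
    r_model = model_implied_correlations(model)
    k = X.shape[1]
    r_obs = np.full((k, k), np.nan)
    for i in range(k):
        r_obs[i, i] = 1.0
        for j in range(i + 1, k):
            ok = ~np.isnan(X[:, i]) & ~np.isnan(X[:, j])
            if ok.sum() >= 3:
                r_obs[i, j] = r_obs[j, i] = np.corrcoef(X[ok, i], X[ok, j])[0, 1]
    iu = np.triu_indices(k, 1)
    d = r_obs[iu] - r_model[iu]
    return float(np.sqrt(np.nanmean(d**2)))


# ---------------------------------------------------------------------------
# Agresti-Coull and the PCA / t-test unidimensionality procedure


def agresti_coull(x: int, n: int, z: float = T_CRIT):
    """Adjusted-Wald binomial CI: n~ = n + z^2, p~ = (x + z^2/2)/n~,
    p~ +/- z sqrt(p~(1-p~)/n~).  Returns (p_tilde, lower, upper)."""
    n_t = n + z**2
    p_t = (x + z**2 / 2.0) / n_t
    half = z * np.sqrt(p_t * (1 - p_t) / n_t)
    return p_t, p_t - half, p_t + half


@dataclass
class UnidimResult:
    proportion: float
    ci_lower: float
    ci_upper: float
    supports_unidimensionality: bool
    n_tested: int
    subset_pos: list
    subset_neg: list
    loadings: np.ndarray


def pca_ttest_unidim(model: PartialCreditModel, X=None,
                     persons: PersonEstimates | None = None) -> UnidimResult:
    """Split items by the sign of their loading on the first principal
    component of the standardized residuals (zero loadings join the
    positive set), re-estimate WLE persons in both subsets, and count
    persons whose two estimates differ at |t| > 1.96.  Unidimensionality
    is supported when the significant proportion is <= 5% or the lower
    Agresti-Coull bound overlaps 5%."""
    X = model._X if X is None else np.asarray(X, dtype=float)
    if X.shape[1] < 4:
        raise EstimationError("PCA/t-test needs at least 4 items")
    z, _, _ = standardized_residuals(model, X, persons)
    complete = ~np.isnan(z).any(axis=1)
    zc = z[complete]
    zc = zc - zc.mean(axis=0)
    corr = np.corrcoef(zc, rowvar=False)
    vals, vecs = np.linalg.eigh(corr)
    loading = vecs[:, -1]
    if (loading <= 0).all():
        loading = -loading
    pos = [i for i in range(X.shape[1]) if loading[i] >= 0]
    neg = [i for i in range(X.shape[1]) if loading[i] < 0]
    if not pos or not neg:
        raise EstimationError("residual PCA produced an empty item subset")

    sub_model_1 = _restrict_model(model, pos)
    sub_model_2 = _restrict_model(model, neg)
    p1 = estimate_persons(sub_model_1, X[:, pos], method="WLE")
    p2 = estimate_persons(sub_model_2, X[:, neg], method="WLE")
    both = ~np.isnan(p1.theta) & ~np.isnan(p2.theta)
    t = (p1.theta[both] - p2.theta[both]) / np.sqrt(p1.se[both] ** 2 + p2.se[both] ** 2)
    n_tested = int(both.sum())
    x_sig = int((np.abs(t) > T_CRIT).sum())
    prop = x_sig / n_tested if n_tested else np.nan
    _, lo, hi = agresti_coull(x_sig, n_tested)
    ok = bool(prop <= PROP_CRIT or lo <= PROP_CRIT)
    return UnidimResult(float(prop), float(lo), float(hi), ok, n_tested, pos, neg, loading)


def _restrict_model(model: PartialCreditModel, items) -> PartialCreditModel:
    """A shallow PCM copy restricted to an item subset (for subset WLEs)."""
    sub = PartialCreditModel(**model.get_params())
    sub.delta_ = model.delta_[list(items)]
    sub.sigma_ = model.sigma_
    sub.nodes_ = model.nodes_
    sub.prior_weights_ = model.prior_weights_
    sub.group_shift_ = None
    sub.group_idx_ = None
    sub._X = None
    return sub


# ---------------------------------------------------------------------------
# Conditional tests for the dichotomous Rasch model


@dataclass
class AndersenResult:
    lr: float
    df: int
    p: float
    significant: bool
    group_fits: dict


def _clean_groups(labels) -> np.ndarray:
    labels = np.asarray(labels, dtype=object)
    return labels


def andersen_lr(X, split_labels, alpha: float = ALPHA) -> AndersenResult:
    """Andersen's conditional LR test: 2(sum_g l_g - l_pooled) ~ chi^2 with
    (k-1)(G-1) df under invariance of item parameters across groups."""
    X = np.asarray(X, dtype=float)
    labels = _clean_groups(split_labels)
    groups = [g for g in pd_unique(labels) if g is not None]
    if len(groups) < 2:
        raise EstimationError("Andersen LR needs at least two groups")
    pooled = fit_rm_cml(X, check_conditioning=True)
    fits = {}
    ll_groups = 0.0
    for g in groups:
        sel = labels == g
        try:
            fits[g] = fit_rm_cml(X[sel], check_conditioning=True)
        except IllConditionedError as err:
            raise IllConditionedError(
                f"subgroup {g!r} is ill-conditioned: {err}", witness=err.witness) from err
        ll_groups += fits[g].loglik
    lr = 2.0 * (ll_groups - pooled.loglik)
    k = X.shape[1]
    df = (k - 1) * (len(groups) - 1)
    p = float(stats.chi2.sf(max(lr, 0.0), df))
    return AndersenResult(float(lr), df, p, p < alpha, fits)


def pd_unique(labels):
    seen, out = set(), []
    for x in labels:
        if x not in seen:
            seen.add(x)
            out.append(x)
    return out


@dataclass
class WaldResult:
    z: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    beta_1: np.ndarray
    beta_2: np.ndarray


def wald_item_z(X, split_labels, alpha: float = ALPHA) -> WaldResult:
    """Per-item Wald z for the difference of CML difficulties between two
    groups under the common sum-to-zero normalization."""
    X = np.asarray(X, dtype=float)
    labels = _clean_groups(split_labels)
    groups = pd_unique([g for g in labels if g is not None])
    if len(groups) != 2:
        raise EstimationError("Wald z needs exactly two groups")
    f1 = fit_rm_cml(X[labels == groups[0]])
    f2 = fit_rm_cml(X[labels == groups[1]])
    z = (f1.beta - f2.beta) / np.sqrt(f1.se**2 + f2.se**2)
    p = 2 * stats.norm.sf(np.abs(z))
    return WaldResult(z, p, p < alpha, f1.beta, f2.beta)


@dataclass
class GraphicalTestData:
    beta_1: np.ndarray
    beta_2: np.ndarray
    se_1: np.ndarray
    se_2: np.ndarray
    radius_95: np.ndarray
    icc_scores: np.ndarray       # raw-score groups used for the empirical ICC
    icc_observed: np.ndarray     # (k, n_scores) observed proportion of 1s
    icc_model: np.ndarray        # (k, n_scores) RM-implied P(X=1 | raw score)


def graphical_test_data(X, split_labels) -> GraphicalTestData:
    """Item difficulty pairs for the graphical model test (identity line is
    the null reference) plus empirical vs model-implied ICC data."""
    X = np.asarray(X, dtype=float)
    labels = _clean_groups(split_labels)
    groups = pd_unique([g for g in labels if g is not None])
    if len(groups) != 2:
        raise EstimationError("graphical test needs exactly two groups")
    f1 = fit_rm_cml(X[labels == groups[0]])
    f2 = fit_rm_cml(X[labels == groups[1]])
    radius = T_CRIT * np.sqrt(f1.se**2 + f2.se**2)

    # empirical ICC per raw score on complete rows, vs conditional model curve
    complete = ~np.isnan(X).any(axis=1)
    Xc = X[complete]
    k = X.shape[1]
    pooled = fit_rm_cml(X)
    eps = np.exp(-pooled.beta)
    g = esf(eps)
    g_loo = esf_leave_one_out(eps)
    scores = np.arange(1, k)
    obs = np.full((k, len(scores)), np.nan)
    mod = np.full((k, len(scores)), np.nan)
    raw = Xc.sum(axis=1)
    for s_idx, r in enumerate(scores):
        sel = raw == r
        mod[:, s_idx] = eps * g_loo[:, r - 1] / g[r]
        if sel.any():
            obs[:, s_idx] = Xc[sel].mean(axis=0)
    return GraphicalTestData(f1.beta, f2.beta, f1.se, f2.se, radius, scores, obs, mod)


# ---------------------------------------------------------------------------
# Facets DIF for the PCM


@dataclass
class DIFRecord:
    item: int
    tau: np.ndarray          # per-group interaction, sums to zero
    z: float
    p: float
    significant: bool


def dif_facets_pcm(X, group_labels, alpha: float = ALPHA,
                   n_quadrature: int = 31, max_iter: int = 200) -> list[DIFRecord]:
    """Facets PCM (item + group + item x group): the interaction tau_ig is
    the DIF magnitude, identified by double sum-to-zero; per-item Wald test
    at the given alpha from empirical-Fisher standard errors."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(group_labels)
    model = PartialCreditModel(n_quadrature=n_quadrature, max_iter=max_iter)
    model.fit(X, groups=labels)
    k = X.shape[1]
    G = model.group_shift_.shape[1]
    if G != 2:
        raise EstimationError("facets Wald test implemented for two groups")

    # empirical Fisher over (delta, free shifts, sigma)
    m1 = model.delta_.shape[1]
    s_free = model.group_shift_[:, 0]     # s_i2 = -s_i1
    params = np.concatenate([model.delta_.ravel(), s_free, [model.sigma_]])

    def person_ll(p):
        delta = p[: k * m1].reshape(k, m1)
        s1 = p[k * m1: k * m1 + k]
        sigma = p[-1]
        shifts = np.column_stack([s1, -s1])
        from scipy.special import roots_hermitenorm
        t, w = roots_hermitenorm(model.n_quadrature)
        w = w / w.sum()
        from .irt import _loglik_persons
        obs = ~np.isnan(X)
        delta_by_group = [delta + shifts[:, g][:, None] for g in range(2)]
        ll, _ = _loglik_persons(X, obs, delta_by_group, model.group_idx_,
                                sigma * t, np.log(w))
        return ll

    h = 1e-4
    scores = np.zeros((X.shape[0], len(params)))
    for j in range(len(params)):
        step = np.zeros_like(params)
        step[j] = h
        scores[:, j] = (person_ll(params + step) - person_ll(params - step)) / (2 * h)
    cov = np.linalg.pinv(scores.T @ scores)
    se_s = np.sqrt(np.clip(np.diag(cov)[k * m1: k * m1 + k], 1e-12, None))

    # tau_i1 = s_i1 - mean_i(s_i1); its variance via the centering matrix
    C = np.eye(k) - np.ones((k, k)) / k
    cov_s = cov[k * m1: k * m1 + k, k * m1: k * m1 + k]
    cov_tau = C @ cov_s @ C.T
    se_tau = np.sqrt(np.clip(np.diag(cov_tau), 1e-12, None))

    records = []
    for i in range(k):
        tau_i = model.tau_[i]
        z = float(tau_i[0] / se_tau[i])
        p = float(2 * stats.norm.sf(abs(z)))
        records.append(DIFRecord(i, tau_i, z, p, p < alpha))
    return records


# ---------------------------------------------------------------------------
# Well-conditioned data (Fischer)


def well_conditioned_check(X):
    """Fischer's criterion for unique CML estimates on dichotomous data.

    Builds the digraph with an edge i -> j whenever some person scored 1 on
    item i and 0 on item j; the data are well-conditioned iff the digraph
    is strongly connected.  If not, returns a witness: the items of a
    source component B — no person scored 1 outside B and 0 inside B, so
    the ordered partition (complement, B) violates the condition.
    """
    X = np.asarray(X, dtype=float)
    k = X.shape[1]
    G = nx.DiGraph()
    G.add_nodes_from(range(k))
    one = X == 1.0
    zero = X == 0.0
    for i in range(k):
        for j in range(k):
            if i != j and bool((one[:, i] & zero[:, j]).any()):
                G.add_edge(i, j)
    if nx.is_strongly_connected(G):
        return True, None
    cond = nx.condensation(G)
    for node in cond.nodes:
        if cond.in_degree(node) == 0:
            witness = set(cond.nodes[node]["members"])
            return False, witness
    return False, set(range(k))  # unreachable


# ---------------------------------------------------------------------------
# Global local-independence test (margin-preserving resampling)


@numba.njit(cache=False)
def _curveball_kernel(mat, n_trades, seed):  # pragma: no cover - jit body
    np.random.seed(seed)
    n, k = mat.shape
    pool = np.empty(k, np.int64)
    for _ in range(n_trades):
        i = np.random.randint(0, n)
        j = np.random.randint(0, n)
        if i == j:
            continue
        cnt = 0
        na = 0
        for c in range(k):
            if mat[i, c] != mat[j, c]:
                pool[cnt] = c
                cnt += 1
                if mat[i, c] == 1:
                    na += 1
        if cnt < 2:
            continue
        for t in range(cnt - 1, 0, -1):  # Fisher-Yates shuffle of the pool
            r = np.random.randint(0, t + 1)
            tmp = pool[t]
            pool[t] = pool[r]
            pool[r] = tmp
        for idx in range(cnt):
            c = pool[idx]
            if idx < na:
                mat[i, c] = 1
                mat[j, c] = 0
            else:
                mat[i, c] = 0
                mat[j, c] = 1


def _curveball(mat: np.ndarray, n_trades: int, seed: int) -> None:
    """In-place curveball trades: each trade picks two rows and randomly
    re-distributes the items they do not share, preserving every row and
    column sum.  Mixes much faster than single checkerboard swaps because
    one trade can move several cells."""
    _curveball_kernel(mat, n_trades, seed)


@dataclass
class GlobalLDResult:
    statistic: float
    p: float
    n_samples: int
    excluded_persons: int
    excluded_items: int


def global_local_independence_rm(X, n_samples: int = 300, burn_in: int = 20000,
                                 thin: int = 2000, seed: int = 0) -> GlobalLDResult:
    """Sum of absolute deviations between observed inter-item correlations
    and their expectation over binary matrices with the observed margins,
    sampled by curveball MCMC; p is the share of sampled statistics at
    least as large as the observed one (including the observed matrix in
    the reference set).  ``burn_in`` and ``thin`` count curveball trades."""
    X = np.asarray(X, dtype=float)
    complete = ~np.isnan(X).any(axis=1)
    mat = X[complete].copy()
    raw = mat.sum(axis=1)
    keep_rows = (raw > 0) & (raw < mat.shape[1])
    excluded_persons = int((~keep_rows).sum()) + int((~complete).sum())
    mat = mat[keep_rows]
    col = mat.sum(axis=0)
    keep_cols = (col > 0) & (col < mat.shape[0])
    excluded_items = int((~keep_cols).sum())
    mat = mat[:, keep_cols]
    if mat.shape[1] < 3 or mat.shape[0] < 10:
        raise EstimationError("too few rows/items after excluding degenerate margins")

    k = mat.shape[1]
    iu = np.triu_indices(k, 1)
    r_obs = np.corrcoef(mat, rowvar=False)[iu]

    work = mat.astype(np.int8)
    seed = int(seed) % (2**31 - 1)
    _curveball(work, burn_in, seed)
    samples = np.empty((n_samples, len(r_obs)))
    for s in range(n_samples):
        _curveball(work, thin, seed + 1 + s)
        samples[s] = np.corrcoef(work.astype(float), rowvar=False)[iu]
    r_bar = samples.mean(axis=0)
    t_obs = float(np.abs(r_obs - r_bar).sum())
    t_samp = np.abs(samples - r_bar[None, :]).sum(axis=1)
    p = float((1 + (t_samp >= t_obs).sum()) / (1 + n_samples))
    return GlobalLDResult(t_obs, p, n_samples, excluded_persons, excluded_items)


# ---------------------------------------------------------------------------
# Split helpers and subsample harness


def education_split(education, threshold: int = 4) -> np.ndarray:
    """Binary education split: ISCED >= threshold counts as higher."""
    edu = np.asarray(education, dtype=float)
    return np.where(edu >= threshold, "higher", "lower").astype(object)


def random_subsamples(n: int, n_subsamples: int = 4, seed: int = 0) -> list[np.ndarray]:
    """Disjoint random person subsamples for replication runs."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, n_subsamples)]
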