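"""Classical psychometrics: internal consistency, latent-normal
correlations, and single-factor confirmatory factor analysis.

Cronbach's alpha is the familiar lower bound on internal consistency on
the observed codes.  Ordinal alpha applies the standardized-alpha formula
to a polychoric (polytomous items) or tetrachoric (dichotomized items)
correlation matrix, i.e. to the correlations of the latent continuous
variables assumed to underlie the ordinal responses.  The single-factor
CFA checks whether one latent dimension reproduces those correlations;
fit is summarised by SRMSR, RMSEA, CFI and TLI with the conventional
target bands SRMSR <= 0.08, RMSEA <= 0.06, CFI/TLI >= 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .base import BaseEstimator, check_is_fitted
from .errors import EstimationError

RHO_CAP = 0.999  # ML estimate capped to avoid boundary failures on degenerate tables


def cronbach_alpha(data: np.ndarray) -> float:
    """alpha = k/(k-1) (1 - sum of item variances / variance of sum scores),
    on listwise-complete cases with n-1 variance denominators."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise EstimationError("alpha needs at least two items")
    complete = ~np.isnan(data).any(axis=1)
    x = data[complete]
    if x.shape[0] < 3:
        raise EstimationError("alpha needs at least 3 complete cases")
    k = x.shape[1]
    total_var = np.var(x.sum(axis=1), ddof=1)
    if total_var <= 0:
        raise EstimationError("zero total variance; alpha undefined")
    return float(k / (k - 1) * (1.0 - x.var(axis=0, ddof=1).sum() / total_var))


# ---------------------------------------------------------------------------
# Polychoric / tetrachoric correlations


def _thresholds(x: np.ndarray, n_categories: int) -> np.ndarray:
    """Inverse-normal thresholds from cumulative category proportions."""
    x = x[~np.isnan(x)]
    counts = np.array([(x == c).sum() for c in range(n_categories)], dtype=float)
    cum = np.cumsum(counts)[:-1] / counts.sum()
    cum = np.clip(cum, 1e-10, 1 - 1e-10)
    return stats.norm.ppf(cum)


def _bvn_cell_probs(thr_a: np.ndarray, thr_b: np.ndarray, rho: float) -> np.ndarray:
    """Rectangle probabilities of the bivariate standard normal for the cell
    grid defined by two (finite, clipped) threshold vectors."""
    big = 8.0  # effectively +/- infinity for the standard normal
    a = np.concatenate([[-big], np.clip(thr_a, -big, big), [big]])
    b = np.concatenate([[-big], np.clip(thr_b, -big, big), [big]])
    aa, bb = np.meshgrid(a, b, indexing="ij")
    pts = np.column_stack([aa.ravel(), bb.ravel()])
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]],
                                    allow_singular=True)
    cdf = np.asarray(mvn.cdf(pts)).reshape(aa.shape)
    p = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
    return np.clip(p, 1e-12, None)


def polychoric_pair(x: np.ndarray, y: np.ndarray, n_categories: int) -> float:
    """Two-step ML estimate of the latent correlation of one item pair."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok].astype(int), y[ok].astype(int)
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return np.nan
    table = np.zeros((n_categories, n_categories))
    np.add.at(table, (x, y), 1.0)
    thr_a = _thresholds(x.astype(float), n_categories)
    thr_b = _thresholds(y.astype(float), n_categories)

    def nll(rho):
        return -float((table * np.log(_bvn_cell_probs(thr_a, thr_b, rho))).sum())

    res = optimize.minimize_scalar(nll, bounds=(-RHO_CAP, RHO_CAP), method="bounded",
                                   options={"xatol": 1e-5})
    return float(res.x)


@dataclass
class CorrelationEstimate:
    matrix: np.ndarray
    kind: str                       # pearson | tetrachoric | polychoric
    thresholds: list = field(default_factory=list)
    failed_items: list = field(default_factory=list)


def polychoric_matrix(data: np.ndarray, n_categories: int = 4,
                      kind: str | None = None) -> CorrelationEstimate:
    """Pairwise-complete latent-correlation matrix.

    ``data`` holds integer category codes 0..m-1 (NaN missing).  With
    m = 2 the estimate is the tetrachoric correlation.  Items with a
    single observed category are flagged and their row/column set to NaN.
    """
    data = np.asarray(data, dtype=float)
    k = data.shape[1]
    if kind is None:
        kind = "tetrachoric" if n_categories == 2 else "polychoric"
    failed = []
    thresholds = []
    for j in range(k):
        col = data[:, j]
        obs = np.unique(col[~np.isnan(col)])
        if obs.size < 2:
            failed.append(j)
            thresholds.append(None)
        else:
            thresholds.append(_thresholds(col, n_categories))
    mat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            if i in failed or j in failed:
                mat[i, j] = mat[j, i] = np.nan
            else:
                mat[i, j] = mat[j, i] = polychoric_pair(data[:, i], data[:, j], n_categories)
    return CorrelationEstimate(mat, kind, thresholds, failed)


def ordinal_alpha(corr: CorrelationEstimate | np.ndarray) -> float:
    """Standardized alpha on the latent correlation matrix:
    k r_bar / (1 + (k-1) r_bar)."""
    mat = corr.matrix if isinstance(corr, CorrelationEstimate) else np.asarray(corr)
    k = mat.shape[0]
    off = mat[np.triu_indices(k, 1)]
    if np.isnan(off).any():
        raise EstimationError("ordinal alpha needs a complete correlation matrix")
    r_bar = float(off.mean())
    denom = 1.0 + (k - 1) * r_bar
    if denom <= 0:
        raise EstimationError("mean inter-item correlation too negative; alpha undefined")
    return float(k * r_bar / denom)


# ---------------------------------------------------------------------------
# Single-factor CFA


@dataclass
class CFAFit:
    loadings: np.ndarray
    residuals: np.ndarray
    srmsr: float
    rmsea: float
    cfi: float
    tli: float
    statistic: float
    df: int
    n: int
    converged: bool
    heywood: bool


class SingleFactorCFA(BaseEstimator):
    """One-factor CFA on a (polychoric) correlation matrix.

    Loadings minimise sum_{i<j} w_ij (r_ij - l_i l_j)^2 with w = 1 (ULS) or
    w = inverse approximate asymptotic variance of r_ij (DWLS).  The test
    statistic is a mean-scaled approximation (documented in the methods
    note); SRMSR and the loadings are exact per their formulas.

    Parameters
    ----------
    estimator : {"uls", "dwls"}
    """

    def __init__(self, estimator: str = "dwls"):
        self.estimator = estimator

    def fit(self, corr, n: int):
        mat = corr.matrix if isinstance(corr, CorrelationEstimate) else np.asarray(corr, dtype=float)
        k = mat.shape[0]
        if n < 50:
            raise EstimationError("CFA needs n >= 50")
        iu = np.triu_indices(k, 1)
        r = mat[iu]
        if np.isnan(r).any():
            raise EstimationError("CFA needs a complete correlation matrix")
        avar = (1.0 - r**2) ** 2 / n
        avar = np.clip(avar, 1e-10, None)
        w = 1.0 / avar if self.estimator == "dwls" else np.ones_like(r)

        # start at the square-root of the first principal component structure
        vals, vecs = np.linalg.eigh(mat)
        lam0 = vecs[:, -1] * np.sqrt(max(vals[-1], 1e-6))
        if lam0.sum() < 0:
            lam0 = -lam0

        def resid(lam):
            return np.sqrt(w) * (r - lam[iu[0]] * lam[iu[1]])

        sol = optimize.least_squares(resid, lam0, method="lm", xtol=1e-12, ftol=1e-12)
        lam = sol.x
        e = r - lam[iu[0]] * lam[iu[1]]

        self.loadings_ = lam
        self.residuals_ = np.zeros((k, k))
        self.residuals_[iu] = e
        self.residuals_ += self.residuals_.T
        self.converged_ = bool(sol.success)
        self.heywood_ = bool((np.abs(lam) > 1.0).any())
        self.srmsr_ = float(np.sqrt(np.mean(e**2)))

        # mean-scaled test statistic with inverse-avar weights
        t_stat = float(np.sum(e**2 / avar))
        df = k * (k - 1) // 2 - k
        t_base = float(np.sum(r**2 / avar))
        df_base = k * (k - 1) // 2
        self.statistic_, self.df_, self.n_ = t_stat, df, n
        self.rmsea_ = float(np.sqrt(max(0.0, (t_stat - df) / (df * (n - 1)))))
        denom = max(t_base - df_base, t_stat - df, 0.0)
        self.cfi_ = 1.0 if denom == 0 else float(1.0 - max(t_stat - df, 0.0) / denom)
        base_ratio = t_base / df_base
        self.tli_ = float((base_ratio - t_stat / df) / (base_ratio - 1.0)) if base_ratio > 1 else 1.0
        self.tli_ = min(self.tli_, 1.0)
        return self

    def result(self) -> CFAFit:
        check_is_fitted(self, "loadings_")
        return CFAFit(self.loadings_, self.residuals_, self.srmsr_, self.rmsea_,
                      self.cfi_, self.tli_, self.statistic_, self.df_, self.n_,
                      self.converged_, self.heywood_)


def cfa_single_factor(corr, n: int, estimator: str = "dwls") -> CFAFit:
    """Functional wrapper over :class:`SingleFactorCFA`."""
    return SingleFactorCFA(estimator=estimator).fit(corr, n).result()
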