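"""Discriminant and concurrent predictive validity.

Discriminant validity compares the general health-literacy score with
special-literacy scores (digital, navigational, ...) through weighted
Pearson correlations; values in (0.4, 0.7) indicate related but distinct
constructs usable together in regressions.  Concurrent validity fits
weighted linear regressions: the HL score on five social determinants
(the social-gradient model), and self-perceived health on the HL score
plus the determinants.  Predictors enter as numeric variables; we report
unstandardized b, standardized beta (via weighted standard deviations)
and the weighted R^2, with listwise deletion of incomplete cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import EstimationError
from .instrument import ResponseMatrix
from .scoring import compute_scores, subdimension_subsets, subscale_scores

DETERMINANTS = ("sex", "age", "education", "status", "findep")
DISCRIMINANT_BAND = (0.4, 0.7)


def weighted_pearson(x, y, w=None) -> float:
    """Weighted Pearson correlation on pairwise-complete cases."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(x) if w is None else np.asarray(w, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 3:
        raise EstimationError("weighted correlation needs >= 3 complete pairs")
    x, y, w = x[ok], y[ok], w[ok]
    mx, my = np.average(x, weights=w), np.average(y, weights=w)
    cov = np.average((x - mx) * (y - my), weights=w)
    vx = np.average((x - mx) ** 2, weights=w)
    vy = np.average((y - my) ** 2, weights=w)
    if vx <= 0 or vy <= 0:
        raise EstimationError("zero variance; correlation undefined")
    return float(cov / np.sqrt(vx * vy))


@dataclass
class RegressionResult:
    outcome: str
    predictors: list
    b: np.ndarray              # unstandardized coefficients
    beta: np.ndarray           # standardized coefficients
    intercept: float
    r_squared: float
    n_valid: int
    n_total: int
    weighted: bool


def weighted_ols(y, X: pd.DataFrame, w=None, outcome: str = "y") -> RegressionResult:
    """Weighted least squares with listwise deletion and standardized
    coefficients beta_j = b_j * sd_w(x_j) / sd_w(y)."""
    y = np.asarray(y, dtype=float)
    Xm = X.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    n_total = len(y)
    w = np.ones(n_total) if w is None else np.asarray(w, dtype=float)
    ok = ~np.isnan(y) & ~np.isnan(Xm).any(axis=1) & ~np.isnan(w)
    y, Xm, w = y[ok], Xm[ok], w[ok]
    n_valid = int(ok.sum())
    if n_valid <= Xm.shape[1] + 1:
        raise EstimationError("too few complete cases for regression")
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(n_valid), Xm]))
    if rank < Xm.shape[1] + 1:
        sds = Xm.std(axis=0)
        bad = [c for c, s in zip(X.columns, sds) if s == 0]
        raise EstimationError(f"design matrix is rank deficient (suspect columns: {bad})")
    model = sm.WLS(y, sm.add_constant(Xm), weights=w).fit()
    b = model.params[1:]
    intercept = float(model.params[0])

    def wsd(v):
        mu = np.average(v, weights=w)
        return np.sqrt(np.average((v - mu) ** 2, weights=w))

    sd_y = wsd(y)
    beta = np.array([b[j] * wsd(Xm[:, j]) / sd_y for j in range(Xm.shape[1])])
    # weighted R^2: 1 - SSR_w / SST_w
    resid = y - model.fittedvalues
    mu_y = np.average(y, weights=w)
    r2 = float(1.0 - np.sum(w * resid**2) / np.sum(w * (y - mu_y) ** 2))
    return RegressionResult(outcome, list(X.columns), np.asarray(b), beta, intercept,
                            r2, n_valid, n_total, w is not None)


def _determinant_frame(cov: pd.DataFrame) -> pd.DataFrame:
    """Numeric codings for the five social determinants (female = 1)."""
    out = pd.DataFrame(index=cov.index)
    sex = cov["sex"]
    out["sex"] = (sex == "female").astype(float) if sex.dtype == object else sex.astype(float)
    for c in ("age", "education", "status", "findep"):
        out[c] = pd.to_numeric(cov[c], errors="coerce")
    return out


def concurrent_validity_models(rm: ResponseMatrix, score_type: str = "D",
                               scores: pd.DataFrame | None = None):
    """The two concurrent-validity regressions for one score type:

    model 1 — HL score on the five determinants (social gradient);
    model 2 — self-perceived health (1 = very good .. 5 = very bad) on the
    HL score plus the determinants.
    """
    if scores is None:
        scores = compute_scores(rm)
    hl = scores[f"score_{score_type.upper()}"].to_numpy(dtype=float)
    det = _determinant_frame(rm.covariates)
    m1 = weighted_ols(hl, det, rm.weights, outcome=f"score_{score_type.upper()}")
    X2 = det.copy()
    X2.insert(0, "hl_score", hl)
    health = pd.to_numeric(rm.covariates["health"], errors="coerce").to_numpy(dtype=float)
    m2 = weighted_ols(health, X2, rm.weights, outcome="health")
    return m1, m2


@dataclass
class DiscriminantReport:
    pairs: list = field(default_factory=list)  # (name, r, within_band, position)

    def add(self, name: str, r: float):
        lo, hi = DISCRIMINANT_BAND
        position = "within" if lo < r < hi else ("below" if r <= lo else "above")
        self.pairs.append((name, float(r), position == "within", position))


def discriminant_check(score, special: pd.DataFrame, w=None) -> DiscriminantReport:
    """Weighted correlations of the general score with each special score,
    flagged against the (0.4, 0.7) band."""
    report = DiscriminantReport()
    for name in special.columns:
        report.add(name, weighted_pearson(score, special[name].to_numpy(), w))
    return report


def shortform_representation(rm_long: ResponseMatrix, q12_item_ids,
                             subdimensions: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Correlations of long-form scores with their short-form (12-item)
    counterparts, overall and per conceptual subdimension.

    Returns a table with one row per (score type, scope) pair.
    """
    ids_long = rm_long.instrument.item_ids
    missing = [i for i in q12_item_ids if i not in ids_long]
    if missing:
        raise EstimationError(f"long form does not contain short-form items {missing}")
    if subdimensions is None:
        subdimensions = subdimension_subsets(rm_long)

    subsets_long = {"general": list(ids_long), **subdimensions}
    subsets_short = {"general": list(q12_item_ids)}
    for name, ids in subdimensions.items():
        subsets_short[name] = [i for i in ids if i in q12_item_ids]

    long_scores = subscale_scores(rm_long, subsets_long)
    short_scores = subscale_scores(rm_long, {k: v for k, v in subsets_short.items() if v})
    rows = []
    for name in subsets_long:
        for typ in ("D", "P"):
            col_l, col_s = f"{name}_{typ}", f"{name}_{typ}"
            if col_s not in short_scores.columns:
                continue
            r = weighted_pearson(long_scores[col_l].to_numpy(),
                                 short_scores[col_s].to_numpy(), rm_long.weights)
            rows.append({"scope": name, "type": typ, "r": r})
    return pd.DataFrame(rows)
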