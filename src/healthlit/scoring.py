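"""HLS19-Q12 score computation and categorical level assignment.

Two summary scores are defined on the 12 four-category items:

* type D — the percentage (0..100) of validly answered items rated "easy"
  or "very easy" (implicit dichotomization);
* type P — the sum of the raw codes (1..4) rescaled linearly to 0..100.

Either score exists only if at least 80% of the items carry valid
responses.  Four ordered levels (excellent / sufficient / problematic /
inadequate) are assigned by separate rulesets for the two score types; the
union of problematic and inadequate is "limited" health literacy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError
from .instrument import ResponseMatrix

LEVELS = ("excellent", "sufficient", "problematic", "inadequate")


@dataclass(frozen=True)
class LevelRuleSet:
    """Cut-offs as the printed decimals.

    The D-rules operate on response-category percentages over valid items
    and are evaluated excellent -> sufficient -> inadequate, with
    problematic as the residual.  The P-rules partition [0, 100].
    """

    d_excellent_ve_min: float = 50.0       # % "very easy" >= this
    d_excellent_diff_max: float = 8.334    # % "difficult"+"very difficult" < this
    d_sufficient_easy_min: float = 83.33   # % "easy"+"very easy" > this
    d_inadequate_ve_max: float = 8.334     # % "very easy" < this
    d_inadequate_diff_min: float = 50.0    # % "difficult"+"very difficult" >= this
    p_excellent: float = 83.33             # score > this
    p_sufficient: float = 66.67            # this < score <= p_excellent
    p_problematic: float = 50.0            # this < score <= p_sufficient
    validity_pct: float = 80.0             # minimum % of items with valid responses


DEFAULT_RULES = LevelRuleSet()


def _valid_mask(rm: ResponseMatrix) -> np.ndarray:
    return ~np.isnan(rm.responses)


def _passes_validity(rm: ResponseMatrix, rules: LevelRuleSet) -> np.ndarray:
    valid = _valid_mask(rm).sum(axis=1)
    return 100.0 * valid / rm.n_items >= rules.validity_pct


def score_type_d(rm: ResponseMatrix, rules: LevelRuleSet = DEFAULT_RULES) -> np.ndarray:
    """Percent of valid responses in {3, 4}; NaN below the validity threshold."""
    valid = _valid_mask(rm)
    n_valid = valid.sum(axis=1)
    easy = np.nansum(rm.responses >= 3, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = 100.0 * easy / n_valid
    score[~_passes_validity(rm, rules)] = np.nan
    return score


def score_type_p(rm: ResponseMatrix, rules: LevelRuleSet = DEFAULT_RULES) -> np.ndarray:
    """Sum of raw codes rescaled to 0..100.

    Complete rows use 100 * (sum - k) / (3k); rows with missing items (but
    above the validity threshold) use the equivalent mean-based form
    100 * (mean - 1) / 3, which extends the rescaling to incomplete rows.
    """
    mean = np.nanmean(np.where(_valid_mask(rm), rm.responses, np.nan), axis=1)
    score = 100.0 * (mean - 1.0) / 3.0
    score[~_passes_validity(rm, rules)] = np.nan
    return score


def _category_percentages(rm: ResponseMatrix) -> dict[str, np.ndarray]:
    """Per-person percentages of each response category over valid items."""
    valid = _valid_mask(rm)
    n_valid = valid.sum(axis=1).astype(float)
    n_valid[n_valid == 0] = np.nan
    resp = rm.responses
    return {
        "ve": 100.0 * np.nansum(resp == 4, axis=1) / n_valid,
        "easy_total": 100.0 * np.nansum(resp >= 3, axis=1) / n_valid,
        "diff_total": 100.0 * np.nansum(resp <= 2, axis=1) / n_valid,
    }


def assign_level_d(rm: ResponseMatrix, rules: LevelRuleSet = DEFAULT_RULES) -> np.ndarray:
    """Type D levels from category percentages over valid items.

    Precedence: excellent, then sufficient, then inadequate; everyone else
    is problematic.  Missing below the validity threshold.
    """
    pct = _category_percentages(rm)
    n = rm.n_persons
    out = np.full(n, None, dtype=object)
    ok = _passes_validity(rm, rules)
    excellent = (pct["ve"] >= rules.d_excellent_ve_min) & (pct["diff_total"] < rules.d_excellent_diff_max)
    sufficient = pct["easy_total"] > rules.d_sufficient_easy_min
    inadequate = (pct["ve"] < rules.d_inadequate_ve_max) & (pct["diff_total"] >= rules.d_inadequate_diff_min)
    out[ok] = "problematic"
    out[ok & inadequate] = "inadequate"
    out[ok & sufficient] = "sufficient"
    out[ok & excellent] = "excellent"
    return out


def assign_level_p(score_p: np.ndarray, rules: LevelRuleSet = DEFAULT_RULES) -> np.ndarray:
    """Type P levels from the score alone; the bands partition [0, 100]."""
    score_p = np.asarray(score_p, dtype=float)
    out = np.full(score_p.shape, None, dtype=object)
    ok = ~np.isnan(score_p)
    out[ok & (score_p <= rules.p_problematic)] = "inadequate"
    out[ok & (score_p > rules.p_problematic) & (score_p <= rules.p_sufficient)] = "problematic"
    out[ok & (score_p > rules.p_sufficient) & (score_p <= rules.p_excellent)] = "sufficient"
    out[ok & (score_p > rules.p_excellent)] = "excellent"
    return out


def limited_flag(levels: np.ndarray) -> np.ndarray:
    """Limited health literacy = problematic or inadequate (None propagates)."""
    out = np.full(levels.shape, None, dtype=object)
    known = np.array([lv is not None for lv in levels])
    out[known] = np.isin(levels[known].astype(str), ("problematic", "inadequate"))
    return out


class HLS19Scorer:
    """Transformer computing per-person scores, levels and limited flags.

    Parameters
    ----------
    rules : LevelRuleSet
        Cut-offs and validity threshold; defaults to the published rules.
    """

    def __init__(self, rules: LevelRuleSet = DEFAULT_RULES):
        self.rules = rules

    def get_params(self, deep=True):
        return {"rules": self.rules}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, rm: ResponseMatrix, y=None):
        self.n_items_ = rm.n_items
        return self

    def transform(self, rm: ResponseMatrix) -> pd.DataFrame:
        d = score_type_d(rm, self.rules)
        p = score_type_p(rm, self.rules)
        level_d = assign_level_d(rm, self.rules)
        level_p = assign_level_p(p, self.rules)
        return pd.DataFrame({
            "score_D": d, "score_P": p,
            "level_D": level_d, "level_P": level_p,
            "limited_D": limited_flag(level_d), "limited_P": limited_flag(level_p),
        })

    def fit_transform(self, rm: ResponseMatrix, y=None) -> pd.DataFrame:
        return self.fit(rm).transform(rm)


def compute_scores(rm: ResponseMatrix, rules: LevelRuleSet = DEFAULT_RULES) -> pd.DataFrame:
    """Functional wrapper over :class:`HLS19Scorer`."""
    return HLS19Scorer(rules).fit_transform(rm)


def subscale_scores(rm: ResponseMatrix, subsets: dict[str, list[str]],
                    rules: LevelRuleSet = DEFAULT_RULES) -> pd.DataFrame:
    """Type D and P scores per named item subset (same formulas; the 80%
    validity rule applies to the subset's own item count)."""
    known = set(rm.instrument.item_ids)
    out = {}
    for name, ids in subsets.items():
        unknown = [i for i in ids if i not in known]
        if unknown:
            raise SchemaError(f"subset {name!r}: unknown item ids {unknown}")
        sub = rm.select_items(ids)
        out[f"{name}_D"] = score_type_d(sub, rules)
        out[f"{name}_P"] = score_type_p(sub, rules)
    return pd.DataFrame(out)


def subdimension_subsets(rm: ResponseMatrix) -> dict[str, list[str]]:
    """Item subsets for the three domains and four processing stages."""
    subsets: dict[str, list[str]] = {}
    for it in rm.instrument.items:
        subsets.setdefault(it.domain, []).append(it.id)
        subsets.setdefault(it.stage, []).append(it.id)
    return subsets


def weighted_quantile(values, q, weights) -> np.ndarray:
    """Weighted quantiles by inverting the weighted empirical CDF."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    ok = ~np.isnan(values)
    values, weights = values[ok], weights[ok]
    order = np.argsort(values)
    values, weights = values[order], weights[order]
    cum = np.cumsum(weights) - 0.5 * weights
    cum /= weights.sum()
    return np.interp(np.atleast_1d(q), cum, values)


def describe_scores(scores: pd.DataFrame, weights=None) -> dict:
    """Weighted mean / sd / quartiles per score and level shares (percent of
    non-missing; shares sum to 100)."""
    n = len(scores)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    out: dict = {}
    for col in ("score_D", "score_P"):
        v = scores[col].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        vv, ww = v[ok], w[ok]
        mean = float(np.average(vv, weights=ww))
        var = float(np.average((vv - mean) ** 2, weights=ww))
        q25, q50, q75 = weighted_quantile(vv, [0.25, 0.5, 0.75], ww)
        out[col] = {"n": int(ok.sum()), "mean": mean, "sd": float(np.sqrt(var)),
                    "q25": float(q25), "median": float(q50), "q75": float(q75)}
    for col in ("level_D", "level_P"):
        lv = scores[col].to_numpy(dtype=object)
        known = np.array([x is not None for x in lv])
        ww = w[known]
        shares = {}
        for level in LEVELS:
            shares[level] = float(100.0 * ww[(lv[known] == level)].sum() / ww.sum()) if ww.sum() else float("nan")
        out[col] = shares
    return out
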