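"""Instrument definition, respondent data model, IO and recodings.

The HLS19-Q12 instrument asks 12 perceived-difficulty items, one for each
cell of the 3x4 health-literacy matrix (domains: health care, disease
prevention, health promotion; processing stages: access, understand,
appraise, apply).  Responses are coded 1 = "very difficult", 2 =
"difficult", 3 = "easy", 4 = "very easy"; anything else counts as missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    DegenerateSplitError,
    EmptyInputError,
    EmptySubgroupError,
    SchemaError,
)

logger = logging.getLogger("healthlit")

DOMAINS = ("health_care", "disease_prevention", "health_promotion")
STAGES = ("access", "understand", "appraise", "apply")

#: Covariate roles recognised throughout the package.
COVARIATE_ROLES = ("sex", "age", "education", "status", "findep", "health", "mode", "country")


@dataclass(frozen=True)
class Item:
    id: str
    text: str
    domain: str
    stage: str

    def __post_init__(self):
        if self.domain not in DOMAINS:
            raise SchemaError(f"unknown domain {self.domain!r} for item {self.id!r}")
        if self.stage not in STAGES:
            raise SchemaError(f"unknown stage {self.stage!r} for item {self.id!r}")


@dataclass(frozen=True)
class InstrumentSpec:
    """An ordered item set with a fixed number of ordered response categories."""

    items: tuple[Item, ...]
    n_categories: int = 4

    def __post_init__(self):
        ids = [it.id for it in self.items]
        if len(set(ids)) != len(ids):
            raise SchemaError("item ids must be unique")
        if self.n_categories < 2:
            raise SchemaError("need at least two response categories")

    @property
    def item_ids(self) -> list[str]:
        return [it.id for it in self.items]

    @property
    def n_items(self) -> int:
        return len(self.items)

    def validate_matrix_coverage(self) -> None:
        """Check the canonical 12-item layout: each (domain, stage) cell once."""
        cells = {(it.domain, it.stage) for it in self.items}
        if len(self.items) != 12 or len(cells) != 12:
            raise SchemaError(
                "canonical HLS19-Q12 layout requires exactly 12 items covering "
                "each (domain, stage) cell of the 3x4 matrix exactly once"
            )

    def subset(self, item_ids) -> "InstrumentSpec":
        by_id = {it.id: it for it in self.items}
        missing = [i for i in item_ids if i not in by_id]
        if missing:
            raise SchemaError(f"unknown item ids: {missing}")
        return InstrumentSpec(tuple(by_id[i] for i in item_ids), self.n_categories)


def hls19_q12() -> InstrumentSpec:
    """The canonical 12-item short-form instrument."""
    texts = [
        ("hl1", "find out where to get professional help when you are ill", "health_care", "access"),
        ("hl2", "understand information about what to do in a medical emergency", "health_care", "understand"),
        ("hl3", "judge the advantages and disadvantages of different treatment options", "health_care", "appraise"),
        ("hl4", "act on advice from your doctor or pharmacist", "health_care", "apply"),
        ("hl5", "find information on how to handle mental health problems", "disease_prevention", "access"),
        ("hl6", "understand information about recommended health screenings or examinations", "disease_prevention", "understand"),
        ("hl7", "judge if information on unhealthy habits are reliable", "disease_prevention", "appraise"),
        ("hl8", "decide how you can protect yourself from illness using information from the mass media", "disease_prevention", "apply"),
        ("hl9", "find information on healthy lifestyles", "health_promotion", "access"),
        ("hl10", "understand advice concerning your health from family or friends", "health_promotion", "understand"),
        ("hl11", "judge how your housing conditions may affect your health and well-being", "health_promotion", "appraise"),
        ("hl12", "make decisions to improve your health and well-being", "health_promotion", "apply"),
    ]
    spec = InstrumentSpec(tuple(Item(*t) for t in texts))
    spec.validate_matrix_coverage()
    return spec


@dataclass
class ResponseMatrix:
    """Persons x items ordinal responses with weights and covariates.

    ``responses`` is a float array with entries in {1..4} and NaN for
    missing.  ``weights`` are positive post-stratification weights carried
    as given (never renormalised here).  ``covariates`` is a DataFrame with
    one row per person; recognised columns are listed in
    :data:`COVARIATE_ROLES` but arbitrary extra columns are allowed.
    """

    responses: np.ndarray
    instrument: InstrumentSpec
    weights: np.ndarray = None
    covariates: pd.DataFrame = None

    def __post_init__(self):
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 2:
            raise SchemaError("responses must be 2-dimensional")
        n, k = self.responses.shape
        if k != self.instrument.n_items:
            raise SchemaError(
                f"{k} response columns but instrument has {self.instrument.n_items} items"
            )
        valid = self.responses[~np.isnan(self.responses)]
        if valid.size and (
            (valid < 1).any() or (valid > self.instrument.n_categories).any()
            or (valid != np.round(valid)).any()
        ):
            raise SchemaError("non-missing responses must be integer codes in 1..n_categories")
        if self.weights is None:
            self.weights = np.ones(n)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (n,):
            raise SchemaError("weights must have one entry per person")
        if (self.weights <= 0).any() or np.isnan(self.weights).any():
            raise SchemaError("weights must be positive")
        if self.covariates is None:
            self.covariates = pd.DataFrame(index=range(n))
        if len(self.covariates) != n:
            raise SchemaError("covariates must have one row per person")

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    def copy(self) -> "ResponseMatrix":
        return ResponseMatrix(
            self.responses.copy(), self.instrument, self.weights.copy(),
            self.covariates.copy().reset_index(drop=True),
        )

    def take(self, index) -> "ResponseMatrix":
        index = np.asarray(index)
        return ResponseMatrix(
            self.responses[index], self.instrument, self.weights[index],
            self.covariates.iloc[index].reset_index(drop=True),
        )

    def select_items(self, item_ids) -> "ResponseMatrix":
        cols = [self.instrument.item_ids.index(i) for i in self.instrument.subset(item_ids).item_ids]
        return ResponseMatrix(
            self.responses[:, cols], self.instrument.subset(item_ids),
            self.weights.copy(), self.covariates.copy().reset_index(drop=True),
        )


@dataclass
class DichotomizedMatrix:
    """Persons x items binary responses (1 = "easy"/"very easy") with provenance flag."""

    responses: np.ndarray
    instrument: InstrumentSpec
    weights: np.ndarray = None
    covariates: pd.DataFrame = None
    dichotomized: bool = True

    def __post_init__(self):
        self.responses = np.asarray(self.responses, dtype=float)
        n = self.responses.shape[0]
        valid = self.responses[~np.isnan(self.responses)]
        if valid.size and not np.isin(valid, (0.0, 1.0)).all():
            raise SchemaError("dichotomized entries must be 0/1 or missing")
        if self.weights is None:
            self.weights = np.ones(n)
        if self.covariates is None:
            self.covariates = pd.DataFrame(index=range(n))

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    def take(self, index) -> "DichotomizedMatrix":
        index = np.asarray(index)
        return DichotomizedMatrix(
            self.responses[index], self.instrument, np.asarray(self.weights)[index],
            self.covariates.iloc[index].reset_index(drop=True),
        )


# ---------------------------------------------------------------------------
# IO


def load_responses(path, schema, instrument: InstrumentSpec | None = None,
                   sep: str = ",") -> ResponseMatrix:
    """Read a delimited survey table into a validated :class:`ResponseMatrix`.

    ``schema`` maps roles to columns::

        {"items": ["q1", ..., "q12"],          # required, in instrument order
         "weight": "wt",                       # optional
         "covariates": {"sex": "gender", ...}} # optional role -> column map

    Out-of-range response codes (anything not in 1..n_categories, including
    blanks) are converted to missing; the count is logged.
    """
    df = pd.read_csv(path, sep=sep)
    if df.shape[0] == 0:
        raise EmptyInputError(f"{path}: no rows")
    item_cols = schema["items"]
    missing_cols = [c for c in item_cols if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing item columns: {missing_cols}")
    if instrument is None:
        if len(item_cols) == 12:
            instrument = hls19_q12()
        else:
            instrument = InstrumentSpec(tuple(
                Item(c, c, "health_care", "access") for c in item_cols))
    resp = df[item_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    in_range = np.isin(resp, np.arange(1, instrument.n_categories + 1))
    n_bad = int((~in_range & ~np.isnan(resp)).sum())
    if n_bad:
        logger.warning("%d response cells outside 1..%d converted to missing",
                       n_bad, instrument.n_categories)
    resp = np.where(in_range, resp, np.nan)

    weights = None
    if schema.get("weight"):
        wcol = schema["weight"]
        if wcol not in df.columns:
            raise SchemaError(f"missing weight column: {wcol}")
        weights = df[wcol].to_numpy(dtype=float)

    cov_map = schema.get("covariates", {})
    missing_cov = [c for c in cov_map.values() if c not in df.columns]
    if missing_cov:
        raise SchemaError(f"missing covariate columns: {missing_cov}")
    covariates = pd.DataFrame({role: df[col].to_numpy() for role, col in cov_map.items()})
    if covariates.empty:
        covariates = pd.DataFrame(index=range(len(df)))

    return ResponseMatrix(resp, instrument, weights, covariates)


def write_responses(rm: ResponseMatrix, path, sep: str = ",") -> None:
    """Write a ResponseMatrix back to a delimited file (round-trips with
    :func:`load_responses` under the identity schema)."""
    df = pd.DataFrame(rm.responses, columns=rm.instrument.item_ids)
    df["weight"] = rm.weights
    for c in rm.covariates.columns:
        df[c] = rm.covariates[c].to_numpy()
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Recodings


def dichotomize(rm: ResponseMatrix) -> DichotomizedMatrix:
    """Merge "very easy"/"easy" (3,4 -> 1) and "very difficult"/"difficult"
    (1,2 -> 0); missing is preserved."""
    resp = rm.responses
    out = np.where(np.isnan(resp), np.nan, (resp >= 3).astype(float))
    return DichotomizedMatrix(out, rm.instrument, rm.weights.copy(),
                              rm.covariates.copy().reset_index(drop=True))


def shift_to_irt_codes(rm: ResponseMatrix) -> np.ndarray:
    """Recode raw categories 1..m to IRT categories 0..m-1 (missing preserved)."""
    return rm.responses - 1.0


def median_split(values, labels=("low", "high")) -> np.ndarray:
    """Split at the sample median; persons at or below the median go to the
    low group (fixed tie rule).  NaN values yield NaN-propagating labels
    (returned as None entries in an object array)."""
    values = np.asarray(values, dtype=float)
    finite = values[~np.isnan(values)]
    if finite.size < 2 or np.unique(finite).size < 2:
        raise DegenerateSplitError("median split needs at least two distinct values")
    med = float(np.median(finite))
    out = np.empty(values.shape, dtype=object)
    out[:] = None
    out[values <= med] = labels[0]
    out[values > med] = labels[1]
    return out


def subgroup(rm: ResponseMatrix, predicate) -> ResponseMatrix:
    """Row-filter by a predicate on the covariate frame.

    ``predicate`` is either a callable DataFrame -> boolean array, or a
    ``(column, value)`` pair selecting rows with equality.
    """
    if callable(predicate):
        mask = np.asarray(predicate(rm.covariates), dtype=bool)
    else:
        col, value = predicate
        if col not in rm.covariates.columns:
            raise SchemaError(f"no covariate named {col!r}")
        mask = (rm.covariates[col] == value).to_numpy()
    if mask.sum() == 0:
        raise EmptySubgroupError("predicate selected no respondents")
    return rm.take(np.nonzero(mask)[0])
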