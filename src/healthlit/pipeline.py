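"""End-to-end orchestration: simulate or load a survey, then run scoring,
classical psychometrics, IRT estimation, diagnostics and validity checks
into one machine-readable report bundle.

Every stage is optional; a failed stage marks the bundle partial instead
of aborting the run.  All randomness flows from a single seed recorded in
the bundle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import classical, diagnostics, irt, scoring, validity
from .instrument import ResponseMatrix, dichotomize, median_split, shift_to_irt_codes
from .simulate import GeneratorConfig, generate

ALL_STAGES = ("score", "classical", "irt", "diagnostics", "validity")


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = None
    stages: tuple = ALL_STAGES
    seed: int = 0
    n_quadrature: int = 31

    def __post_init__(self):
        if self.generator is None:
            self.generator = GeneratorConfig(seed=self.seed)


@dataclass
class ReportBundle:
    seed: int
    sections: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)

    @property
    def partial(self) -> bool:
        return bool(self.errors)

    def to_json(self, **kwargs) -> str:
        return json.dumps({"seed": self.seed, "partial": self.partial,
                           "sections": self.sections, "errors": self.errors},
                          default=_jsonable, sort_keys=True, **kwargs)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    return str(obj)


def item_difficulty_table(rm: ResponseMatrix, weights=None) -> pd.DataFrame:
    """Per-item weighted percentage of "difficult"/"very difficult"
    responses, ordered from easiest to hardest."""
    w = rm.weights if weights is None else np.asarray(weights, dtype=float)
    rows = []
    for j, item_id in enumerate(rm.instrument.item_ids):
        col = rm.responses[:, j]
        ok = ~np.isnan(col)
        pct = 100.0 * np.average((col[ok] <= 2).astype(float), weights=w[ok]) if ok.any() else np.nan
        rows.append({"item": item_id, "pct_difficult": pct})
    return pd.DataFrame(rows).sort_values("pct_difficult").reset_index(drop=True)


def run_pipeline(config: PipelineConfig, rm: ResponseMatrix | None = None) -> ReportBundle:
    """Run the configured stages; deterministic under (config, seed)."""
    bundle = ReportBundle(seed=config.seed)
    dataset = None
    if rm is None:
        dataset = generate(config.generator)
        rm = dataset.rm

    bundle.sections["item_difficulty"] = item_difficulty_table(rm).to_dict(orient="list")

    scores = None
    if "score" in config.stages:
        try:
            scores = scoring.compute_scores(rm)
            bundle.sections["scores"] = scoring.describe_scores(scores, rm.weights)
        except Exception as err:  # noqa: BLE001 - partial bundles by contract
            bundle.errors["score"] = repr(err)

    if "classical" in config.stages:
        try:
            codes = shift_to_irt_codes(rm)
            poly = classical.polychoric_matrix(codes, rm.instrument.n_categories)
            di = dichotomize(rm)
            tet = classical.polychoric_matrix(di.responses, 2)
            fit_poly = classical.cfa_single_factor(poly, rm.n_persons)
            fit_tet = classical.cfa_single_factor(tet, rm.n_persons)
            bundle.sections["classical"] = {
                "cronbach_alpha": classical.cronbach_alpha(rm.responses),
                "cronbach_alpha_dichotomized": classical.cronbach_alpha(di.responses),
                "ordinal_alpha": classical.ordinal_alpha(poly),
                "ordinal_alpha_dichotomized": classical.ordinal_alpha(tet),
                "cfa_polytomous": {"srmsr": fit_poly.srmsr, "rmsea": fit_poly.rmsea,
                                   "cfi": fit_poly.cfi, "tli": fit_poly.tli},
                "cfa_dichotomized": {"srmsr": fit_tet.srmsr, "rmsea": fit_tet.rmsea,
                                     "cfi": fit_tet.cfi, "tli": fit_tet.tli},
            }
        except Exception as err:  # noqa: BLE001
            bundle.errors["classical"] = repr(err)

    model = None
    persons_wle = None
    if "irt" in config.stages:
        try:
            codes = shift_to_irt_codes(rm)
            model = irt.fit_pcm_mml(codes, n_quadrature=config.n_quadrature)
            persons_wle = irt.estimate_persons(model, method="WLE")
            persons_eap = irt.estimate_persons(model, method="EAP")
            bundle.sections["irt"] = {
                "delta": model.delta_.tolist(),
                "sigma": model.sigma_,
                "loglik": model.loglik_,
                "wle_reliability": irt.reliability(persons_wle),
                "eap_reliability": irt.reliability(persons_eap),
            }
        except Exception as err:  # noqa: BLE001
            bundle.errors["irt"] = repr(err)

    if "diagnostics" in config.stages and model is not None:
        try:
            fit_res = diagnostics.infit(model, persons=persons_wle)
            q3 = diagnostics.q3_family(model, persons=persons_wle)
            unidim = diagnostics.pca_ttest_unidim(model, persons=persons_wle)
            di = dichotomize(rm)
            age_split = median_split(rm.covariates["age"].to_numpy(dtype=float))
            lr = diagnostics.andersen_lr(di.responses, age_split)
            bundle.sections["diagnostics"] = {
                "infit": fit_res.infit.tolist(),
                "infit_t": fit_res.t.tolist(),
                "n_underfit": int(fit_res.underfit.sum()),
                "n_overfit": int(fit_res.overfit.sum()),
                "mad_aq3": q3.mad_aq3,
                "n_holm_significant_pairs": int(np.nansum(np.triu(q3.significant, 1))),
                "srmsr": diagnostics.srmsr_irt(model),
                "unidim_proportion": unidim.proportion,
                "unidim_ci_lower": unidim.ci_lower,
                "unidim_supported": unidim.supports_unidimensionality,
                "andersen_age": {"lr": lr.lr, "df": lr.df, "p": lr.p,
                                 "significant": lr.significant},
            }
        except Exception as err:  # noqa: BLE001
            bundle.errors["diagnostics"] = repr(err)

    if "validity" in config.stages and scores is not None:
        try:
            section = {}
            m1d, m2d = validity.concurrent_validity_models(rm, "D", scores)
            m1p, m2p = validity.concurrent_validity_models(rm, "P", scores)
            for tag, m in (("gradient_D", m1d), ("health_D", m2d),
                           ("gradient_P", m1p), ("health_P", m2p)):
                section[tag] = {"beta": dict(zip(m.predictors, m.beta.tolist())),
                                "r_squared": m.r_squared, "n_valid": m.n_valid}
            special_cols = [c for c in rm.covariates.columns
                            if c.startswith("special_") or c.endswith("_hl")]
            if special_cols:
                rep = validity.discriminant_check(
                    scores["score_P"].to_numpy(), rm.covariates[special_cols], rm.weights)
                section["discriminant"] = [
                    {"score": n, "r": r, "within_band": wb, "position": pos}
                    for n, r, wb, pos in rep.pairs]
            bundle.sections["validity"] = section
        except Exception as err:  # noqa: BLE001
            bundle.errors["validity"] = repr(err)

    return bundle
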