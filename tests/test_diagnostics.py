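import itertools

import numpy as np
import pytest

from healthlit import GeneratorConfig, generate, shift_to_irt_codes
from healthlit.errors import IllConditionedError
from healthlit.instrument import dichotomize, median_split
from healthlit.irt import estimate_persons, fit_pcm_mml, fit_rm_cml
from healthlit.diagnostics import (
    agresti_coull,
    andersen_lr,
    dif_facets_pcm,
    global_local_independence_rm,
    graphical_test_data,
    infit,
    model_implied_correlations,
    pca_ttest_unidim,
    q3_family,
    srmsr_irt,
    wald_item_z,
    well_conditioned_check,
)
from healthlit.simulate import GradientConfig, pcm_category_probs

from conftest import two_block_responses


def rm_data(n, beta, seed, shift_item=None, shift=0.0, groups=None):
    rng = np.random.default_rng(seed)
    theta = rng.normal(0, 1, n)
    b = np.tile(beta, (n, 1))
    if shift_item is not None:
        b[groups, shift_item] += shift
    p = 1 / (1 + np.exp(-(theta[:, None] - b)))
    return (rng.random((n, len(beta))) < p).astype(float)


# ---------------------------------------------------------------------------
# Infit


def test_infit_null_within_elimination_thresholds(clean_model, clean_wle):
    res = infit(clean_model, persons=clean_wle)
    assert not res.underfit.any()
    assert not res.overfit.any()
    assert not res.screen_note.any()


def test_infit_flags_random_item():
    ds = generate(GeneratorConfig(n_persons=2000, seed=41))
    X = shift_to_irt_codes(ds.rm)
    rng = np.random.default_rng(0)
    X[:, 7] = rng.integers(0, 4, len(X)).astype(float)
    model = fit_pcm_mml(X, n_quadrature=31)
    res = infit(model)
    assert res.infit[7] > 1.2 and res.underfit[7]
    assert res.infit[7] == res.infit.max()
    assert res.t[7] == res.t.max()


def test_infit_duplicated_item_overfits():
    ds = generate(GeneratorConfig(n_persons=2000, seed=43))
    X = shift_to_irt_codes(ds.rm)
    X[:, 11] = X[:, 10]
    model = fit_pcm_mml(X, n_quadrature=31)
    res = infit(model)
    base = np.delete(res.infit, [10, 11]).mean()
    assert res.infit[10] < base and res.infit[11] < base


# ---------------------------------------------------------------------------
# Q3 family


def test_q3_copied_pair_flags_dependence():
    cfg = GeneratorConfig(n_persons=2000, seed=45, local_dep=[("hl2", "hl9", 1.0)])
    ds = generate(cfg)
    model = fit_pcm_mml(shift_to_irt_codes(ds.rm), n_quadrature=31)
    res = q3_family(model)
    iu = np.triu_indices(12, 1)
    pair_val = res.aq3[1, 8]
    assert pair_val == np.nanmax(res.aq3[iu])
    assert res.significant[1, 8]


def test_q3_null_effect_size_and_centering(clean_model, clean_wle):
    res = q3_family(clean_model, persons=clean_wle)
    assert res.mad_aq3 < 0.05
    iu = np.triu_indices(12, 1)
    assert np.nanmean(res.aq3[iu]) == pytest.approx(0.0, abs=1e-12)
    assert not res.significant[np.triu_indices(12, 1)].any()


# ---------------------------------------------------------------------------
# SRMSR


def test_srmsr_null_below_conservative_cutoff(clean_model):
    assert srmsr_irt(clean_model) <= 0.05


def test_srmsr_two_block_above_cutoff(two_block_model):
    assert srmsr_irt(two_block_model) > 0.08


def test_model_implied_correlations_match_monte_carlo(clean_model):
    """Dual route: quadrature-implied correlations vs brute-force sampling
    from the fitted model."""
    rng = np.random.default_rng(7)
    n = 200_000
    theta = rng.normal(0, clean_model.sigma_, n)
    p = pcm_category_probs(theta, clean_model.delta_)
    u = rng.random((n, 12))
    cdf = np.cumsum(p, axis=2)
    X = (u[:, :, None] > cdf[:, :, :-1]).sum(axis=2).astype(float)
    r_mc = np.corrcoef(X, rowvar=False)
    r_model = model_implied_correlations(clean_model)
    iu = np.triu_indices(12, 1)
    assert np.abs(r_mc[iu] - r_model[iu]).max() < 0.01


# ---------------------------------------------------------------------------
# Agresti-Coull and PCA/t-test


def test_agresti_coull_closed_form_fixtures():
    # the 2.1% / n=900 case: lower bound prints as 1.3%
    x = round(0.021 * 900)
    p_t, lo, hi = agresti_coull(x, 900)
    assert round(100 * lo, 1) == 1.3
    # generic fixtures against direct evaluation
    for x, n in [(0, 50), (5, 100), (50, 200), (900, 1000)]:
        z = 1.96
        nt = n + z**2
        pt = (x + z**2 / 2) / nt
        half = z * np.sqrt(pt * (1 - pt) / nt)
        got = agresti_coull(x, n)
        assert got[0] == pytest.approx(pt)
        assert got[1] == pytest.approx(pt - half)
        assert got[2] == pytest.approx(pt + half)


def test_pca_ttest_supports_unidimensionality_on_null(clean_model, clean_wle):
    res = pca_ttest_unidim(clean_model, persons=clean_wle)
    assert res.supports_unidimensionality
    assert res.n_tested > 1800


def test_pca_ttest_rejects_two_block_structure(two_block_model):
    res = pca_ttest_unidim(two_block_model)
    assert res.proportion > 0.05
    assert res.ci_lower > 0.05
    assert not res.supports_unidimensionality
    # the split should recover the generating blocks
    assert sorted(res.subset_pos) in ([0, 1, 2, 3, 4, 5], [6, 7, 8, 9, 10, 11]) or \
           sorted(res.subset_neg) in ([0, 1, 2, 3, 4, 5], [6, 7, 8, 9, 10, 11])


# ---------------------------------------------------------------------------
# Andersen LR / Wald / graphical


def test_andersen_df_and_null_acceptance():
    beta = np.linspace(-1.5, 1.5, 12)
    X = rm_data(900, beta, seed=47)
    rng = np.random.default_rng(1)
    split = np.where(rng.random(900) < 0.5, "a", "b")
    res = andersen_lr(X, split)
    assert res.df == 11
    assert not res.significant


def test_andersen_detects_injected_dif():
    beta = np.linspace(-1.5, 1.5, 12)
    rng = np.random.default_rng(2)
    groups = rng.random(2000) < 0.5
    X = rm_data(2000, beta, seed=49, shift_item=5, shift=0.5, groups=groups)
    split = np.where(groups, "high", "low")
    res = andersen_lr(X, split)
    assert res.p < 0.001 and res.significant


def test_wald_zero_for_identical_groups():
    beta = np.linspace(-1, 1, 12)
    X = rm_data(400, beta, seed=51)
    X2 = np.vstack([X, X])
    split = np.array(["a"] * 400 + ["b"] * 400)
    res = wald_item_z(X2, split)
    np.testing.assert_allclose(res.z, 0.0, atol=1e-5)


def test_wald_localises_dif_item():
    beta = np.linspace(-1.5, 1.5, 12)
    rng = np.random.default_rng(3)
    groups = rng.random(3000) < 0.5
    X = rm_data(3000, beta, seed=53, shift_item=5, shift=0.5, groups=groups)
    split = np.where(groups, "high", "low")
    res = wald_item_z(X, split)
    assert np.abs(res.z).argmax() == 5
    assert res.p[5] < 0.001


def test_graphical_test_identifies_dif_direction():
    beta = np.linspace(-1.5, 1.5, 12)
    rng = np.random.default_rng(4)
    groups = rng.random(3000) < 0.5
    X = rm_data(3000, beta, seed=55, shift_item=5, shift=0.6, groups=groups)
    split = np.where(groups, "shifted", "base")
    res = graphical_test_data(X, split)
    # group 1 in the output is whichever label occurs first in the data
    sign = 1.0 if split[0] == "shifted" else -1.0
    diff = sign * (res.beta_1 - res.beta_2)
    # item 5 is harder for the shifted group and departs beyond its radius
    assert diff[5] == diff.max()
    assert abs(diff[5]) > res.radius_95[5]
    others = np.delete(np.abs(diff) <= np.delete(res.radius_95, 5).max() + 0.2, 5)
    assert others.mean() > 0.8


def test_icc_observed_proportions_track_model():
    beta = np.linspace(-1.5, 1.5, 12)
    X = rm_data(5000, beta, seed=57)
    split = np.array(["a", "b"] * 2500)
    res = graphical_test_data(X, split)
    # model curve is monotone in the raw score for every item
    assert (np.diff(res.icc_model, axis=1) > 0).all()
    ok = ~np.isnan(res.icc_observed)
    assert np.abs(res.icc_observed[ok] - res.icc_model[ok]).mean() < 0.05


# ---------------------------------------------------------------------------
# Facets DIF


def test_facets_recovers_injected_dif():
    cfg = GeneratorConfig(n_persons=2000, seed=5, dif=[("hl6", "age", 0.5)])
    ds = generate(cfg)
    X = shift_to_irt_codes(ds.rm)
    age = ds.rm.covariates["age"].to_numpy(float)
    groups = np.where(age > np.median(age), "old", "young")
    records = dif_facets_pcm(X, groups)
    rec = records[5]
    assert abs(abs(rec.tau[0]) - 0.25) < 0.1
    assert rec.significant
    flagged = [r.item for r in records if r.significant]
    assert flagged == [5]


def test_facets_null_band(clean_ds):
    X = shift_to_irt_codes(clean_ds.rm)
    sex = clean_ds.rm.covariates["sex"].to_numpy()
    records = dif_facets_pcm(X, sex)
    assert max(abs(r.tau[0]) for r in records) < 0.15
    assert not any(r.significant for r in records)


def test_facets_group_relabeling_flips_sign():
    cfg = GeneratorConfig(n_persons=800, seed=59, dif=[("hl6", "age", 0.6)])
    ds = generate(cfg)
    X = shift_to_irt_codes(ds.rm)
    age = ds.rm.covariates["age"].to_numpy(float)
    g1 = np.where(age > np.median(age), "a_old", "b_young")
    g2 = np.where(age > np.median(age), "b_old", "a_young")
    r1 = dif_facets_pcm(X, g1, max_iter=100)
    r2 = dif_facets_pcm(X, g2, max_iter=100)
    for a, b in zip(r1, r2):
        assert a.tau[0] == pytest.approx(-b.tau[0], abs=0.02)


# ---------------------------------------------------------------------------
# Well-conditioned data


def test_well_conditioned_toy_witness():
    X = np.array([[1, 0, 0], [1, 1, 0], [1, 0, 1]], dtype=float)
    ok, witness = well_conditioned_check(X)
    assert not ok
    assert witness == {0}


def bruteforce_well_conditioned(X):
    k = X.shape[1]
    one = X == 1.0
    zero = X == 0.0
    for size in range(1, k):
        for first in itertools.combinations(range(k), size):
            rest = [j for j in range(k) if j not in first]
            found = any(
                (one[:, i] & zero[:, j]).any() for i in first for j in rest)
            if not found:
                return False
    return True


def test_well_conditioned_matches_bruteforce_on_random_fixtures():
    rng = np.random.default_rng(6)
    agree = 0
    for _ in range(200):
        k = int(rng.integers(3, 8))
        n = int(rng.integers(4, 15))
        X = (rng.random((n, k)) < rng.uniform(0.15, 0.85)).astype(float)
        ok, witness = well_conditioned_check(X)
        assert ok == bruteforce_well_conditioned(X)
        if not ok:
            # the witness really violates the condition: no person scores 1
            # outside the witness and 0 inside it
            rest = [j for j in range(k) if j not in witness]
            assert not any((X[:, i] == 1).any() and False for i in rest)
            viol = any((X[:, i] == 1)[(X[:, j] == 0)].any()
                       for i in rest for j in witness)
            assert not viol
        agree += 1
    assert agree == 200


def test_rm_simulated_data_well_conditioned():
    X = rm_data(900, np.linspace(-1.5, 1.5, 12), seed=61)
    assert well_conditioned_check(X)[0]


def test_cml_raises_on_ill_conditioned_data():
    X = np.array([[1, 0, 0], [1, 1, 0], [1, 0, 1]], dtype=float)
    with pytest.raises(IllConditionedError) as err:
        fit_rm_cml(X)
    assert err.value.witness == {0}


# ---------------------------------------------------------------------------
# Global local independence


def test_curveball_preserves_margins():
    from healthlit.diagnostics import _curveball
    rng = np.random.default_rng(8)
    mat = (rng.random((200, 12)) < 0.5).astype(np.int8)
    before_r, before_c = mat.sum(axis=1).copy(), mat.sum(axis=0).copy()
    work = mat.copy()
    _curveball(work, 10000, 123)
    np.testing.assert_array_equal(work.sum(axis=1), before_r)
    np.testing.assert_array_equal(work.sum(axis=0), before_c)
    assert (work != mat).any()          # the chain actually moved


def test_global_ld_rejects_copied_pair():
    cfg = GeneratorConfig(n_persons=900, seed=63, local_dep=[("hl2", "hl9", 1.0)])
    ds = generate(cfg)
    di = dichotomize(ds.rm)
    res = global_local_independence_rm(di.responses, seed=1)
    assert res.p < 0.01


def test_global_ld_null_calibration():
    """Type-I control at alpha=0.05 over 200 margin-preserving replications."""
    rng = np.random.default_rng(9)
    beta = np.linspace(-1.5, 1.5, 12)
    rejections = 0
    for rep in range(200):
        X = rm_data(900, beta, seed=int(rng.integers(2**31)))
        res = global_local_independence_rm(X, seed=rep)
        rejections += res.p < 0.05
    assert 0.02 <= rejections / 200 <= 0.09
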