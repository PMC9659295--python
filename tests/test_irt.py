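import itertools

import numpy as np
import pytest
from scipy.stats import norm

from healthlit import GeneratorConfig, generate, shift_to_irt_codes
from healthlit.instrument import InstrumentSpec, Item, dichotomize
from healthlit.irt import (
    NominalResponseModel,
    PartialCreditModel,
    esf,
    estimate_persons,
    fit_nrm,
    fit_pcm_mml,
    fit_rm_cml,
    pcm_probs,
    reliability,
)


# ---------------------------------------------------------------------------
# Elementary symmetric functions


def esf_bruteforce(eps):
    """gamma_r as a sum over all response patterns with raw score r."""
    k = len(eps)
    g = np.zeros(k + 1)
    for pattern in itertools.product((0, 1), repeat=k):
        r = sum(pattern)
        g[r] += np.prod([e**x for e, x in zip(eps, pattern)])
    return g


def test_esf_binomial_case():
    np.testing.assert_allclose(esf([1.0, 1.0]), [1, 2, 1])


def test_esf_matches_bruteforce_enumeration():
    np.testing.assert_allclose(esf([1.0, 2.0, 3.0]), [1, 6, 11, 6])
    rng = np.random.default_rng(0)
    eps = rng.uniform(0.2, 3.0, 10)
    np.testing.assert_allclose(esf(eps), esf_bruteforce(eps), rtol=1e-10)


def test_esf_polynomial_identity():
    rng = np.random.default_rng(1)
    eps = rng.uniform(0.1, 2.0, 7)
    g = esf(eps)
    for t in (0.3, 1.0, 1.7):
        poly = sum(g[r] * t**r for r in range(len(g)))
        prod = np.prod(1 + eps * t)
        assert poly == pytest.approx(prod, rel=1e-12)


# ---------------------------------------------------------------------------
# Rasch CML


def rm_data(n, beta, seed, theta_sd=1.0):
    rng = np.random.default_rng(seed)
    theta = rng.normal(0, theta_sd, n)
    p = 1 / (1 + np.exp(-(theta[:, None] - beta[None, :])))
    return (rng.random((n, len(beta))) < p).astype(float)


def test_cml_matches_grid_search_on_two_items():
    X = rm_data(400, np.array([0.7, -0.7]), seed=2)[:, :2]
    fit = fit_rm_cml(X, check_conditioning=False)
    # brute-force grid over the one free parameter (beta2 = -beta1)
    grid = np.linspace(-3, 3, 60001)
    sel = X.sum(axis=1) == 1
    x1 = X[sel, 0]

    def cll(b):
        eps = np.exp(-np.array([b, -b]))
        return float(-(x1 * b + (1 - x1) * (-b)).sum() - sel.sum() * np.log(esf(eps)[1]))

    vals = np.array([cll(b) for b in grid[::100]])
    coarse = grid[::100][np.argmax(vals)]
    fine = grid[np.abs(grid - coarse) < 0.02]
    best = fine[np.argmax([cll(b) for b in fine])]
    assert fit.beta[0] == pytest.approx(best, abs=1e-4)


def test_cml_parameter_recovery():
    beta = np.linspace(-1.5, 1.5, 12)
    beta -= beta.mean()
    X = rm_data(2000, beta, seed=3)
    fit = fit_rm_cml(X)
    assert np.abs(fit.beta - beta).mean() < 0.10
    assert fit.beta.sum() == pytest.approx(0.0, abs=1e-8)
    assert (fit.se > 0).all()


def test_cml_column_permutation_equivariance():
    beta = np.linspace(-1, 1, 6)
    X = rm_data(500, beta, seed=4)
    perm = np.array([3, 0, 5, 1, 4, 2])
    f1 = fit_rm_cml(X, check_conditioning=False)
    f2 = fit_rm_cml(X[:, perm], check_conditioning=False)
    np.testing.assert_allclose(f2.beta, f1.beta[perm], atol=1e-6)


def test_cml_sufficiency_row_permutation():
    beta = np.linspace(-1, 1, 6)
    X = rm_data(300, beta, seed=5)
    f1 = fit_rm_cml(X, check_conditioning=False)
    f2 = fit_rm_cml(X[::-1], check_conditioning=False)
    np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-10)


# ---------------------------------------------------------------------------
# PCM MML-EM


def test_pcm_parameter_recovery(clean_ds, clean_model):
    err = np.abs(clean_model.delta_ - clean_ds.item_params).mean()
    assert err < 0.10
    assert clean_model.sigma_ == pytest.approx(1.0, abs=0.1)
    assert clean_model.converged_


def test_pcm_em_loglik_monotone(clean_model):
    diffs = np.diff(clean_model.loglik_path_)
    assert (diffs > -1e-6).all()


def test_pcm_invariant_to_doubling_persons():
    ds = generate(GeneratorConfig(n_persons=300, seed=6))
    X = shift_to_irt_codes(ds.rm)
    m1 = fit_pcm_mml(X)
    m2 = fit_pcm_mml(np.vstack([X, X]))
    np.testing.assert_allclose(m1.delta_, m2.delta_, atol=1e-4)
    np.testing.assert_allclose(m1.sigma_, m2.sigma_, atol=1e-4)


def test_pcm_quadrature_refinement():
    ds = generate(GeneratorConfig(n_persons=400, seed=9))
    X = shift_to_irt_codes(ds.rm)
    m_default = fit_pcm_mml(X)
    m_fine = fit_pcm_mml(X, n_quadrature=2 * m_default.n_quadrature - 1)
    assert np.abs(m_default.delta_ - m_fine.delta_).max() < 1e-3


def test_pcm_reduces_to_rm_on_dichotomized_data(clean_ds):
    di = dichotomize(clean_ds.rm)
    pcm2 = fit_pcm_mml(di.responses)
    rm = fit_rm_cml(di.responses)
    d = pcm2.delta_[:, 0]
    from scipy.stats import spearmanr
    assert spearmanr(d, rm.beta).statistic == pytest.approx(1.0)


def test_pcm_standard_errors_positive():
    ds = generate(GeneratorConfig(n_persons=400, seed=10))
    model = fit_pcm_mml(shift_to_irt_codes(ds.rm), n_quadrature=31)
    se = model.standard_errors()
    assert se.shape == model.delta_.shape
    assert (se > 0).all() and (se < 1.0).all()


# ---------------------------------------------------------------------------
# Person estimates and reliability


def test_wle_zero_for_central_score_on_symmetric_items():
    delta = np.array([[-0.5, 0.0, 0.5], [-0.5, 0.0, 0.5]])
    model = PartialCreditModel()
    model.delta_ = delta
    model.sigma_ = 1.0
    model.nodes_ = np.linspace(-6, 6, 61)
    model.prior_weights_ = norm.pdf(model.nodes_)
    model.prior_weights_ /= model.prior_weights_.sum()
    model.group_shift_ = None
    model.group_idx_ = None
    model._X = np.array([[1.0, 2.0]])   # raw score 3 of 6: symmetric centre
    est = estimate_persons(model, method="WLE")
    assert est.theta[0] == pytest.approx(0.0, abs=1e-6)


def test_eap_contracts_and_matches_grid_integration(clean_model):
    X = clean_model._X
    eap = estimate_persons(clean_model, method="EAP")
    assert (eap.se**2 < clean_model.sigma_**2).all()
    grid = np.linspace(-8, 8, 4001)
    p = pcm_probs(grid, clean_model.delta_)
    prior = norm.pdf(grid, 0, clean_model.sigma_)
    for v in range(20):
        x = X[v].astype(int)
        like = np.prod([p[:, i, x[i]] for i in range(12)], axis=0)
        post = like * prior
        post /= np.trapezoid(post, grid)
        mean = np.trapezoid(grid * post, grid)
        assert eap.theta[v] == pytest.approx(mean, abs=1e-4)


def test_eap_shrinks_relative_to_wle(clean_model, clean_wle):
    eap = estimate_persons(clean_model, method="EAP")
    assert np.var(eap.theta) < np.var(clean_wle.theta)


def test_reliability_band_and_monotonicity(clean_model, clean_wle):
    rel_wle = reliability(clean_wle)
    rel_eap = reliability(estimate_persons(clean_model, method="EAP"))
    assert 0.75 <= rel_wle <= 0.92
    assert 0.75 <= rel_eap <= 0.92

    # a 48-item instrument measures the same persons more reliably
    items = tuple(Item(f"g{i}", f"g{i}", "health_care", "access") for i in range(48))
    inst48 = InstrumentSpec(items)
    loc = np.linspace(-1, 1, 48)
    params48 = loc[:, None] + np.array([-0.7, 0.0, 0.7])
    cfg = GeneratorConfig(n_persons=1000, seed=12, instrument=inst48,
                          item_params=params48)
    ds48 = generate(cfg)
    m48 = fit_pcm_mml(shift_to_irt_codes(ds48.rm), n_quadrature=31)
    rel48 = reliability(estimate_persons(m48, method="WLE"))

    cfg12 = GeneratorConfig(n_persons=1000, seed=12)
    ds12 = generate(cfg12)
    m12 = fit_pcm_mml(shift_to_irt_codes(ds12.rm), n_quadrature=31)
    rel12 = reliability(estimate_persons(m12, method="WLE"))
    assert rel48 > rel12


def test_reliability_collapses_without_true_variance():
    from healthlit.simulate import GradientConfig
    cfg = GeneratorConfig(n_persons=800, seed=14, latent_sd=0.05,
                          gradient=GradientConfig(b_sex=0, b_age=0, b_edu=0,
                                                  b_status=0, b_findep=0))
    ds = generate(cfg)
    model = fit_pcm_mml(shift_to_irt_codes(ds.rm), n_quadrature=31)
    rel = reliability(estimate_persons(model, method="EAP"))
    assert rel < 0.2


# ---------------------------------------------------------------------------
# Nominal categories model


def test_nrm_confirms_ordering_on_pcm_data():
    ds = generate(GeneratorConfig(n_persons=5000, seed=15))
    fit = fit_nrm(shift_to_irt_codes(ds.rm))
    assert fit.ordered.all()
    assert not fit.unstable.any()


def test_nrm_detects_swapped_categories():
    ds = generate(GeneratorConfig(n_persons=5000, seed=16))
    X = shift_to_irt_codes(ds.rm)
    swapped = X.copy()
    col = swapped[:, 0]
    one, two = col == 1.0, col == 2.0
    col[one], col[two] = 2.0, 1.0
    fit = fit_nrm(swapped)
    assert not fit.ordered[0]
    assert fit.ordered[1:].all()


def test_nrm_flags_low_endorsement():
    ds = generate(GeneratorConfig(n_persons=3000, seed=17))
    X = shift_to_irt_codes(ds.rm)
    # crush category 0 of item 0 below 1%
    col = X[:, 0]
    zeros = np.nonzero(col == 0.0)[0]
    col[zeros[5:]] = 1.0
    fit = fit_nrm(X)
    assert fit.unstable[0]
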