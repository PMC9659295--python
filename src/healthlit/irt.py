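"""Rasch-family IRT estimation.

Implements from scratch:

* elementary symmetric functions (ESF) and conditional maximum likelihood
  (CML) for the dichotomous Rasch model, with sum-to-zero difficulties;
* marginal maximum likelihood (MML) EM estimation of the partial credit
  model (PCM) with Gauss-Hermite quadrature, latent mean fixed at 0 and
  the latent standard deviation estimated;
* a facets extension of the PCM with per-group item shifts
  (item + group + item x group) for differential item functioning;
* the nominal categories model (NCM/NRM) for checking the empirical
  ordering of response categories;
* Warm's weighted likelihood (WLE) and expected-a-posteriori (EAP) person
  estimates with the induced reliability coefficients.

Category codes are 0..m-1 throughout this module; NaN marks missing and
drops out of the person's likelihood factor (ignorable missingness).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import logsumexp, roots_hermitenorm

from .base import BaseEstimator, check_is_fitted
from .errors import EstimationError, IllConditionedError

# ---------------------------------------------------------------------------
# Elementary symmetric functions


def esf(eps: np.ndarray) -> np.ndarray:
    """Elementary symmetric functions gamma_0..gamma_k of the easiness
    parameters, via the summation algorithm (gamma_0 = 1)."""
    eps = np.asarray(eps, dtype=float)
    g = np.zeros(len(eps) + 1)
    g[0] = 1.0
    for e in eps:
        g[1:] = g[1:] + e * g[:-1]
    return g


def esf_leave_one_out(eps: np.ndarray) -> np.ndarray:
    """gamma^(i)_r : ESF of eps with item i removed, shape (k, k)."""
    eps = np.asarray(eps, dtype=float)
    k = len(eps)
    out = np.empty((k, k))
    for i in range(k):
        out[i] = esf(np.delete(eps, i))
    return out


# ---------------------------------------------------------------------------
# Dichotomous Rasch model, CML


@dataclass
class RMFit:
    beta: np.ndarray           # sum-to-zero difficulties
    se: np.ndarray
    loglik: float              # conditional log-likelihood
    cov: np.ndarray            # covariance of beta (singular along 1-direction)
    n_used: int                # persons with non-extreme scores


def _cml_nll_grad(beta_free: np.ndarray, patterns, k: int):
    """Negative conditional log-likelihood and gradient, grouped by
    observed-item pattern.  ``patterns`` maps an observed-items tuple to
    (score_counts, item_sums) for persons sharing that pattern."""
    beta = np.append(beta_free, -beta_free.sum())
    nll = 0.0
    grad = np.zeros(k)
    for obs, (score_counts, item_sums) in patterns.items():
        obs = np.array(obs)
        eps = np.exp(-beta[obs])
        g = esf(eps)
        g_loo = esf_leave_one_out(eps)
        ko = len(obs)
        for r, c in score_counts.items():
            nll += c * np.log(g[r])
        # -sum_i x_vi beta_i term
        nll += float(item_sums @ beta[obs])
        # gradient of the nll: sum_v (x_vi - pi_vi) per item
        for r, c in score_counts.items():
            if r == 0 or r == ko:
                continue
            pi = eps * g_loo[:, r - 1] / g[r]
            grad[obs] -= c * pi
        grad[obs] += item_sums
    grad_free = grad[:-1] - grad[-1]
    return nll, grad_free


class RaschModel(BaseEstimator):
    """Dichotomous Rasch model estimated by conditional maximum likelihood.

    Persons with extreme raw scores (0 or all-correct on their observed
    items) carry no conditional information and are dropped; difficulties
    are normalised to sum to zero.

    Parameters
    ----------
    check_conditioning : bool
        Verify Fischer's well-conditioned-data criterion before fitting.
    """

    def __init__(self, check_conditioning: bool = True):
        self.check_conditioning = check_conditioning

    def fit(self, X):
        X = np.asarray(X, dtype=float)
        n, k = X.shape
        if self.check_conditioning:
            from .diagnostics import well_conditioned_check
            ok, witness = well_conditioned_check(X)
            if not ok:
                raise IllConditionedError(
                    f"data are ill-conditioned; no person separates item subsets "
                    f"{sorted(witness)} from the rest", witness=witness)

        patterns: dict = {}
        n_used = 0
        for v in range(n):
            obs = tuple(np.nonzero(~np.isnan(X[v]))[0])
            ko = len(obs)
            if ko < 2:
                continue
            r = int(np.nansum(X[v]))
            if r == 0 or r == ko:
                continue
            n_used += 1
            sc, sums = patterns.setdefault(obs, ({}, np.zeros(ko)))
            sc[r] = sc.get(r, 0) + 1
            sums += X[v, list(obs)]
        if not patterns:
            raise EstimationError("no persons with non-extreme raw scores")

        x0 = np.zeros(k - 1)
        res = optimize.minimize(_cml_nll_grad, x0, args=(patterns, k),
                                jac=True, method="L-BFGS-B",
                                options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-9})
        beta_free = res.x
        beta = np.append(beta_free, -beta_free.sum())

        # observed information (numerical Hessian of the reduced nll)
        h = 1e-5
        m = k - 1
        hess = np.zeros((m, m))
        for j in range(m):
            step = np.zeros(m)
            step[j] = h
            gp = _cml_nll_grad(beta_free + step, patterns, k)[1]
            gm = _cml_nll_grad(beta_free - step, patterns, k)[1]
            hess[:, j] = (gp - gm) / (2 * h)
        hess = 0.5 * (hess + hess.T)
        cov_free = np.linalg.pinv(hess)
        # map to full beta: beta = A b with A = [I; -1']
        A = np.vstack([np.eye(m), -np.ones(m)])
        cov = A @ cov_free @ A.T

        self.beta_ = beta
        self.se_ = np.sqrt(np.clip(np.diag(cov), 0, None))
        self.cov_ = cov
        self.loglik_ = -float(res.fun)
        self.n_used_ = n_used
        return self

    def result(self) -> RMFit:
        check_is_fitted(self, "beta_")
        return RMFit(self.beta_, self.se_, self.loglik_, self.cov_, self.n_used_)


def fit_rm_cml(X, check_conditioning: bool = True) -> RMFit:
    """Functional wrapper over :class:`RaschModel`. ``X`` is 0/1 with NaN."""
    return RaschModel(check_conditioning=check_conditioning).fit(X).result()


# ---------------------------------------------------------------------------
# PCM moments and probabilities


def pcm_probs(theta, delta) -> np.ndarray:
    """PCM category probabilities, theta (q,), delta (k, m-1) -> (q, k, m)."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    delta = np.asarray(delta, dtype=float)
    m = delta.shape[1] + 1
    cumdelta = np.concatenate([np.zeros((delta.shape[0], 1)), np.cumsum(delta, axis=1)], axis=1)
    psi = theta[:, None, None] * np.arange(m)[None, None, :] - cumdelta[None, :, :]
    psi -= psi.max(axis=2, keepdims=True)
    ex = np.exp(psi)
    return ex / ex.sum(axis=2, keepdims=True)


def pcm_moments(theta, delta):
    """Conditional mean, variance and third central moment of each item
    score at each theta: three arrays of shape (q, k)."""
    p = pcm_probs(theta, delta)
    x = np.arange(p.shape[2])
    e = (p * x).sum(axis=2)
    v = (p * x**2).sum(axis=2) - e**2
    mu3 = (p * x**3).sum(axis=2) - 3 * e * v - e**3
    return e, v, mu3


def _loglik_persons(X, obs, delta_by_group, group_idx, nodes, log_prior):
    """Marginal log-likelihood contribution per person.

    ``delta_by_group``: list of (k, m-1) arrays, one per group.
    Returns (loglik_vector, posterior (n, q))."""
    n, k = X.shape
    q = len(nodes)
    Xi = np.where(obs, X, 0).astype(int)
    ll_vq = np.zeros((n, q))
    for g, delta in enumerate(delta_by_group):
        sel = group_idx == g
        if not sel.any():
            continue
        logp = np.log(np.clip(pcm_probs(nodes, delta), 1e-300, None))  # (q,k,m)
        onehot = np.zeros((sel.sum(), k, logp.shape[2]))
        rows = np.repeat(np.arange(sel.sum()), k)
        cols = np.tile(np.arange(k), sel.sum())
        onehot[rows, cols, Xi[sel].ravel()] = obs[sel].ravel()
        ll_vq[sel] = np.einsum("qkm,nkm->nq", logp, onehot)
    joint = ll_vq + log_prior[None, :]
    ll = logsumexp(joint, axis=1)
    post = np.exp(joint - ll[:, None])
    return ll, post


def _mstep_item(delta_i, shifts, counts_gqx, probs_fn, nodes, n_groups, max_newton=50):
    """Newton maximisation of the expected complete-data log-likelihood for
    one item.  Parameters: m-1 shared steps plus (G-1) free group shifts
    (last shift = -sum).  ``counts_gqx``: (G, q, m) expected counts."""
    m = counts_gqx.shape[2]
    n_free = (m - 1) + (n_groups - 1)
    params = np.concatenate([delta_i, shifts[:-1]])

    def unpack(p):
        d = p[: m - 1]
        if n_groups > 1:
            s_free = p[m - 1:]
            s = np.append(s_free, -s_free.sum())
        else:
            s = np.zeros(1)
        return d, s

    def neg_obj_grad(p):
        d, s = unpack(p)
        obj = 0.0
        grad = np.zeros(n_free)
        for g in range(n_groups):
            pr = probs_fn(nodes, (d + s[g])[None, :])[:, 0, :]  # (q, m)
            lp = np.log(np.clip(pr, 1e-300, None))
            cnt = counts_gqx[g]
            obj += float((cnt * lp).sum())
            n_q = cnt.sum(axis=1)                      # (q,)
            p_ge = np.cumsum(pr[:, ::-1], axis=1)[:, ::-1]   # P(X>=x)
            c_ge = np.cumsum(cnt[:, ::-1], axis=1)[:, ::-1]
            # d logp_x / d delta_k = P(X>=k) - 1{x>=k}
            gk = (n_q[:, None] * p_ge[:, 1:] - c_ge[:, 1:]).sum(axis=0)  # (m-1,)
            grad[: m - 1] += gk
            if n_groups > 1:
                gs = gk.sum()
                if g < n_groups - 1:
                    grad[m - 1 + g] += gs
                else:
                    grad[m - 1:] -= gs
        return -obj, -grad

    res = optimize.minimize(neg_obj_grad, params, jac=True, method="L-BFGS-B",
                            options={"maxiter": max_newton, "ftol": 1e-12, "gtol": 1e-10})
    d, s = unpack(res.x)
    return d, s


@dataclass
class PCMFit:
    delta: np.ndarray          # (k, m-1) step parameters
    sigma: float
    loglik: float
    loglik_path: np.ndarray
    nodes: np.ndarray
    prior_weights: np.ndarray
    converged: bool
    n_iter: int
    group_shift: np.ndarray | None = None   # (k, G) item x group shifts
    group_main: np.ndarray | None = None    # (G,) facet main effect
    tau: np.ndarray | None = None           # (k, G) interaction, double sum-to-zero


class PartialCreditModel(BaseEstimator):
    """Partial credit model by MML-EM with Gauss-Hermite quadrature.

    The latent distribution is Normal(0, sigma^2); the mean is fixed at 0
    for identification and sigma is estimated (set ``estimate_sigma=False``
    to keep it fixed at ``sigma0``).  With ``groups`` passed to ``fit`` the
    model becomes the facets extension item + group + item x group: every
    item's steps are shifted by s_ig = main_g + tau_ig with both margins of
    tau summing to zero.

    Parameters
    ----------
    n_quadrature : int
        Gauss-Hermite nodes.  The default of 61 keeps the quadrature error
        of the step estimates below 1e-4; with substantially fewer nodes
        the spacing near the centre exceeds the posterior spread of a
        12-item response pattern and the error grows to ~5e-3.
    tol : float
        EM stops when the largest parameter change is below this.
    max_iter : int
        EM iteration cap.
    """

    def __init__(self, n_quadrature: int = 61, tol: float = 1e-5,
                 max_iter: int = 500, estimate_sigma: bool = True,
                 sigma0: float = 1.0):
        self.n_quadrature = n_quadrature
        self.tol = tol
        self.max_iter = max_iter
        self.estimate_sigma = estimate_sigma
        self.sigma0 = sigma0

    def fit(self, X, groups=None):
        X = np.asarray(X, dtype=float)
        n, k = X.shape
        obs = ~np.isnan(X)
        m = int(np.nanmax(X)) + 1
        if m < 2:
            raise EstimationError("need at least two observed categories")
        for i in range(k):
            if np.unique(X[obs[:, i], i]).size < 2:
                raise EstimationError(f"item {i} has fewer than two observed categories")

        if groups is None:
            group_idx = np.zeros(n, dtype=int)
            n_groups = 1
        else:
            labels, group_idx = np.unique(np.asarray(groups), return_inverse=True)
            n_groups = len(labels)
            self.group_labels_ = labels

        t, w = roots_hermitenorm(self.n_quadrature)   # weights for N(0,1) kernel
        w = w / w.sum()
        sigma = float(self.sigma0)
        delta = np.zeros((k, m - 1))
        shifts = np.zeros((k, n_groups))
        Xi = np.where(obs, X, 0).astype(int)

        loglik_path = []
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            nodes = sigma * t
            log_prior = np.log(w)
            delta_by_group = [delta + shifts[:, g][:, None] for g in range(n_groups)]
            ll_v, post = _loglik_persons(X, obs, delta_by_group, group_idx, nodes, log_prior)
            loglik_path.append(float(ll_v.sum()))

            # expected counts per (group, node, item, category)
            old = np.concatenate([delta.ravel(), shifts.ravel(), [sigma]])
            new_delta = np.empty_like(delta)
            new_shifts = np.empty_like(shifts)
            for i in range(k):
                counts = np.zeros((n_groups, len(nodes), m))
                for g in range(n_groups):
                    sel = (group_idx == g) & obs[:, i]
                    if not sel.any():
                        counts[g] = 0
                        continue
                    onehot = np.zeros((sel.sum(), m))
                    onehot[np.arange(sel.sum()), Xi[sel, i]] = 1.0
                    counts[g] = post[sel].T @ onehot
                d_i, s_i = _mstep_item(delta[i], shifts[i], counts, pcm_probs,
                                       nodes, n_groups)
                new_delta[i] = d_i
                new_shifts[i] = s_i
            delta, shifts = new_delta, new_shifts

            if self.estimate_sigma:
                second_moment = float((post * (nodes**2)[None, :]).sum() / n)
                sigma = float(np.sqrt(max(second_moment, 1e-6)))

            change = np.max(np.abs(np.concatenate([delta.ravel(), shifts.ravel(), [sigma]]) - old))
            if change < self.tol:
                converged = True
                break

        nodes = sigma * t
        delta_by_group = [delta + shifts[:, g][:, None] for g in range(n_groups)]
        ll_v, post = _loglik_persons(X, obs, delta_by_group, group_idx, nodes, np.log(w))
        loglik_path.append(float(ll_v.sum()))

        self.delta_ = delta
        self.sigma_ = sigma
        self.loglik_ = float(ll_v.sum())
        self.loglik_path_ = np.array(loglik_path)
        self.nodes_ = nodes
        self.prior_weights_ = w
        self.converged_ = converged
        self.n_iter_ = it
        self.n_categories_ = m
        self.group_idx_ = group_idx
        if n_groups > 1:
            self.group_shift_ = shifts
            self.group_main_ = shifts.mean(axis=0)
            self.tau_ = shifts - self.group_main_[None, :]
        else:
            self.group_shift_ = None
            self.group_main_ = None
            self.tau_ = None
        self._X = X
        return self

    # -- helpers used by person estimation and diagnostics

    def person_posterior(self, X=None):
        """Posterior over quadrature nodes per person: (loglik, post)."""
        check_is_fitted(self, "delta_")
        X = self._X if X is None else np.asarray(X, dtype=float)
        obs = ~np.isnan(X)
        n_groups = 1 if self.group_shift_ is None else self.group_shift_.shape[1]
        group_idx = self.group_idx_ if X is self._X else np.zeros(len(X), dtype=int)
        shifts = self.group_shift_ if self.group_shift_ is not None else np.zeros((X.shape[1], 1))
        delta_by_group = [self.delta_ + shifts[:, g][:, None] for g in range(n_groups)]
        return _loglik_persons(X, obs, delta_by_group, group_idx, self.nodes_,
                               np.log(self.prior_weights_))

    def per_person_loglik(self, delta_flat_sigma=None):
        """Marginal log-likelihood per person at given flat parameters
        (delta entries then sigma); used for empirical-Fisher SEs."""
        X = self._X
        obs = ~np.isnan(X)
        k, m1 = self.delta_.shape
        if delta_flat_sigma is None:
            delta, sigma = self.delta_, self.sigma_
        else:
            delta = delta_flat_sigma[: k * m1].reshape(k, m1)
            sigma = delta_flat_sigma[-1]
        t, w = roots_hermitenorm(self.n_quadrature)
        w = w / w.sum()
        ll, _ = _loglik_persons(X, obs, [delta], np.zeros(len(X), dtype=int),
                                sigma * t, np.log(w))
        return ll

    def standard_errors(self) -> np.ndarray:
        """Empirical-Fisher standard errors for the step parameters,
        from outer products of per-person numerical score vectors."""
        check_is_fitted(self, "delta_")
        k, m1 = self.delta_.shape
        params = np.concatenate([self.delta_.ravel(), [self.sigma_]])
        h = 1e-4
        scores = np.zeros((len(self._X), len(params)))
        for j in range(len(params)):
            step = np.zeros_like(params)
            step[j] = h
            scores[:, j] = (self.per_person_loglik(params + step)
                            - self.per_person_loglik(params - step)) / (2 * h)
        info = scores.T @ scores
        cov = np.linalg.pinv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        self.se_delta_ = se[: k * m1].reshape(k, m1)
        self.se_sigma_ = float(se[-1])
        return self.se_delta_

    def result(self) -> PCMFit:
        check_is_fitted(self, "delta_")
        return PCMFit(self.delta_, self.sigma_, self.loglik_, self.loglik_path_,
                      self.nodes_, self.prior_weights_, self.converged_, self.n_iter_,
                      self.group_shift_, self.group_main_, self.tau_)


def fit_pcm_mml(X, n_quadrature: int = 61, **kwargs) -> PartialCreditModel:
    """Fit a PCM on IRT codes 0..m-1 (NaN missing); returns the estimator."""
    return PartialCreditModel(n_quadrature=n_quadrature, **kwargs).fit(X)


# ---------------------------------------------------------------------------
# Person estimation


@dataclass
class PersonEstimates:
    theta: np.ndarray
    se: np.ndarray
    method: str                # "WLE" | "EAP"


def _wle_solve(x_obs, delta_obs, lo=-12.0, hi=12.0):
    """Warm's weighted likelihood estimate for one response pattern."""
    r = x_obs.sum()

    def f(th):
        e, v, mu3 = pcm_moments(np.array([th]), delta_obs)
        info = v.sum()
        corr = mu3.sum() / (2 * info) if info > 1e-12 else 0.0
        return (r - e.sum()) + corr

    flo, fhi = f(lo), f(hi)
    while flo < 0 and lo > -40:
        lo -= 6
        flo = f(lo)
    while fhi > 0 and hi < 40:
        hi += 6
        fhi = f(hi)
    if flo * fhi > 0:
        return (lo if abs(flo) < abs(fhi) else hi)
    return optimize.brentq(f, lo, hi, xtol=1e-8)


def estimate_persons(model: PartialCreditModel, X=None, method: str = "WLE",
                     eap_quadrature: int = 101) -> PersonEstimates:
    """WLE or EAP person estimates from a fitted PCM.

    WLE solves the bias-corrected score equation and stays finite for
    extreme patterns; EAP is the posterior mean under Normal(0, sigma^2)
    with the posterior standard deviation as SE, integrated on its own
    (finer) Gauss-Hermite grid.  All-missing persons get NaN estimates.
    """
    check_is_fitted(model, "delta_")
    X = model._X if X is None else np.asarray(X, dtype=float)
    obs = ~np.isnan(X)
    n = X.shape[0]
    theta = np.full(n, np.nan)
    se = np.full(n, np.nan)

    if method.upper() == "EAP":
        q = max(eap_quadrature, model.n_quadrature)
        t, w = roots_hermitenorm(q)
        w = w / w.sum()
        nodes = model.sigma_ * t
        n_groups = 1 if model.group_shift_ is None else model.group_shift_.shape[1]
        shifts = model.group_shift_ if model.group_shift_ is not None else np.zeros((X.shape[1], 1))
        group_idx = (model.group_idx_ if (model._X is X and model.group_idx_ is not None)
                     else np.zeros(n, dtype=int))
        delta_by_group = [model.delta_ + shifts[:, g][:, None] for g in range(n_groups)]
        ll, post = _loglik_persons(X, obs, delta_by_group, group_idx, nodes, np.log(w))
        any_obs = obs.any(axis=1)
        mean = post @ nodes
        var = post @ nodes**2 - mean**2
        theta[any_obs] = mean[any_obs]
        se[any_obs] = np.sqrt(np.clip(var[any_obs], 1e-12, None))
        return PersonEstimates(theta, se, "EAP")

    if method.upper() != "WLE":
        raise ValueError("method must be 'WLE' or 'EAP'")

    cache: dict = {}
    for v in range(n):
        if not obs[v].any():
            continue
        key = (tuple(np.nonzero(obs[v])[0]), tuple(X[v, obs[v]].astype(int)))
        if key not in cache:
            items = list(key[0])
            x_obs = np.array(key[1], dtype=float)
            delta_obs = model.delta_[items]
            th = _wle_solve(x_obs, delta_obs)
            _, v_i, _ = pcm_moments(np.array([th]), delta_obs)
            info = float(v_i.sum())
            cache[key] = (th, 1.0 / np.sqrt(max(info, 1e-12)))
        theta[v], se[v] = cache[key]
    return PersonEstimates(theta, se, "WLE")


def reliability(persons: PersonEstimates, model: PartialCreditModel | None = None) -> float:
    """WLE reliability 1 - mean(SE^2)/var(theta_hat), or EAP reliability
    var(EAP)/(var(EAP) + mean posterior variance)."""
    ok = ~np.isnan(persons.theta)
    th, s = persons.theta[ok], persons.se[ok]
    var = float(np.var(th, ddof=1))
    if var <= 0:
        raise EstimationError("degenerate person-estimate variance")
    if persons.method == "WLE":
        return float(1.0 - np.mean(s**2) / var)
    return float(var / (var + np.mean(s**2)))


# ---------------------------------------------------------------------------
# Nominal categories model


@dataclass
class NRMFit:
    slopes: np.ndarray         # (k, m), first category anchored at 0
    intercepts: np.ndarray     # (k, m)
    ordered: np.ndarray        # bool per item: slopes strictly increasing
    unstable: np.ndarray       # bool per item: a category below min share
    loglik: float


def _nrm_probs(theta, a, c):
    """theta (q,), a/c (m,) -> (q, m)."""
    z = theta[:, None] * a[None, :] + c[None, :]
    z -= z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


class NominalResponseModel(BaseEstimator):
    """Nominal categories model by MML-EM, latent fixed N(0, 1).

    Per item and category x: log P(x) prop. a_x theta + c_x with category 0
    anchored (a_0 = c_0 = 0).  An item's response categories are "ordered"
    when the estimated slopes increase strictly with the category code.
    Categories endorsed by fewer than ``min_share`` of respondents make the
    ordering decision unstable and are flagged.
    """

    def __init__(self, n_quadrature: int = 31, tol: float = 1e-4,
                 max_iter: int = 200, min_share: float = 0.01):
        self.n_quadrature = n_quadrature
        self.tol = tol
        self.max_iter = max_iter
        self.min_share = min_share

    def fit(self, X):
        X = np.asarray(X, dtype=float)
        n, k = X.shape
        obs = ~np.isnan(X)
        m = int(np.nanmax(X)) + 1
        Xi = np.where(obs, X, 0).astype(int)
        t, w = roots_hermitenorm(self.n_quadrature)
        w = w / w.sum()
        nodes = t
        log_prior = np.log(w)

        a = np.tile(np.arange(m, dtype=float), (k, 1))   # PCM-like start
        c = np.zeros((k, m))

        def person_ll():
            ll_vq = np.zeros((n, len(nodes)))
            for i in range(k):
                logp = np.log(np.clip(_nrm_probs(nodes, a[i], c[i]), 1e-300, None))
                ll_vq[obs[:, i]] += logp[:, Xi[obs[:, i], i]].T
            joint = ll_vq + log_prior[None, :]
            ll = logsumexp(joint, axis=1)
            return ll, np.exp(joint - ll[:, None])

        prev = None
        for _ in range(self.max_iter):
            ll, post = person_ll()
            total = float(ll.sum())
            old = np.concatenate([a.ravel(), c.ravel()])
            for i in range(k):
                sel = obs[:, i]
                onehot = np.zeros((sel.sum(), m))
                onehot[np.arange(sel.sum()), Xi[sel, i]] = 1.0
                counts = post[sel].T @ onehot            # (q, m)

                def neg(p, counts=counts):
                    ai = np.concatenate([[0.0], p[: m - 1]])
                    ci = np.concatenate([[0.0], p[m - 1:]])
                    pr = _nrm_probs(nodes, ai, ci)
                    obj = float((counts * np.log(np.clip(pr, 1e-300, None))).sum())
                    n_q = counts.sum(axis=1)
                    resid = counts - n_q[:, None] * pr   # (q, m)
                    ga = (resid * nodes[:, None]).sum(axis=0)[1:]
                    gc = resid.sum(axis=0)[1:]
                    return -obj, -np.concatenate([ga, gc])

                p0 = np.concatenate([a[i, 1:], c[i, 1:]])
                res = optimize.minimize(neg, p0, jac=True, method="L-BFGS-B",
                                        options={"maxiter": 50})
                a[i] = np.concatenate([[0.0], res.x[: m - 1]])
                c[i] = np.concatenate([[0.0], res.x[m - 1:]])
            change = np.max(np.abs(np.concatenate([a.ravel(), c.ravel()]) - old))
            prev = total
            if change < self.tol:
                break

        ll, _ = person_ll()
        unstable = np.zeros(k, dtype=bool)
        for i in range(k):
            col = X[obs[:, i], i]
            freq = np.array([(col == x).mean() for x in range(m)])
            unstable[i] = bool((freq < self.min_share).any())
        ordered = np.array([bool(np.all(np.diff(a[i]) > 0)) for i in range(k)])

        self.slopes_ = a
        self.intercepts_ = c
        self.ordered_ = ordered
        self.unstable_ = unstable
        self.loglik_ = float(ll.sum())
        return self

    def result(self) -> NRMFit:
        check_is_fitted(self, "slopes_")
        return NRMFit(self.slopes_, self.intercepts_, self.ordered_,
                      self.unstable_, self.loglik_)


def fit_nrm(X, **kwargs) -> NRMFit:
    """Fit the nominal categories model on IRT codes 0..m-1."""
    return NominalResponseModel(**kwargs).fit(X).result()
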