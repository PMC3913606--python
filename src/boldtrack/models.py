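"""Mixed models, repeatability and likelihood-ratio testing.

Everything is fitted by maximum likelihood (ML), never REML, because all
hypothesis tests here are ANOVA-style comparisons of a full model to the
model without the term of interest, and ML log-likelihoods are the only
ones comparable across fixed-effect structures.

Contents
--------
* Gaussian random-intercept LMM via profile likelihood over the variance
  ratio (closed-form GLS given the ratio, scalar optimisation) — the engine
  behind repeatability (ICC) with parametric-bootstrap uncertainty and a
  boundary-corrected likelihood-ratio p-value.
* Binomial GLM (delegated to statsmodels' IRLS) with separation detection.
* Binomial and cumulative-logit (proportional odds) models with random
  intercepts: a single factor is integrated by adaptive Gauss–Hermite
  quadrature, two factors (nested or crossed) by a Laplace approximation.
* Likelihood-ratio tests and the breeding-success (fitness) analysis with
  sex × score × SSTa interactions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

# SSTa tercile bands of year quality (deg C anomaly, Sep-Nov mean)
SSTA_LOW = (-0.60, -0.36)
SSTA_MEDIUM = (-0.36, -0.15)
SSTA_HIGH = (-0.15, 0.13)


def ssta_band(ssta: float) -> str:
    """Year-quality band from the SSTa tercile boundaries (-0.36, -0.15)."""
    if ssta < SSTA_LOW[1]:
        return "low"
    if ssta < SSTA_MEDIUM[1]:
        return "medium"
    return "high"


# ---------------------------------------------------------------------------
# result containers


@dataclass
class ModelFit:
    family: str  # gaussian | binomial | ordinal
    params: dict[str, float]
    loglik: float
    n_params: int
    nobs: int
    converged: bool = True
    re_variances: dict[str, float] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def coef(self, name: str) -> float:
        return self.params[name]


@dataclass(frozen=True)
class LRTResult:
    chi2: float
    df: int
    p: float
    term: str | None = None


@dataclass
class RepeatabilityEstimate:
    r: float
    var_individual: float
    var_residual: float
    se: float | None
    ci: tuple[float, float] | None
    p: float


def lrt(full: ModelFit, reduced: ModelFit, term: str | None = None) -> LRTResult:
    """Chi-square comparison of nested ML fits (ANOVA model comparison)."""
    if full.nobs != reduced.nobs:
        raise ValueError(f"row-count mismatch: {full.nobs} vs {reduced.nobs}")
    df = full.n_params - reduced.n_params
    if df < 1:
        raise ValueError("models are not nested (full has no extra parameters)")
    chi2 = 2.0 * (full.loglik - reduced.loglik)
    if chi2 < 0:
        if chi2 < -1e-6:
            logger.warning("negative LRT statistic %.3g clamped to 0", chi2)
        chi2 = 0.0
    return LRTResult(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)), term=term)


# ---------------------------------------------------------------------------
# Gaussian random-intercept LMM (profile likelihood)


@dataclass
class LMMFit(ModelFit):
    # retained for bootstrap refits
    _y: np.ndarray | None = None
    _X: np.ndarray | None = None
    _codes: np.ndarray | None = None
    _xnames: list[str] | None = None


def _lmm_profile(y, X, codes, n_groups, lam):
    """Profile -2 log-likelihood pieces for variance ratio lam = s2_b/s2_e."""
    n, p = X.shape
    n_i = np.bincount(codes, minlength=n_groups).astype(float)
    shrink = lam / (1.0 + lam * n_i)  # per-group J-term weight
    Sx = np.zeros((n_groups, p))
    for j in range(p):
        Sx[:, j] = np.bincount(codes, weights=X[:, j], minlength=n_groups)
    Sy = np.bincount(codes, weights=y, minlength=n_groups)
    XtVX = X.T @ X - (Sx * shrink[:, None]).T @ Sx
    XtVy = X.T @ y - Sx.T @ (shrink * Sy)
    beta = np.linalg.solve(XtVX, XtVy)
    r = y - X @ beta
    Sr = np.bincount(codes, weights=r, minlength=n_groups)
    quad = r @ r - shrink @ Sr**2
    s2 = quad / n
    logdet = np.log1p(lam * n_i).sum()
    ll = -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
    return ll, beta, s2


def fit_lmm_random_intercept(y, X, groups, xnames=None) -> LMMFit:
    """ML fit of y = X beta + b_group + e with one random intercept.

    The likelihood is profiled over the between/within variance ratio and
    maximised by bounded scalar search on the log-ratio, with the boundary
    (ratio 0, i.e. plain OLS) evaluated explicitly.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    codes, levels = pd.factorize(np.asarray(groups), sort=True)
    G = len(levels)
    if G < 2:
        raise ValueError("need >= 2 groups")

    def negll(loglam):
        return -_lmm_profile(y, X, codes, G, np.exp(loglam))[0]

    res = optimize.minimize_scalar(negll, bounds=(-14.0, 14.0), method="bounded",
                                   options={"xatol": 1e-10})
    ll_in, lam = -res.fun, float(np.exp(res.x))
    ll0 = _lmm_profile(y, X, codes, G, 0.0)[0]
    if ll0 >= ll_in:
        lam, ll = 0.0, ll0
    else:
        ll = ll_in
    _, beta, s2 = _lmm_profile(y, X, codes, G, lam)
    if xnames is None:
        xnames = [f"x{j}" for j in range(X.shape[1])]
    params = dict(zip(xnames, beta))
    return LMMFit(
        family="gaussian",
        params=params,
        loglik=float(ll),
        n_params=X.shape[1] + 2,
        nobs=len(y),
        re_variances={"group": float(lam * s2), "residual": float(s2)},
        extra={"lambda": lam},
        _y=y, _X=X, _codes=codes, _xnames=list(xnames),
    )


def _lmm_boundary_p(fit: LMMFit) -> float:
    """LRT p-value for var_individual = 0 against the 50:50 chi-square
    mixture reference (the variance sits on the parameter boundary)."""
    ll0 = _lmm_profile(fit._y, fit._X, fit._codes,
                       int(fit._codes.max()) + 1, 0.0)[0]
    chi2 = max(0.0, 2.0 * (fit.loglik - ll0))
    if chi2 <= 1e-12:
        return 1.0
    return float(0.5 * stats.chi2.sf(chi2, 1))


def repeatability(fit: LMMFit, n_boot: int = 1000, rng=None) -> RepeatabilityEstimate:
    """ICC from the variance ratio of a converged Gaussian fit.

    Uncertainty by parametric bootstrap (simulate from the fitted model,
    refit, percentile CI); significance by the boundary-mixture LRT.
    """
    vb, ve = fit.re_variances["group"], fit.re_variances["residual"]
    r = vb / (vb + ve) if vb + ve > 0 else 0.0
    p = _lmm_boundary_p(fit)
    se = ci = None
    if n_boot and n_boot > 0:
        rng = np.random.default_rng(rng)
        G = int(fit._codes.max()) + 1
        mu = fit._X @ np.array([fit.params[k] for k in fit._xnames])
        draws = np.empty(n_boot)
        for b in range(n_boot):
            bb = rng.normal(0.0, np.sqrt(vb), G)
            ysim = mu + bb[fit._codes] + rng.normal(0.0, np.sqrt(ve), len(mu))
            f = fit_lmm_random_intercept(ysim, fit._X, fit._codes)
            vbs, ves = f.re_variances["group"], f.re_variances["residual"]
            draws[b] = vbs / (vbs + ves) if vbs + ves > 0 else 0.0
        se = float(draws.std(ddof=1))
        ci = (float(np.percentile(draws, 2.5)), float(np.percentile(draws, 97.5)))
        if vb == 0.0 and ci[0] > 0:
            ci = (0.0, ci[1])
    return RepeatabilityEstimate(r=float(r), var_individual=float(vb),
                                 var_residual=float(ve), se=se, ci=ci, p=p)


# ---------------------------------------------------------------------------
# binomial GLM (statsmodels IRLS) with separation detection


class SeparationError(RuntimeError):
    pass


def fit_glm_binomial(y, X, xnames=None) -> ModelFit:
    """Logistic regression via statsmodels' IRLS; complete separation is
    reported as an error rather than returned as diverging coefficients."""
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError("binomial response must be 0/1")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        except (PerfectSeparationWarning, Exception) as err:  # noqa: BLE001
            if "erfect" in str(type(err).__name__) + str(err):
                raise SeparationError("complete separation detected") from err
            raise
    if np.max(np.abs(res.params)) > 30:
        raise SeparationError("diverging coefficients suggest separation")
    if xnames is None:
        xnames = [f"x{j}" for j in range(X.shape[1])]
    return ModelFit(
        family="binomial",
        params=dict(zip(xnames, res.params)),
        loglik=float(res.llf),
        n_params=X.shape[1],
        nobs=len(y),
        extra={"bse": dict(zip(xnames, res.bse))},
    )


# ---------------------------------------------------------------------------
# likelihood families (per-observation log-lik and derivatives in eta)


class _Bernoulli:
    name = "binomial"

    @staticmethod
    def ll(eta, y):
        # -log(1+exp(eta)) computed stably
        return y * eta - np.logaddexp(0.0, eta)

    @staticmethod
    def d1(eta, y):
        return y - special.expit(eta)

    @staticmethod
    def d2(eta, y):
        p = special.expit(eta)
        return -p * (1.0 - p)


class _CumulativeLogit:
    """Proportional-odds likelihood: P(y <= k) = logistic(alpha_k - eta)."""

    name = "ordinal"

    def __init__(self, alphas: np.ndarray):
        self.a = np.concatenate([[-np.inf], np.asarray(alphas, float), [np.inf]])

    def _probs(self, eta, y):
        F1 = special.expit(self.a[y + 1] - eta)
        F0 = special.expit(self.a[y] - eta)
        return F0, F1

    def ll(self, eta, y):
        F0, F1 = self._probs(eta, y)
        return np.log(np.clip(F1 - F0, 1e-300, None))

    def d1(self, eta, y):
        F0, F1 = self._probs(eta, y)
        P = np.clip(F1 - F0, 1e-300, None)
        f1 = F1 * (1 - F1)
        f0 = F0 * (1 - F0)
        return -(f1 - f0) / P

    def d2(self, eta, y):
        F0, F1 = self._probs(eta, y)
        P = np.clip(F1 - F0, 1e-300, None)
        f1 = F1 * (1 - F1)
        f0 = F0 * (1 - F0)
        dP = -(f1 - f0)
        d2P = f1 * (1 - 2 * F1) - f0 * (1 - 2 * F0)
        return d2P / P - (dP / P) ** 2


# ---------------------------------------------------------------------------
# random-intercept integration: adaptive Gauss-Hermite and Laplace


def _group_mode(family, eta, y, codes, G, sigma, tol=1e-9, max_iter=100):
    """Per-group mode and curvature of the integrand exponent h(u) =
    sum_j ll(eta_j + sigma*u) - u^2/2, vectorised over groups with
    per-group backtracking."""
    u = np.zeros(G)

    def per_group_obj(u):
        off = eta + sigma * u[codes]
        return np.bincount(codes, weights=family.ll(off, y), minlength=G) - 0.5 * u**2

    obj = per_group_obj(u)
    for _ in range(max_iter):
        off = eta + sigma * u[codes]
        g = sigma * np.bincount(codes, weights=family.d1(off, y), minlength=G) - u
        h = sigma**2 * np.bincount(codes, weights=family.d2(off, y), minlength=G) - 1.0
        step = -g / h
        scale = np.ones(G)
        for _bt in range(12):
            unew = u + scale * step
            onew = per_group_obj(unew)
            bad = onew < obj - 1e-12
            if not bad.any():
                break
            scale[bad] *= 0.5
        moved = np.max(np.abs(scale * step))
        u, obj = unew, onew
        if moved < tol:
            break
    off = eta + sigma * u[codes]
    h = sigma**2 * np.bincount(codes, weights=family.d2(off, y), minlength=G) - 1.0
    return u, -h  # mode, positive curvature


def agq_loglik(family, eta, y, codes, sigma, n_nodes=15):
    """Marginal log-likelihood with one standard-normal random intercept per
    group, scaled by ``sigma``, via adaptive Gauss-Hermite quadrature."""
    G = int(codes.max()) + 1
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    if sigma < 1e-8:
        return float(family.ll(eta, y).sum())
    mode, curv = _group_mode(family, eta, y, codes, G, sigma)
    s = 1.0 / np.sqrt(curv)
    # integral of f(u) = exp(ll_g(u)) * phi(u) over u, re-centred at the
    # per-group mode:  int f du = sqrt(2)*s * sum_k w_k exp(x_k^2) f(m + sqrt(2)*s*x_k)
    terms = np.empty((n_nodes, G))
    for k in range(n_nodes):
        u = mode + np.sqrt(2.0) * s * x[k]
        off = eta + sigma * u[codes]
        llg = np.bincount(codes, weights=family.ll(off, y), minlength=G)
        h = llg - 0.5 * u**2 - 0.5 * np.log(2 * np.pi)
        terms[k] = h + x[k] ** 2 + np.log(w[k]) + 0.5 * np.log(2.0) + np.log(s)
    return float(special.logsumexp(terms, axis=0).sum())


def _build_factors(groups, groups2):
    codes1, lev1 = pd.factorize(np.asarray(groups), sort=True)
    if groups2 is None:
        return [codes1], [len(lev1)]
    codes2, lev2 = pd.factorize(np.asarray(groups2), sort=True)
    return [codes1, codes2], [len(lev1), len(lev2)]


def laplace_loglik(family, eta, y, factors, qs, sds, tol=1e-8, max_iter=60,
                   u_init=None, u_out=None):
    """Laplace-approximate marginal log-likelihood with one random intercept
    per factor (nested or crossed), standard-normal scaled by ``sds``.

    ``u_init`` warm-starts the inner Newton solve (the outer ML optimiser
    passes the previous mode back in via ``u_out``, a one-element list).
    """
    q = sum(qs)
    offsets = np.cumsum([0] + list(qs))[:-1]
    u = np.zeros(q) if u_init is None else np.asarray(u_init, float).copy()
    nf = len(factors)
    # combined codes for cross blocks (bincount is far cheaper than add.at)
    pair = {}
    for a in range(nf):
        for b in range(a + 1, nf):
            pair[(a, b)] = factors[a] * qs[b] + factors[b]

    def eta_full(u):
        out = eta.copy()
        for f, off, s in zip(factors, offsets, sds):
            out = out + s * u[off + f]
        return out

    def hessian(w):
        H = np.eye(q)
        for a in range(nf):
            oa, qa, sa = offsets[a], qs[a], sds[a]
            diag = np.bincount(factors[a], weights=w, minlength=qa)
            H[oa:oa + qa, oa:oa + qa] += sa * sa * np.diag(diag)
            for b in range(a + 1, nf):
                ob, qb, sb = offsets[b], qs[b], sds[b]
                blk = np.bincount(pair[(a, b)], weights=w,
                                  minlength=qa * qb).reshape(qa, qb)
                H[oa:oa + qa, ob:ob + qb] += sa * sb * blk
                H[ob:ob + qb, oa:oa + qa] += sa * sb * blk.T
        return H

    def objective(u):
        return family.ll(eta_full(u), y).sum() - 0.5 * u @ u

    obj = objective(u)
    for _ in range(max_iter):
        et = eta_full(u)
        d1 = family.d1(et, y)
        w = -family.d2(et, y)
        grad = np.concatenate([
            s * np.bincount(f, weights=d1, minlength=qi)
            for f, qi, s in zip(factors, qs, sds)
        ]) - u
        H = hessian(w)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = grad / np.diag(H)
        # backtracking: Newton can overshoot on flat logistic surfaces
        scale = 1.0
        for _bt in range(12):
            unew = u + scale * step
            onew = objective(unew)
            if onew >= obj - 1e-12:
                break
            scale *= 0.5
        moved = np.max(np.abs(scale * step))
        u, obj = unew, onew
        if moved < tol:
            break
    et = eta_full(u)
    H = hessian(-family.d2(et, y))
    sign, logdet = np.linalg.slogdet(H)
    if u_out is not None:
        u_out[0] = u
    if sign <= 0:
        return -np.inf
    g = family.ll(et, y).sum() - 0.5 * u @ u
    return float(g - 0.5 * logdet)


# ---------------------------------------------------------------------------
# mixed-model fitters


def fit_glmm_binomial(y, X, groups, groups2=None, xnames=None, n_quad=15,
                      method=None, start_params=None) -> ModelFit:
    """Random-intercept logistic model by ML.

    One grouping factor: adaptive Gauss-Hermite quadrature (``n_quad``
    nodes).  Two factors (e.g. trip nested in bird, or bird crossed with
    year): Laplace approximation.  ``method`` can force "laplace" or "agq"
    for the single-factor case.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    factors, qs = _build_factors(groups, groups2)
    n_re = len(factors)
    if method is None:
        method = "agq" if n_re == 1 else "laplace"
    if method == "agq" and n_re > 1:
        raise ValueError("quadrature supports a single grouping factor")
    fam = _Bernoulli()
    p = X.shape[1]

    if start_params is not None:
        theta0 = np.asarray(start_params, float)
    else:
        try:
            start_glm = fit_glm_binomial(y, X)
            beta0 = np.array(list(start_glm.params.values()))
        except SeparationError:
            beta0 = np.zeros(p)
        theta0 = np.concatenate([beta0, np.full(n_re, np.log(0.3))])
    # random-intercept SD capped at 5 logit units: beyond that the group
    # effect saturates the response and the Laplace surface degenerates
    bounds = [(-20.0, 20.0)] * p + [(-8.0, np.log(5.0))] * n_re

    warm = [None]

    def negll(theta):
        eta = X @ theta[:p]
        sds = np.exp(theta[p:])
        if method == "agq":
            ll = agq_loglik(fam, eta, y, factors[0], sds[0], n_nodes=n_quad)
        else:
            ll = laplace_loglik(fam, eta, y, factors, qs, sds,
                                u_init=warm[0], u_out=warm)
        return -ll if np.isfinite(ll) else 1e12

    res = optimize.minimize(negll, theta0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-10, "gtol": 1e-7})
    theta = res.x
    if xnames is None:
        xnames = [f"x{j}" for j in range(p)]
    re_names = ["group"] if n_re == 1 else ["group", "group2"]
    sds = np.exp(theta[p:])
    suspect = bool(np.max(np.abs(theta[:p])) > 15)
    if suspect:
        logger.warning("GLMM fixed effect beyond +/-15 logits: "
                       "possible (quasi-)separation; interpret with care")
    return ModelFit(
        family="binomial",
        params=dict(zip(xnames, theta[:p])),
        loglik=float(-res.fun),
        n_params=p + n_re,
        nobs=len(y),
        converged=bool(res.success),
        re_variances=dict(zip(re_names, (sds**2).tolist())),
        extra={"method": method, "opt_message": str(res.message),
               "separation_suspect": suspect},
    )


def fit_ordinal(y, X=None, groups=None, groups2=None, xnames=None,
                n_quad=15, start_params=None) -> ModelFit:
    """Proportional-odds (cumulative logit) model by ML, optionally with one
    random intercept (quadrature) or a nested/crossed pair (Laplace).

    ``y`` is integer-coded 0..K-1 in habitat order; empty categories are
    collapsed with a warning.
    """
    y = np.asarray(y)
    codes, levels = pd.factorize(y, sort=True)
    K = len(levels)
    if K < 2:
        raise ValueError("need >= 2 observed categories")
    if np.issubdtype(np.asarray(y).dtype, np.integer) and int(np.max(y)) + 1 > K:
        logger.warning("ordinal response has empty categories; collapsed to "
                       "%d observed levels", K)
    if X is None:
        X = np.empty((len(y), 0))
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    p = X.shape[1]
    factors, qs = (None, None)
    n_re = 0
    if groups is not None:
        factors, qs = _build_factors(groups, groups2)
        n_re = len(factors)

    # start values: thresholds at empirical cumulative logits, beta = 0
    freq = np.bincount(codes, minlength=K) / len(codes)
    cum = np.clip(np.cumsum(freq)[:-1], 1e-6, 1 - 1e-6)
    a0 = special.logit(cum)
    d0 = np.concatenate([[a0[0]], np.log(np.clip(np.diff(a0), 1e-3, None))])
    theta0 = np.concatenate([d0, np.zeros(p), np.full(n_re, np.log(0.3))])
    if start_params is not None:
        theta0 = np.asarray(start_params, float)

    def unpack(theta):
        alphas = np.concatenate([[theta[0]], theta[0] + np.cumsum(np.exp(theta[1:K - 1]))])
        beta = theta[K - 1:K - 1 + p]
        sds = np.exp(theta[K - 1 + p:])
        return alphas, beta, sds

    warm = [None]

    def negll(theta):
        alphas, beta, sds = unpack(theta)
        fam = _CumulativeLogit(alphas)
        eta = X @ beta if p else np.zeros(len(codes))
        if n_re == 0:
            ll = fam.ll(eta, codes).sum()
        elif n_re == 1:
            ll = agq_loglik(fam, eta, codes, factors[0], sds[0], n_nodes=n_quad)
        else:
            ll = laplace_loglik(fam, eta, codes, factors, qs, sds,
                                u_init=warm[0], u_out=warm)
        return -ll if np.isfinite(ll) else 1e12

    bounds = [(None, None)] * (K - 1 + p) + [(-8.0, np.log(5.0))] * n_re
    res = optimize.minimize(negll, theta0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12})
    alphas, beta, sds = unpack(res.x)
    if xnames is None:
        xnames = [f"x{j}" for j in range(p)]
    params = {f"threshold_{k + 1}": float(a) for k, a in enumerate(alphas)}
    params.update(dict(zip(xnames, beta)))
    re_names = ["group", "group2"][:n_re]
    return ModelFit(
        family="ordinal",
        params=params,
        loglik=float(-res.fun),
        n_params=K - 1 + p + n_re,
        nobs=len(y),
        converged=bool(res.success),
        re_variances=dict(zip(re_names, (sds**2).tolist())),
        extra={"categories": list(levels)},
    )


# ---------------------------------------------------------------------------
# nested-comparison helpers (fit reduced, warm-start full from it)


def glmm_binomial_term_test(y, X_full, xnames, drop, groups, groups2=None):
    """LRT for one fixed-effect column of a binomial GLMM.

    Fits the reduced model without column ``drop`` (by name), then the full
    model warm-started at the reduced optimum with the dropped coefficient
    at zero, so the likelihood comparison cannot go negative through
    optimiser noise.  Returns (lrt_result, full_fit, reduced_fit).
    """
    X_full = np.asarray(X_full, float)
    j = list(xnames).index(drop)
    keep = [i for i in range(X_full.shape[1]) if i != j]
    red_names = [xnames[i] for i in keep]
    reduced = fit_glmm_binomial(y, X_full[:, keep], groups, groups2,
                                xnames=red_names)
    beta = np.zeros(X_full.shape[1])
    for i, name in zip(keep, red_names):
        beta[i] = reduced.params[name]
    logsds = [0.5 * np.log(max(v, 1e-12)) for v in reduced.re_variances.values()]
    full = fit_glmm_binomial(y, X_full, groups, groups2, xnames=list(xnames),
                             start_params=np.concatenate([beta, logsds]))
    return lrt(full, reduced, term=drop), full, reduced


def ordinal_term_test(y, X_full, xnames, drop, groups=None, groups2=None):
    """LRT for one fixed-effect column of a cumulative-logit model, with
    the same warm-start guarantee as :func:`glmm_binomial_term_test`."""
    X_full = np.asarray(X_full, float)
    j = list(xnames).index(drop)
    keep = [i for i in range(X_full.shape[1]) if i != j]
    red_names = [xnames[i] for i in keep]
    reduced = fit_ordinal(y, X_full[:, keep], groups=groups, groups2=groups2,
                          xnames=red_names)
    K = len(reduced.extra["categories"])
    alphas = [reduced.params[f"threshold_{k + 1}"] for k in range(K - 1)]
    d = np.concatenate([[alphas[0]],
                        np.log(np.clip(np.diff(alphas), 1e-6, None))]) if K > 2 \
        else np.array([alphas[0]])
    beta = np.zeros(X_full.shape[1])
    for i, name in zip(keep, red_names):
        beta[i] = reduced.params[name]
    logsds = [0.5 * np.log(max(v, 1e-12)) for v in reduced.re_variances.values()]
    start = np.concatenate([d, beta, logsds])
    full = fit_ordinal(y, X_full, groups=groups, groups2=groups2,
                       xnames=list(xnames), start_params=start)
    return lrt(full, reduced, term=drop), full, reduced


# ---------------------------------------------------------------------------
# fitness analysis


FITNESS_TERMS = ["intercept", "score", "sex", "ssta",
                 "score:sex", "score:ssta", "sex:ssta", "score:sex:ssta"]
INTERACTION_TERMS = ["score:sex", "score:ssta", "sex:ssta", "score:sex:ssta"]


def _fitness_design(df: pd.DataFrame):
    s = df["score"].to_numpy(float)
    m = (df["sex"].astype(str).str.lower().map({"female": 0.0, "male": 1.0})
         .to_numpy(float))
    if np.isnan(m).any():
        raise ValueError("sex must be 'female' or 'male'")
    a = df["ssta"].to_numpy(float)
    cols = {
        "intercept": np.ones(len(df)), "score": s, "sex": m, "ssta": a,
        "score:sex": s * m, "score:ssta": s * a, "sex:ssta": m * a,
        "score:sex:ssta": s * m * a,
    }
    return cols


def fitness_analysis(breeding: pd.DataFrame, scores: pd.Series,
                     ssta: pd.Series, score_name: str = "score"):
    """Multi-year breeding-success analysis.

    ``breeding`` has columns bird_id, year, sex, success (0/1); ``scores``
    is the mean-centred personality score per bird; ``ssta`` maps year to
    the Sep-Nov SSTa.  Fledging is modelled on the logit scale with the
    full score x sex x SSTa interaction structure and random intercepts for
    bird and year; the headline test drops the four interaction terms
    (score:sex, score:ssta, sex:ssta and the three-way), a 4-df comparison.

    Returns a dict with the full and reduced fits, the 4-df LRTResult, and
    the analysis table used.
    """
    df = breeding.copy()
    df["score"] = df["bird_id"].map(scores)
    df = df.dropna(subset=["score"])
    missing_years = sorted(set(df["year"]) - set(ssta.index))
    if missing_years:
        raise ValueError(f"no SSTa value for year(s): {missing_years}")
    df["ssta"] = df["year"].map(ssta)
    cols = _fitness_design(df)
    y = df["success"].to_numpy(float)
    Xfull = np.column_stack([cols[t] for t in FITNESS_TERMS])
    reduced_terms = [t for t in FITNESS_TERMS if t not in INTERACTION_TERMS]
    Xred = np.column_stack([cols[t] for t in reduced_terms])
    reduced = fit_glmm_binomial(y, Xred, groups=df["bird_id"], groups2=df["year"],
                                xnames=reduced_terms)
    # warm-start the full model at the reduced optimum (interactions at 0):
    # descent from there guarantees ll_full >= ll_reduced
    start = np.concatenate([
        [reduced.params[t] for t in reduced_terms],
        np.zeros(len(INTERACTION_TERMS)),
        [0.5 * np.log(max(v, 1e-12)) for v in reduced.re_variances.values()],
    ])
    full = fit_glmm_binomial(y, Xfull, groups=df["bird_id"], groups2=df["year"],
                             xnames=FITNESS_TERMS, start_params=start)
    test = lrt(full, reduced, term=f"{score_name} x sex x SSTa (4 df)")
    return {"full": full, "reduced": reduced, "interaction_test": test, "data": df}


def single_year_fitness(breeding_year: pd.DataFrame, scores: pd.Series):
    """Single-season analysis: success ~ score * sex by logistic GLM (one
    record per bird, so no random structure is identifiable).

    Returns LRTs for the score main effect and the score x sex interaction.
    """
    df = breeding_year.copy()
    df["score"] = df["bird_id"].map(scores)
    df = df.dropna(subset=["score"])
    s = df["score"].to_numpy(float)
    m = (df["sex"].astype(str).str.lower().map({"female": 0.0, "male": 1.0})
         .to_numpy(float))
    y = df["success"].to_numpy(float)
    one = np.ones(len(df))
    fit_full = fit_glm_binomial(y, np.column_stack([one, s, m, s * m]),
                                xnames=["intercept", "score", "sex", "score:sex"])
    fit_nosx = fit_glm_binomial(y, np.column_stack([one, s, m]),
                                xnames=["intercept", "score", "sex"])
    fit_noscore = fit_glm_binomial(y, np.column_stack([one, m]),
                                   xnames=["intercept", "sex"])
    return {
        "score": lrt(fit_nosx, fit_noscore, term="score"),
        "score:sex": lrt(fit_full, fit_nosx, term="score:sex"),
        "full": fit_full,
    }


def prediction_curves(fit: ModelFit, score_grid=None) -> pd.DataFrame:
    """Fixed-effect predicted fledging probability over a score grid for
    each sex x SSTa band (band midpoints; random effects at zero) —
    the stratified curves behind the year-quality plots."""
    if score_grid is None:
        score_grid = np.linspace(-3.0, 3.0, 61)
    bands = {"low": np.mean(SSTA_LOW), "medium": np.mean(SSTA_MEDIUM),
             "high": np.mean(SSTA_HIGH)}
    rows = []
    for band, a in bands.items():
        for sex, m in [("female", 0.0), ("male", 1.0)]:
            for s in score_grid:
                eta = (fit.params["intercept"] + fit.params["score"] * s
                       + fit.params["sex"] * m + fit.params["ssta"] * a
                       + fit.params["score:sex"] * s * m
                       + fit.params["score:ssta"] * s * a
                       + fit.params["sex:ssta"] * m * a
                       + fit.params["score:sex:ssta"] * s * m * a)
                rows.append({"band": band, "sex": sex, "score": s,
                             "p_fledge": float(special.expit(eta))})
    return pd.DataFrame(rows)
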