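"""Cumulative-odds ordinal logistic regression with partial proportional odds.

The outcome equation of the mediation model is a cumulative logit for a
K-level ordinal response Y (here K = 4 sleep-disturbance categories):

    logit P(Y > j | x) = alpha_j + sum_k beta_k x_k,          j = 0..K-2

Under proportional odds each predictor has one slope across all K-1 cuts.
A *partial* proportional-odds model relaxes that constraint for a chosen
subset of predictors, giving each of them one slope per cut
(beta_{k,0}, .., beta_{k,K-2}); no ordering constraint is imposed on the
per-cut slopes, so cell probabilities

    P(Y = j) = P(Y > j-1) - P(Y > j)

can approach zero and the likelihood is maximised over the region where
they stay positive (invalid steps are rejected by the optimiser).

With this parameterisation a positive slope means higher odds of a more
frequent/severe outcome, and the fitted alpha_j decrease in j. Estimation
is maximum likelihood with an analytic gradient (quasi-Newton with a
Newton polish using a finite-difference Hessian of the analytic gradient);
standard errors come from the observed information at the optimum, and
coefficient p-values are Wald z tests.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .dataset import Dataset
from .errors import (
    ConvergenceError,
    InsufficientDataError,
    SingularDesignError,
    ValidationError,
)

__all__ = [
    "CumulativeLogit",
    "MultinomialFit",
    "LRTResult",
    "fit_cumulative_logit",
    "fit_multinomial",
    "likelihood_ratio_test",
    "odds_ratio",
]


# ---------------------------------------------------------------------------
# likelihood core (module-level for speed; reused by the bootstrap loop)
# ---------------------------------------------------------------------------

def _nll_grad(theta, Xp, Xn, A, Bm, K):
    """Negative log-likelihood and gradient.

    Xp : (n, p_par) parallel-slope design (no intercept column)
    Xn : (n, p_np)  relaxed-slope design
    A  : (n, K-1) boolean, A[i, j] = (y_i == j + 1)
    Bm : (n, K-1) boolean, Bm[i, j] = (y_i == j)
    theta = [alpha_0..alpha_{K-2}, beta_par, vec(beta_np by predictor)]
    """
    n = A.shape[0]
    J = K - 1
    p_par = Xp.shape[1]
    alpha = theta[:J]
    H = np.tile(alpha, (n, 1))
    if p_par:
        H += (Xp @ theta[J:J + p_par])[:, None]
    if Xn.shape[1]:
        Bn = theta[J + p_par:].reshape(Xn.shape[1], J)
        H += Xn @ Bn
    G = expit(H)                      # survivor probabilities P(Y > j)
    # observed-cell probability: gamma_{y-1} - gamma_y, gamma_{-1}=1, gamma_{K-1}=0
    p_prev = np.where(Bm[:, 0], 1.0, (A * G).sum(axis=1))  # gamma_{y-1}
    p_next = (Bm * G).sum(axis=1)                          # gamma_y (0 if y = K-1)
    p_obs = p_prev - p_next
    if np.min(p_obs) <= 0.0 or not np.all(np.isfinite(p_obs)):
        return np.inf, np.zeros_like(theta)
    nll = -np.log(p_obs).sum()
    W = G * (1.0 - G)
    g = W * (A - Bm) / p_obs[:, None]          # dloglik/deta_j per obs
    grad = np.empty_like(theta)
    grad[:J] = g.sum(axis=0)
    if p_par:
        grad[J:J + p_par] = Xp.T @ g.sum(axis=1)
    if Xn.shape[1]:
        grad[J + p_par:] = (Xn.T @ g).ravel()
    return nll, -grad


def _design_cuts(Xp, Xn, J):
    """Per-cut design matrices C_j with d(eta_j) = C_j d(theta)."""
    n = Xp.shape[0]
    p_par, p_np = Xp.shape[1], Xn.shape[1]
    d = J + p_par + p_np * J
    Cs = []
    for j in range(J):
        C = np.zeros((n, d))
        C[:, j] = 1.0
        if p_par:
            C[:, J:J + p_par] = Xp
        for m in range(p_np):
            C[:, J + p_par + m * J + j] = Xn[:, m]
        Cs.append(C)
    return Cs


def _nll_grad_hess(theta, Xp, Xn, A, Bm, K, Cs):
    """NLL, gradient and analytic (observed-information) Hessian."""
    n = A.shape[0]
    J = K - 1
    p_par = Xp.shape[1]
    alpha = theta[:J]
    H = np.tile(alpha, (n, 1))
    if p_par:
        H += (Xp @ theta[J:J + p_par])[:, None]
    if Xn.shape[1]:
        Bn = theta[J + p_par:].reshape(Xn.shape[1], J)
        H += Xn @ Bn
    G = expit(H)
    p_prev = np.where(Bm[:, 0] > 0, 1.0, (A * G).sum(axis=1))
    p_next = (Bm * G).sum(axis=1)
    p_obs = p_prev - p_next
    if np.min(p_obs) <= 0.0 or not np.all(np.isfinite(p_obs)):
        return np.inf, None, None
    nll = -np.log(p_obs).sum()
    c = A - Bm
    W = G * (1.0 - G)
    u = c * W / p_obs[:, None]                 # dloglik/deta_j
    D = c * W * (1.0 - 2.0 * G) / p_obs[:, None]
    d = len(theta)
    grad = np.zeros(d)
    Hess = np.zeros((d, d))
    for j in range(J):
        grad += Cs[j].T @ u[:, j]
        for k in range(J):
            m_jk = -u[:, j] * u[:, k]
            if j == k:
                m_jk = m_jk + D[:, j]
            Hess += Cs[j].T @ (m_jk[:, None] * Cs[k])
    return nll, -grad, -Hess


def _start_values(y, K, p_par, p_np):
    n = len(y)
    J = K - 1
    counts = np.bincount(y, minlength=K).astype(float)
    gt = np.clip(counts[::-1].cumsum()[::-1][1:], 0.5, n - 0.5)
    return np.concatenate([np.log(gt / (n - gt)), np.zeros(p_par + p_np * J)])


def _fit_core(Xp, Xn, y, K, start=None, tol=1e-6, max_iter=500):
    """Maximise the cumulative-logit likelihood.

    Newton iterations with analytic gradient/Hessian and step halving
    (invalid steps — any non-positive fitted cell probability — are
    rejected by the halving); quasi-Newton (L-BFGS-B) fallback when a
    Newton step is unusable. Returns
    ``(theta, nll, n_iter, grad_max_norm, args)``.
    """
    J = K - 1
    A = (y[:, None] == np.arange(1, K)[None, :]).astype(float)
    Bm = (y[:, None] == np.arange(0, J)[None, :]).astype(float)
    args = (Xp, Xn, A, Bm, K)
    Cs = _design_cuts(Xp, Xn, J)
    if start is None:
        start = _start_values(y, K, Xp.shape[1], Xn.shape[1])
    theta = np.asarray(start, dtype=float).copy()
    f, g, Hm = _nll_grad_hess(theta, *args, Cs)
    if not np.isfinite(f):  # degenerate warm start: restart from empirical logits
        theta = _start_values(y, K, Xp.shape[1], Xn.shape[1])
        f, g, Hm = _nll_grad_hess(theta, *args, Cs)
    n_iter = 0
    stalled = False
    while n_iter < max_iter:
        if np.max(np.abs(g)) < tol:
            break
        try:
            step = np.linalg.solve(Hm, g)
        except np.linalg.LinAlgError:
            stalled = True
            break
        t = 1.0
        ftol = 1e-13 * max(1.0, abs(f))  # tolerate ulp-level noise near the optimum
        for _ in range(40):
            f_new, g_new, H_new = _nll_grad_hess(theta - t * step, *args, Cs)
            if np.isfinite(f_new) and f_new <= f + ftol:
                break
            t *= 0.5
        else:
            stalled = True
            break
        theta = theta - t * step
        f, g, Hm = f_new, g_new, H_new
        n_iter += 1
    if stalled and np.max(np.abs(g)) >= tol:
        res = optimize.minimize(
            _nll_grad, theta, args=args, jac=True, method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-15, "gtol": 1e-10},
        )
        theta = res.x
        f, g, Hm = _nll_grad_hess(theta, *args, Cs)
        n_iter += int(res.nit)
    gnorm = float(np.max(np.abs(g))) if g is not None else np.inf
    return theta, float(f), n_iter, gnorm, args


def _hessian(theta, args):
    """Observed information (Hessian of the NLL) at theta."""
    Xp, Xn, A, Bm, K = args
    Cs = _design_cuts(Xp, Xn, K - 1)
    _, _, H = _nll_grad_hess(theta, *args, Cs)
    return H


class CumulativeLogit(BaseEstimator):
    """Cumulative-odds ordinal logistic regression (optionally partial PO).

    Parameters
    ----------
    nonparallel : sequence of str
        Predictors whose proportional-odds constraint is relaxed; each gets
        one slope per cut.
    tol : float
        Convergence criterion: gradient max-norm at the optimum.
    max_iter : int
        Iteration cap for the optimiser.
    compute_se : bool
        If False, skip the observed-information standard errors (used by
        the bootstrap, which only needs point estimates).

    Fitted attributes (trailing underscore) include ``thresholds_``
    (``"0|1"`` etc. -> alpha_j on the logit P(Y > j) scale), ``slopes_``
    (name -> float, or an array of one slope per cut for relaxed
    predictors), ``se_``, ``ci95_``, ``z_``, ``p_``, ``odds_ratios_``,
    ``log_likelihood_``, ``df_resid_`` and ``n_used_``.
    """

    def __init__(self, nonparallel=(), tol=1e-6, max_iter=500, compute_se=True):
        self.nonparallel = nonparallel
        self.tol = tol
        self.max_iter = max_iter
        self.compute_se = compute_se

    # -- sklearn plumbing -------------------------------------------------
    def fit(self, X, y, feature_names=None, start=None):
        if isinstance(X, pd.DataFrame):
            feature_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if feature_names is None:
            feature_names = [f"x{i}" for i in range(X.shape[1])]
        y = np.asarray(y)
        mask = np.isfinite(X).all(axis=1) & np.isfinite(np.asarray(y, dtype=float))
        X, y = X[mask], np.asarray(y, dtype=float)[mask].astype(int)
        cats = np.unique(y)
        if len(cats) < 2:
            raise ValidationError("outcome has fewer than 2 observed categories")
        # recode to 0..K-1 in ascending order
        codes = np.searchsorted(cats, y)
        K = len(cats)
        nonpar = [f for f in self.nonparallel]
        unknown = set(nonpar) - set(feature_names)
        if unknown:
            raise ValidationError(f"nonparallel predictors not in design: {sorted(unknown)}")
        par_names = [f for f in feature_names if f not in nonpar]
        np_names = [f for f in feature_names if f in nonpar]
        cols = {nm: i for i, nm in enumerate(feature_names)}
        Xp = X[:, [cols[nm] for nm in par_names]]
        Xn = X[:, [cols[nm] for nm in np_names]]
        full = np.column_stack([np.ones(len(X)), X])
        if np.linalg.matrix_rank(full) < full.shape[1]:
            from .linear import _check_rank

            _check_rank(full, ["(Intercept)"] + feature_names)
        if len(y) < full.shape[1] + K:
            raise InsufficientDataError("too few complete cases for ordinal fit")

        theta, nll, n_iter, gnorm, args = _fit_core(
            Xp, Xn, codes, K, start=start, tol=self.tol, max_iter=self.max_iter
        )
        converged = gnorm < self.tol
        if not converged:
            raise ConvergenceError(
                "cumulative-logit fit did not converge",
                diagnostics={"grad_max_norm": gnorm, "n_iter": n_iter, "nll": nll},
            )
        J = K - 1
        names = (
            [f"{int(cats[j])}|{int(cats[j + 1])}" for j in range(J)]
            + par_names
            + [f"{nm}[{j}]" for nm in np_names for j in range(J)]
        )
        self.categories_ = cats
        self.feature_names_ = list(feature_names)
        self.parallel_names_ = par_names
        self.nonparallel_ = tuple(np_names)
        self.n_cuts_ = J
        self.theta_ = theta
        self.param_names_ = names
        self.n_params_ = len(theta)
        self.n_used_ = len(y)
        self.df_resid_ = len(y) * J - len(theta)
        self.log_likelihood_ = -float(nll)
        self.aic_ = 2 * len(theta) + 2 * float(nll)
        self.n_iter_ = n_iter
        self.converged_ = True
        self.grad_max_norm_ = gnorm
        self.thresholds_ = {names[j]: float(theta[j]) for j in range(J)}
        slopes: dict[str, object] = {}
        for i, nm in enumerate(par_names):
            slopes[nm] = float(theta[J + i])
        off = J + len(par_names)
        for i, nm in enumerate(np_names):
            slopes[nm] = theta[off + i * J: off + (i + 1) * J].copy()
        self.slopes_ = slopes

        if self.compute_se:
            H = _hessian(theta, args)
            try:
                cov = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                cov = np.linalg.pinv(H)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            zq = norm.ppf(0.975)
            self.cov_params_ = cov
            self.se_ = dict(zip(names, map(float, se)))
            self.z_ = {nm: float(theta[i] / se[i]) if se[i] > 0 else np.nan
                       for i, nm in enumerate(names)}
            self.p_ = {nm: float(2 * norm.sf(abs(z))) if np.isfinite(z) else np.nan
                       for nm, z in self.z_.items()}
            self.ci95_ = {nm: (float(theta[i] - zq * se[i]), float(theta[i] + zq * se[i]))
                          for i, nm in enumerate(names)}
            self.odds_ratios_ = {
                nm: (float(np.exp(theta[i])),
                     (float(np.exp(self.ci95_[nm][0])), float(np.exp(self.ci95_[nm][1]))))
                for i, nm in enumerate(names)
            }
        self.p_adjusted_ = None
        return self

    # -- prediction -------------------------------------------------------
    def _linear_cuts(self, X):
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names_].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        n = len(X)
        J = self.n_cuts_
        cols = {nm: i for i, nm in enumerate(self.feature_names_)}
        H = np.tile(self.theta_[:J], (n, 1))
        if self.parallel_names_:
            Xp = X[:, [cols[nm] for nm in self.parallel_names_]]
            H += (Xp @ self.theta_[J:J + len(self.parallel_names_)])[:, None]
        for nm in self.nonparallel_:
            H += X[:, [cols[nm]]] * self.slopes_[nm][None, :]
        return H

    def predict_proba(self, X):
        """Cell probabilities P(Y = category) per row, columns in category order."""
        G = expit(self._linear_cuts(X))
        n = len(G)
        full = np.column_stack([np.ones(n), G, np.zeros(n)])
        return full[:, :-1] - full[:, 1:]

    def predict(self, X):
        return self.categories_[np.argmax(self.predict_proba(X), axis=1)]

    def log_likelihood(self, X, y):
        P = self.predict_proba(X)
        codes = np.searchsorted(self.categories_, np.asarray(y))
        return float(np.log(P[np.arange(len(P)), codes]).sum())

    def to_json(self) -> str:
        payload = {
            "thresholds": self.thresholds_,
            "slopes": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                       for k, v in self.slopes_.items()},
            "nonparallel": list(self.nonparallel_),
            "log_likelihood": self.log_likelihood_,
            "n_params": self.n_params_,
            "df_resid": self.df_resid_,
            "n_used": self.n_used_,
            "n_iter": self.n_iter_,
            "grad_max_norm": self.grad_max_norm_,
        }
        if getattr(self, "se_", None) is not None and self.compute_se:
            payload.update({"se": self.se_, "p": self.p_, "p_adjusted": self.p_adjusted_})
        return json.dumps(payload)


def fit_cumulative_logit(ds: Dataset, outcome: str, predictors, nonparallel=(),
                         **kwargs) -> CumulativeLogit:
    """Fit the (partial) proportional-odds model on an equation's complete cases."""
    predictors = list(predictors)
    data = ds.table[[outcome] + predictors].dropna()
    model = CumulativeLogit(nonparallel=tuple(nonparallel), **kwargs)
    return model.fit(data[predictors], data[outcome].to_numpy(dtype=int))


# ---------------------------------------------------------------------------
# multinomial baseline-category logit (for the model-family comparison)
# ---------------------------------------------------------------------------

@dataclass
class MultinomialFit:
    log_likelihood_: float
    n_params_: int
    n_used_: int
    converged_: bool
    separation_flag: bool
    fitted_probs: np.ndarray

    @property
    def aic_(self) -> float:
        return 2 * self.n_params_ - 2 * self.log_likelihood_


def fit_multinomial(ds: Dataset, outcome: str, predictors) -> MultinomialFit:
    """Baseline-category logit (reference = lowest category) via statsmodels.

    Used only for the likelihood-ratio comparison against the cumulative
    model; reports the log-likelihood and the parameter count
    (K-1)(p+1). Quasi-separation is flagged, with capped estimates kept.
    """
    import statsmodels.api as sm

    predictors = list(predictors)
    data = ds.table[[outcome] + predictors].dropna()
    y = data[outcome].to_numpy(dtype=int)
    X = sm.add_constant(data[predictors].to_numpy(dtype=float), has_constant="add")
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.MNLogit(y, X).fit(method="newton", maxiter=200, disp=0)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            res = sm.MNLogit(y, X).fit(method="bfgs", maxiter=500, disp=0)
            converged = bool(res.mle_retvals.get("converged", True))
        if any("separation" in str(w.message).lower() or "Hessian" in str(w.message)
               for w in caught):
            separation = True
    if separation:
        warnings.warn("possible separation in multinomial fit; estimates capped",
                      stacklevel=2)
    K = len(np.unique(y))
    return MultinomialFit(
        log_likelihood_=float(res.llf),
        n_params_=(K - 1) * X.shape[1],
        n_used_=len(y),
        converged_=converged,
        separation_flag=separation,
        fitted_probs=np.asarray(res.predict()),
    )


# ---------------------------------------------------------------------------
# likelihood ratio test and odds-ratio conversion
# ---------------------------------------------------------------------------

@dataclass
class LRTResult:
    chi2: float
    df: int
    p: float
    preferred: str


def _fit_attr(fit, name):
    for nm in (name + "_", name):
        if hasattr(fit, nm):
            return getattr(fit, nm)
    raise AttributeError(f"{type(fit).__name__} lacks {name!r}")


def likelihood_ratio_test(fit_restricted, fit_general, alpha: float = 0.05,
                          labels=("restricted", "general")) -> LRTResult:
    """LRT of two fits: chi2 = 2(LL_general - LL_restricted), df = parameter gap.

    Accepts any pair of fits exposing a log-likelihood, parameter count and
    sample size (ordinal, multinomial or linear). Both fits must use the
    same rows. A chi2 below -1e-6 triggers a non-nesting warning (the
    statistic is reported clamped at 0); tiny negative values are numerical
    noise and clamp silently.
    """
    n_r, n_g = _fit_attr(fit_restricted, "n_used"), _fit_attr(fit_general, "n_used")
    if n_r != n_g:
        raise ValidationError(f"fits use different samples ({n_r} vs {n_g})")
    df = _fit_attr(fit_general, "n_params") - _fit_attr(fit_restricted, "n_params")
    if df < 0:
        raise ValidationError("fit_general has fewer parameters than fit_restricted")
    chi2 = 2.0 * (_fit_attr(fit_general, "log_likelihood")
                  - _fit_attr(fit_restricted, "log_likelihood"))
    if chi2 < -1e-6:
        warnings.warn(
            f"negative LRT statistic ({chi2:.3g}): models may not be nested",
            stacklevel=2,
        )
    chi2 = max(chi2, 0.0)
    p = 1.0 if df == 0 else float(chi2_dist.sf(chi2, df))
    preferred = labels[1] if (df > 0 and p < alpha) else labels[0]
    return LRTResult(chi2=float(chi2), df=int(df), p=p, preferred=preferred)


def odds_ratio(beta: float, ci: tuple[float, float] | None = None):
    """Convert a standardized logit coefficient (and CI) to an odds ratio."""
    if not np.isfinite(beta):
        raise ValidationError("beta must be finite")
    if ci is None:
        return float(np.exp(beta))
    lo, hi = ci
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise ValidationError("CI bounds must be finite")
    return float(np.exp(beta)), (float(np.exp(lo)), float(np.exp(hi)))
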