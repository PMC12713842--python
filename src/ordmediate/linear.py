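"""OLS mediator equations and the variance inflation factor.

Each mediator equation of the serial mediation model is an ordinary
least-squares regression of a (standardized) continuous mediator on the
exposure, any upstream mediators and retained covariates. Estimation is
delegated to statsmodels; this module shapes the result into the fields
the mediation layer consumes (coefficients, classical SEs, t-based 95%
CIs, R^2, F) and adds design-rank diagnostics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .dataset import Dataset
from .errors import InsufficientDataError, SingularDesignError


@dataclass
class LinearFit:
    """OLS estimates for one mediator equation."""

    outcome: str
    coefficients: dict[str, float]
    se: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    t: dict[str, float]
    p: dict[str, float]
    r2: float
    r2_adjusted: float
    f_stat: tuple[float, int, int]
    n_used: int
    log_likelihood: float
    aic: float
    p_adjusted: dict[str, float] | None = None
    # diagnostics payload (not serialized)
    resid: np.ndarray = field(default=None, repr=False)
    exog: np.ndarray = field(default=None, repr=False)
    exog_names: list[str] = field(default_factory=list, repr=False)

    @property
    def n_params(self) -> int:
        return len(self.coefficients)

    def to_json(self) -> str:
        payload = {
            "outcome": self.outcome,
            "coefficients": self.coefficients,
            "se": self.se,
            "ci95": self.ci95,
            "t": self.t,
            "p": self.p,
            "p_adjusted": self.p_adjusted,
            "r2": self.r2,
            "r2_adjusted": self.r2_adjusted,
            "f_stat": self.f_stat,
            "n_used": self.n_used,
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
        }
        return json.dumps(payload)


def _check_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns involved in the dependency via the null space
        _, s, vt = np.linalg.svd(X)
        null = vt[rank:]
        involved = sorted(
            {names[j] for row in null for j in np.flatnonzero(np.abs(row) > 1e-8)}
        )
        raise SingularDesignError(
            f"design is rank deficient; collinear set: {involved}", columns=involved
        )


def fit_ols(ds: Dataset | "pd.DataFrame", outcome: str, predictors) -> LinearFit:
    """Exact least-squares fit of ``outcome ~ predictors`` on complete cases."""
    predictors = list(predictors)
    table = ds.table if isinstance(ds, Dataset) else ds
    cols = [outcome] + predictors
    data = table[cols].dropna()
    n = len(data)
    if n < len(predictors) + 2:
        raise InsufficientDataError(
            f"{n} complete cases for {len(predictors)} predictors"
        )
    y = data[outcome].to_numpy(dtype=float)
    X = sm.add_constant(data[predictors].to_numpy(dtype=float), has_constant="add")
    names = ["(Intercept)"] + predictors
    _check_rank(X, names)
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    return LinearFit(
        outcome=outcome,
        coefficients=dict(zip(names, map(float, res.params))),
        se=dict(zip(names, map(float, res.bse))),
        ci95={nm: (float(lo), float(hi)) for nm, (lo, hi) in zip(names, ci)},
        t=dict(zip(names, map(float, res.tvalues))),
        p=dict(zip(names, map(float, res.pvalues))),
        r2=float(res.rsquared),
        r2_adjusted=float(res.rsquared_adj),
        f_stat=(float(res.fvalue), int(res.df_model), int(res.df_resid)),
        n_used=n,
        log_likelihood=float(res.llf),
        aic=float(res.aic),
        resid=np.asarray(res.resid),
        exog=X,
        exog_names=names,
    )


def vif(ds: Dataset | "pd.DataFrame", predictors) -> dict[str, float]:
    """Variance inflation factors: VIF_k = 1 / (1 - R^2_k).

    R^2_k comes from regressing predictor k on the remaining predictors
    (with intercept) over complete cases. Perfect collinearity yields
    ``inf`` for the affected predictors.
    """
    predictors = list(predictors)
    if len(predictors) < 2:
        raise InsufficientDataError("VIF needs at least 2 predictors")
    table = ds.table if isinstance(ds, Dataset) else ds
    data = table[predictors].dropna().to_numpy(dtype=float)
    if data.shape[0] < len(predictors) + 2:
        raise InsufficientDataError("too few complete cases for VIF")
    out: dict[str, float] = {}
    for k, name in enumerate(predictors):
        yk = data[:, k]
        Xk = np.column_stack([np.ones(len(data)), np.delete(data, k, axis=1)])
        beta, _, _, _ = np.linalg.lstsq(Xk, yk, rcond=None)
        resid = yk - Xk @ beta
        tss = np.sum((yk - yk.mean()) ** 2)
        if tss == 0:
            out[name] = float("inf")
            continue
        r2 = 1.0 - np.sum(resid**2) / tss
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else float(1.0 / (1.0 - r2))
    return out
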