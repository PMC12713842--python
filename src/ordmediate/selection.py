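"""Model-building decisions: proportional-odds testing, partial-PO structure
selection, backward covariate elimination, and BH-FDR adjustment.

The decision tree mirrors common practice for partial proportional-odds
modelling: test each candidate predictor's proportional-odds constraint
with a likelihood-ratio test (df = K-1 extra slopes per relaxed
predictor), and when several candidates violate the constraint prefer the
most parsimonious relaxation that the data cannot distinguish from the
fully relaxed model. Covariates (never the exposure or mediators) are
removed backward by largest non-significant p-value, with an AIC guard so
a covariate that improves overall fit is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .dataset import Dataset
from .errors import ValidationError
from .linear import fit_ols
from .ordinal import LRTResult, fit_cumulative_logit, likelihood_ratio_test

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionStep",
    "SelectionTrace",
    "test_proportional_odds",
    "select_nonparallel_structure",
    "backward_eliminate_covariates",
    "fdr_adjust",
]


@dataclass
class SelectionStep:
    action: str
    statistic: float | None
    df: int | None
    p: float | None
    decision: str

    def as_dict(self):
        return self.__dict__.copy()


@dataclass
class SelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)
    final_nonparallel: tuple[str, ...] = ()
    final_covariates: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def record(self, action, statistic, df, p, decision):
        step = SelectionStep(action, statistic, df, p, decision)
        self.steps.append(step)
        logger.info("%s: stat=%s df=%s p=%s -> %s", action, statistic, df, p, decision)
        return step

    def to_json_dict(self):
        return {
            "steps": [s.as_dict() for s in self.steps],
            "final_nonparallel": list(self.final_nonparallel),
            "final_covariates": {k: list(v) for k, v in self.final_covariates.items()},
        }


def test_proportional_odds(ds: Dataset, outcome: str, predictors, candidate) -> LRTResult:
    """LRT of the parallel fit against the fit with relaxed slopes for *candidate*.

    ``candidate`` may be one predictor name or a set of names; relaxing one
    predictor adds K-2 slopes (2 per predictor for a 4-level outcome), so
    df = 2 x |candidate|.
    """
    cand = [candidate] if isinstance(candidate, str) else list(candidate)
    if not set(cand) <= set(predictors):
        raise ValidationError(f"candidate {cand} not a subset of predictors")
    parallel = fit_cumulative_logit(ds, outcome, predictors, nonparallel=(),
                                    compute_se=False)
    relaxed = fit_cumulative_logit(ds, outcome, predictors, nonparallel=tuple(cand),
                                   compute_se=False)
    return likelihood_ratio_test(parallel, relaxed, labels=("parallel", "relaxed"))


def select_nonparallel_structure(ds: Dataset, outcome: str, predictors,
                                 candidates, alpha: float = 0.05) -> SelectionTrace:
    """Choose which candidate predictors get per-cut slopes.

    1. Test each candidate (and, when more than one, the joint set) for a
       proportional-odds violation against the fully parallel model.
    2. If several violate, test whether the all-relaxed model improves on
       each singly-relaxed model.
    3. If it does for every one, keep the all-relaxed model; otherwise keep
       the singly-relaxed model with the higher log-likelihood (ties: fewer
       parameters, then name order).
    """
    candidates = list(candidates)
    trace = SelectionTrace()
    single_fits = {}
    violators = []
    parallel = fit_cumulative_logit(ds, outcome, predictors, nonparallel=(),
                                    compute_se=False)
    for cand in candidates:
        fit_c = fit_cumulative_logit(ds, outcome, predictors, nonparallel=(cand,),
                                     compute_se=False)
        single_fits[cand] = fit_c
        lrt = likelihood_ratio_test(parallel, fit_c, labels=("parallel", cand))
        violated = lrt.p < alpha
        trace.record(f"po_test:{cand}", lrt.chi2, lrt.df, lrt.p,
                     "violated" if violated else "held")
        if violated:
            violators.append(cand)
    if len(candidates) > 1:
        joint = fit_cumulative_logit(ds, outcome, predictors,
                                     nonparallel=tuple(candidates), compute_se=False)
        lrt = likelihood_ratio_test(parallel, joint, labels=("parallel", "joint"))
        trace.record("po_test:joint", lrt.chi2, lrt.df, lrt.p,
                     "violated" if lrt.p < alpha else "held")

    if not violators:
        trace.record("structure", None, None, None, "fully parallel model retained")
        trace.final_nonparallel = ()
        return trace
    if len(violators) == 1:
        trace.final_nonparallel = (violators[0],)
        trace.record("structure", None, None, None,
                     f"partial PO with relaxed slopes for {violators[0]}")
        return trace

    joint = fit_cumulative_logit(ds, outcome, predictors,
                                 nonparallel=tuple(violators), compute_se=False)
    joint_better_than_all = True
    for cand in violators:
        lrt = likelihood_ratio_test(single_fits[cand], joint, labels=(cand, "joint"))
        trace.record(f"joint_vs_single:{cand}", lrt.chi2, lrt.df, lrt.p,
                     "joint better" if lrt.p < alpha else "joint not better")
        if lrt.p >= alpha:
            joint_better_than_all = False
    if joint_better_than_all:
        trace.final_nonparallel = tuple(violators)
        trace.record("structure", None, None, None,
                     f"all-relaxed model retained for {violators}")
        return trace
    # prefer the singly-relaxed candidate with the higher log-likelihood
    ranked = sorted(
        violators,
        key=lambda c: (-single_fits[c].log_likelihood_, single_fits[c].n_params_, c),
    )
    winner = ranked[0]
    lls = {c: single_fits[c].log_likelihood_ for c in violators}
    trace.record("single_model_comparison", None, None, None,
                 f"log-likelihoods {lls}; chose {winner}")
    trace.final_nonparallel = (winner,)
    return trace


def backward_eliminate_covariates(ds: Dataset, outcome: str, focal_predictors,
                                  covariates, alpha: float = 0.05, *,
                                  kind: str = "ols", nonparallel=(),
                                  criterion: str = "lrt"):
    """Backward-stepwise removal of non-significant covariates for one equation.

    Repeatedly drops the covariate with the largest p-value above *alpha*
    (t-based for OLS equations, Wald-z for the ordinal equation), refitting
    after each removal, but keeps a covariate whose removal worsens overall
    fit by the retention criterion: with ``criterion="lrt"`` (default) a
    likelihood-ratio test of the removal significant at *alpha*, with
    ``criterion="aic"`` any AIC increase. Focal predictors (exposure,
    mediators) are never eliminable. The elimination loop is run on the
    complete cases of the full starting variable set so every comparison
    shares one sample; the returned fit is refit on the final variable
    set's complete cases.

    Returns ``(trace, fit)``.
    """
    focal = list(focal_predictors)
    covs = list(covariates)
    trace = SelectionTrace()
    all_cols = [outcome] + focal + covs
    frozen = Dataset(table=ds.table[all_cols].dropna(),
                     roles={c: ds.roles.get(c, "covariate") for c in all_cols},
                     standardized=ds.standardized & set(all_cols))

    def _fit(cv, data):
        preds = focal + cv
        if kind == "ols":
            return fit_ols(data, outcome, preds)
        return fit_cumulative_logit(data, outcome, preds,
                                    nonparallel=tuple(n for n in nonparallel
                                                      if n in preds))

    current = list(covs)
    fit = _fit(current, frozen)
    locked: set[str] = set()
    while True:
        pvals = fit.p if kind == "ols" else fit.p_
        cand = [(pvals[c], c) for c in current
                if c not in locked and c in pvals and pvals[c] > alpha]
        if not cand:
            break
        # largest p first; exact ties broken lexicographically
        cand.sort(key=lambda t: (-t[0], t[1]))
        _, worst = cand[0]
        reduced = [c for c in current if c != worst]
        fit_red = _fit(reduced, frozen)
        if criterion == "aic":
            aic_full = fit.aic if kind == "ols" else fit.aic_
            aic_red = fit_red.aic if kind == "ols" else fit_red.aic_
            if aic_red > aic_full:
                locked.add(worst)
                trace.record(f"retain:{worst}", aic_red - aic_full, None,
                             pvals[worst], "removal raises AIC; covariate retained")
                continue
            trace.record(f"remove:{worst}", aic_full - aic_red, None, pvals[worst],
                         "covariate removed")
        else:  # "lrt": retain if removal significantly worsens overall fit
            lrt = likelihood_ratio_test(fit_red, fit, alpha=alpha,
                                        labels=("reduced", "full"))
            if lrt.p < alpha:
                locked.add(worst)
                trace.record(f"retain:{worst}", lrt.chi2, lrt.df, lrt.p,
                             "removal significantly worsens fit; covariate retained")
                continue
            trace.record(f"remove:{worst}", lrt.chi2, lrt.df, lrt.p,
                         "covariate removed")
        current = reduced
        fit = fit_red
    trace.final_covariates = {outcome: tuple(current)}
    final_fit = _fit(current, ds)  # refit on the final variable set's complete cases
    return trace, final_fit


def fdr_adjust(pvalues):
    """Benjamini-Hochberg step-up adjusted p-values, labels preserved.

    Accepts a dict, Series, or sequence; returns the same shape. Adjusted
    values are >= raw, order-preserving, capped at 1.
    """
    if isinstance(pvalues, dict):
        labels, vals = list(pvalues), np.asarray(list(pvalues.values()), dtype=float)
    elif isinstance(pvalues, pd.Series):
        labels, vals = list(pvalues.index), pvalues.to_numpy(dtype=float)
    else:
        labels, vals = None, np.asarray(list(pvalues), dtype=float)
    if vals.size == 0:
        return {} if labels is not None else vals
    if np.any(~np.isfinite(vals)) or np.any(vals < 0) or np.any(vals > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    adjusted = multipletests(vals, method="fdr_bh")[1]
    if isinstance(pvalues, dict):
        return dict(zip(labels, map(float, adjusted)))
    if isinstance(pvalues, pd.Series):
        return pd.Series(adjusted, index=labels)
    return adjusted
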