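"""Serial multiple mediation: paths, products, bootstrap, FCR.

A serial multiple mediation model with an ordinal outcome chains an
exposure X through first-order mediators M1 (modelled by OLS on X and
covariates), second-order parallel mediators M2 (OLS on X, the M1s and
covariates), into a cumulative-logit outcome equation. With standardized
predictors throughout, every indirect effect is the product of the
standardized coefficients along its pathway (product-of-coefficients
method), spanning the OLS and ordinal-logit stages; when a mediator has
per-cut (non-parallel) outcome slopes, its specific X -> M -> Y effect is
reported once per cut.

Inference is a case-resampling percentile bootstrap: rows are resampled
with replacement, predictors re-standardized within each resample, all
equations refit with the model structure frozen, and each pathway's
product stored; CIs are empirical quantiles of the draws. Confidence
levels are widened by the false coverage rate (FCR) construction for
selected parameters: level = 1 - q * (n_selected / n_total).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .dataset import Dataset, standardize
from .errors import ConvergenceError, StructuralError, ValidationError
from .linear import LinearFit, fit_ols, vif
from .ordinal import (
    CumulativeLogit,
    _fit_core,
    fit_cumulative_logit,
    fit_multinomial,
    likelihood_ratio_test,
)
from .selection import (
    SelectionTrace,
    backward_eliminate_covariates,
    fdr_adjust,
    select_nonparallel_structure,
)

__all__ = [
    "MediationSpec",
    "PathEffect",
    "BootstrapResult",
    "enumerate_paths",
    "product_of_coefficients",
    "bootstrap_mediation",
    "fcr_ci_level",
    "decompose_effects",
    "SerialMediation",
]


@dataclass
class MediationSpec:
    """Topology of one serial mediation model."""

    exposure: str
    first_order: tuple[str, ...]
    second_order: tuple[str, ...]
    outcome: str
    covariates: tuple[str, ...] = ()
    model_label: str = "model"

    def __post_init__(self):
        self.first_order = tuple(self.first_order)
        self.second_order = tuple(self.second_order)
        self.covariates = tuple(self.covariates)
        names = [self.exposure, *self.first_order, *self.second_order, self.outcome]
        if len(set(names)) != len(names):
            raise ValidationError("exposure, mediators and outcome must be distinct")
        if not self.first_order or not self.second_order:
            raise ValidationError("need at least one first- and one second-order mediator")

    @property
    def mediators(self) -> tuple[str, ...]:
        return self.first_order + self.second_order


@dataclass
class PathEffect:
    """One labelled mediation pathway and its estimate/CI."""

    label: str
    description: str
    edges: list[tuple[str, str, int | None]]
    estimate: float | None = None
    se_boot: float | None = None
    ci: tuple[float, float] | None = None
    level: float | None = None
    significant: bool | None = None
    ci_base: tuple[float, float] | None = None

    @property
    def is_indirect(self) -> bool:
        return self.label not in ("c", "c_prime", "total_indirect")


@dataclass
class BootstrapResult:
    B: int
    seed: int
    level_nominal: float
    draws: dict[str, np.ndarray]
    n_failed: int
    level_fcr: float | None = None

    @property
    def n_ok(self) -> int:
        return self.B - self.n_failed


# ---------------------------------------------------------------------------
# path enumeration and products
# ---------------------------------------------------------------------------

def _cut_label(j: int) -> str:
    return f"{j}|{j + 1}"


def enumerate_paths(spec: MediationSpec, nonparallel=(), n_cuts: int = 3):
    """Emit PathEffect skeletons in fixed reporting order.

    Order: exposure->M1->outcome specific effects (one per cut for
    non-parallel mediators), exposure->M2->outcome specific effects,
    serial exposure->M1->M2->outcome effects per (M1, M2) pair, then
    ``total_indirect``, ``c_prime`` (direct) and ``c`` (total).

    Symbolic labels follow the usual product-of-coefficients notation:
    a_i for exposure->mediator_i, d_{ts} for first->second-order edges and
    b_k for outcome-equation slopes, with b numbering consuming one slot
    per cut for relaxed predictors.
    """
    nonparallel = set(nonparallel)
    mediators = spec.mediators
    a_idx = {m: i + 1 for i, m in enumerate(mediators)}
    b_slots: dict[str, list[tuple[str, int | None]]] = {}
    counter = 1
    for m in mediators:
        if m in nonparallel:
            b_slots[m] = [(f"b{counter + j}", j) for j in range(n_cuts)]
            counter += n_cuts
        else:
            b_slots[m] = [(f"b{counter}", None)]
            counter += 1

    X, Y = spec.exposure, spec.outcome
    paths: list[PathEffect] = []
    for m in mediators:  # specific effects, first- then second-order
        for b_lab, cut in b_slots[m]:
            suffix = f"[{_cut_label(cut)}]" if cut is not None else ""
            paths.append(PathEffect(
                label=f"a{a_idx[m]}*{b_lab}",
                description=f"{X} -> {m}{suffix} -> {Y}",
                edges=[(X, m, None), (m, Y, cut)],
            ))
    for m1 in spec.first_order:  # serial effects
        for m2 in spec.second_order:
            d_lab = f"d{a_idx[m2]}{a_idx[m1]}"
            for b_lab, cut in b_slots[m2]:
                suffix = f"[{_cut_label(cut)}]" if cut is not None else ""
                paths.append(PathEffect(
                    label=f"a{a_idx[m1]}*{d_lab}*{b_lab}",
                    description=f"{X} -> {m1} -> {m2}{suffix} -> {Y}",
                    edges=[(X, m1, None), (m1, m2, None), (m2, Y, cut)],
                ))
    paths.append(PathEffect("total_indirect", "sum of all indirect pathways", []))
    paths.append(PathEffect("c_prime", f"{X} -> {Y} (direct)", [(X, Y, None)]))
    paths.append(PathEffect("c", "total effect (direct + total indirect)", []))
    return paths


def _edge_coefficient(fits, src, tgt, cut):
    if tgt not in fits:
        raise StructuralError(f"no fitted equation for target {tgt!r} (edge {src}->{tgt})")
    fit = fits[tgt]
    if isinstance(fit, dict):
        table = fit
    elif isinstance(fit, LinearFit):
        table = fit.coefficients
    elif isinstance(fit, CumulativeLogit):
        table = fit.slopes_
    elif hasattr(fit, "slopes_"):
        table = fit.slopes_
    elif hasattr(fit, "coefficients"):
        table = fit.coefficients
    else:
        raise StructuralError(f"cannot read coefficients from {type(fit).__name__}")
    if src not in table:
        raise StructuralError(f"coefficient for edge {src}->{tgt} missing from fit")
    val = table[src]
    if np.ndim(val) > 0:
        if cut is None:
            raise StructuralError(
                f"edge {src}->{tgt} has per-cut slopes but no cut was requested")
        return float(np.asarray(val)[cut])
    if cut is not None:
        raise StructuralError(f"edge {src}->{tgt} is parallel but cut {cut} was requested")
    return float(val)


def product_of_coefficients(path: PathEffect, fits) -> float:
    """Estimate a pathway effect as the product of its edge coefficients."""
    prod = 1.0
    for (src, tgt, cut) in path.edges:
        prod *= _edge_coefficient(fits, src, tgt, cut)
    return prod


# ---------------------------------------------------------------------------
# percentile bootstrap
# ---------------------------------------------------------------------------

def percentile_ci(draws: np.ndarray, level: float) -> tuple[float, float]:
    """Type-1 (inverse empirical CDF) percentile interval of the draws."""
    x = np.sort(np.asarray(draws, dtype=float))
    m = len(x)
    if m == 0:
        raise ValidationError("no bootstrap draws")

    def q(p):
        k = min(max(int(math.ceil(p * m)), 1), m)
        return float(x[k - 1])

    alpha = (1.0 - level) / 2.0
    return q(alpha), q(1.0 - alpha)


def _build_equations(spec: MediationSpec, covariate_sets, nonparallel):
    """(target, predictors, kind) for every equation, in causal order."""
    covs = dict(covariate_sets or {})
    eqs = []
    for m1 in spec.first_order:
        eqs.append((m1, [spec.exposure] + list(covs.get(m1, spec.covariates)), "ols"))
    for m2 in spec.second_order:
        eqs.append((m2, [spec.exposure] + list(spec.first_order)
                    + list(covs.get(m2, spec.covariates)), "ols"))
    eqs.append((spec.outcome, [spec.exposure] + list(spec.mediators)
                + list(covs.get(spec.outcome, spec.covariates)), "ordinal"))
    return eqs


def bootstrap_mediation(ds: Dataset, spec: MediationSpec, nonparallel=(),
                        covariate_sets=None, B: int = 1000, seed: int = 0,
                        level: float = 0.95, restandardize: bool = True,
                        fits=None, paths=None):
    """Case-resampling percentile bootstrap of all pathway products.

    Model structure (non-parallel set, retained covariates) is frozen; each
    of the B resamples redraws n rows with replacement from the complete
    cases of the most inclusive equation, re-standardizes the predictors
    that were standardized on the full sample, refits every equation
    (warm-started at the full-sample ordinal solution), and stores each
    pathway's coefficient product. Deterministic given ``seed`` and
    extendable in B: replicate b uses the (seed, b) substream, so earlier
    replicates never reshuffle.

    Returns ``(BootstrapResult, completed PathEffects)``.
    """
    if B < 100:
        raise ValidationError("B must be at least 100")
    nonparallel = tuple(nonparallel)
    eqs = _build_equations(spec, covariate_sets, nonparallel)
    used_cols = sorted({spec.outcome} | {c for _, preds, _ in eqs for c in preds}
                       | {t for t, _, _ in eqs})
    frame = ds.table[used_cols].dropna()
    n = len(frame)

    # full-sample fits (point estimates) unless supplied by the caller
    sub = Dataset(table=frame, roles={c: ds.roles.get(c, "covariate") for c in used_cols},
                  standardized=ds.standardized & set(used_cols))
    if fits is None:
        fits = {}
        for target, preds, kind in eqs:
            if kind == "ols":
                fits[target] = fit_ols(sub, target, preds)
            else:
                fits[target] = fit_cumulative_logit(sub, target, preds,
                                                    nonparallel=nonparallel)
    out_fit: CumulativeLogit = fits[spec.outcome]
    n_cuts = out_fit.n_cuts_
    K = n_cuts + 1
    if paths is None:
        paths = enumerate_paths(spec, nonparallel=nonparallel, n_cuts=n_cuts)

    # ---- precompile the numeric problem --------------------------------
    col_idx = {c: i for i, c in enumerate(used_cols)}
    V = frame.to_numpy(dtype=float)
    std_cols = [col_idx[c] for c in sorted(ds.standardized & set(used_cols))]
    ols_eqs = [(col_idx[t], np.array([col_idx[p] for p in preds]))
               for t, preds, kind in eqs if kind == "ols"]
    ols_targets = [t for t, _, kind in eqs if kind == "ols"]
    o_target, o_preds, _ = eqs[-1]
    par_names = [p for p in o_preds if p not in nonparallel]
    np_names = [p for p in o_preds if p in nonparallel]
    o_par_idx = np.array([col_idx[p] for p in par_names], dtype=int)
    o_np_idx = np.array([col_idx[p] for p in np_names], dtype=int)
    o_y_idx = col_idx[o_target]
    cats = out_fit.categories_
    theta_start = out_fit.theta_.copy()

    # resolve each path edge to (kind, eq, coef index)
    def _resolve(src, tgt, cut):
        if tgt == spec.outcome:
            if src in np_names:
                j = np_names.index(src)
                return ("o", n_cuts + len(par_names) + j * n_cuts + cut)
            return ("o", n_cuts + par_names.index(src))
        ei = ols_targets.index(tgt)
        preds = eqs[ei][1]
        return ("m", ei, 1 + preds.index(src))

    indirect = [p for p in paths if p.is_indirect]
    compiled = [[_resolve(*e) for e in p.edges] for p in indirect]
    direct_slot = _resolve(spec.exposure, spec.outcome, None)

    labels = [p.label for p in indirect] + ["total_indirect", "c_prime", "c"]
    draws = np.full((B, len(labels)), np.nan)
    n_failed = 0
    for b in range(B):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(b,)))
        idx = rng.integers(0, n, n)
        M = V[idx]
        try:
            if restandardize and std_cols:
                block = M[:, std_cols]
                mu = block.mean(axis=0)
                sd = block.std(axis=0, ddof=1)
                if np.any(sd == 0):
                    raise ConvergenceError("degenerate resample")
                M[:, std_cols] = (block - mu) / sd
            betas = []
            for (ti, pi) in ols_eqs:
                Xb = np.column_stack([np.ones(n), M[:, pi]])
                beta = np.linalg.solve(Xb.T @ Xb, Xb.T @ M[:, ti])
                betas.append(beta)
            yb = M[:, o_y_idx].astype(int)
            codes = np.searchsorted(cats, yb)
            if np.bincount(codes, minlength=K).min() == 0:
                raise ConvergenceError("resample lost an outcome category")
            Xp = M[:, o_par_idx]
            Xn = M[:, o_np_idx] if len(o_np_idx) else np.empty((n, 0))
            theta, _, _, gnorm, _ = _fit_core(Xp, Xn, codes, K, start=theta_start,
                                              tol=1e-4, max_iter=200)
            if not np.isfinite(gnorm) or gnorm > 1e-3:
                raise ConvergenceError("bootstrap ordinal refit did not converge")
        except (np.linalg.LinAlgError, ConvergenceError):
            n_failed += 1
            continue

        def slot_value(slot):
            if slot[0] == "o":
                return theta[slot[1]]
            return betas[slot[1]][slot[2]]

        vals = [float(np.prod([slot_value(s) for s in slots])) for slots in compiled]
        ti = float(np.sum(vals))
        cp = float(slot_value(direct_slot))
        draws[b] = vals + [ti, cp, ti + cp]

    ok = ~np.isnan(draws[:, 0])
    if n_failed / B > 0.10:
        raise ConvergenceError(f"{n_failed}/{B} bootstrap replicates failed")
    if n_failed / B > 0.01:
        warnings.warn(f"{n_failed}/{B} bootstrap replicates failed", stacklevel=2)
    draw_map = {lab: draws[ok, j].copy() for j, lab in enumerate(labels)}

    # complete the PathEffects
    est_map = {}
    for p in paths:
        if p.is_indirect or p.label == "c_prime":
            est_map[p.label] = product_of_coefficients(p, fits)
    est_map["total_indirect"] = sum(v for k, v in est_map.items()
                                    if k not in ("c_prime",))
    est_map["c"] = est_map["total_indirect"] + est_map["c_prime"]
    for p in paths:
        p.estimate = est_map[p.label]
        d = draw_map[p.label]
        p.se_boot = float(np.std(d, ddof=1))
        p.ci = percentile_ci(d, level)
        p.ci_base = p.ci
        p.level = level
        p.significant = not (p.ci[0] <= 0.0 <= p.ci[1])
    result = BootstrapResult(B=B, seed=seed, level_nominal=level,
                             draws=draw_map, n_failed=n_failed)
    return result, paths


# ---------------------------------------------------------------------------
# FCR-corrected confidence level and effect decomposition
# ---------------------------------------------------------------------------

def fcr_ci_level(base_q: float, n_selected: int, n_total: int) -> float:
    """Effective CI level 1 - q * (n_selected / n_total) for selected parameters.

    This is the false coverage rate construction: when only a fraction of
    effects is selected as non-null, the CIs of the selected ones are
    reported at a level above the nominal 1-q (wider intervals). With all
    effects selected the level is the nominal one; with none selected
    there is nothing to correct and the base level is returned with a
    warning.
    """
    if not (0.0 < base_q < 1.0):
        raise ValidationError("base_q must be in (0, 1)")
    if n_selected < 0 or n_total < 1 or n_selected > n_total:
        raise ValidationError("need 0 <= n_selected <= n_total, n_total >= 1")
    if n_selected == 0:
        warnings.warn("no effects selected; no CIs to correct, base level returned",
                      stacklevel=2)
        return 1.0 - base_q
    return 1.0 - base_q * (n_selected / n_total)


@dataclass
class EffectDecomposition:
    total: PathEffect
    direct: PathEffect
    total_indirect: PathEffect
    mediation: bool | None
    suppression: bool


def decompose_effects(paths, fits=None) -> EffectDecomposition:
    """Total / direct / total-indirect decomposition, c = c' + sum(indirect).

    Mediation is declared when the total and total-indirect CIs exclude 0
    while the direct CI includes 0; the suppression flag is raised when
    direct and total-indirect estimates have opposite signs.
    """
    by_label = {p.label: p for p in paths}
    for need in ("c", "c_prime", "total_indirect"):
        if need not in by_label:
            raise StructuralError(f"path list lacks {need!r}")
    indirect_sum = sum(p.estimate for p in paths if p.is_indirect)
    cp = by_label["c_prime"]
    if cp.estimate is None and fits is not None:
        cp.estimate = product_of_coefficients(cp, fits)
    by_label["total_indirect"].estimate = indirect_sum
    by_label["c"].estimate = indirect_sum + cp.estimate
    total, direct, ti = by_label["c"], cp, by_label["total_indirect"]
    mediation = None
    if total.ci is not None and ti.ci is not None and direct.ci is not None:
        excl = lambda p: not (p.ci[0] <= 0.0 <= p.ci[1])
        mediation = excl(total) and excl(ti) and not excl(direct)
    suppression = bool(direct.estimate * ti.estimate < 0)
    return EffectDecomposition(total=total, direct=direct, total_indirect=ti,
                               mediation=mediation, suppression=suppression)


# ---------------------------------------------------------------------------
# the end-to-end estimator
# ---------------------------------------------------------------------------

class SerialMediation(BaseEstimator):
    """End-to-end serial multiple mediation with an ordinal outcome.

    ``fit`` standardizes the predictors, compares the cumulative model
    against a multinomial baseline-category logit, tests the
    proportional-odds assumption for the candidate mediators and selects
    the partial-PO structure, backward-eliminates non-significant
    covariates per equation, fits the final equations, FDR-adjusts the
    coefficient p-values, bootstraps every pathway product, applies the
    FCR correction to the CI level, and decomposes total/direct/indirect
    effects.

    Parameters mirror the analysis choices: ``n_boot`` (replicates),
    ``ci_level`` (nominal percentile level), ``fcr_q`` (FCR miscoverage),
    ``fcr_level`` (optional fixed override, e.g. 0.97), ``alpha``
    (selection threshold), ``random_state`` (bootstrap master seed).
    """

    def __init__(self, exposure="gratitude", first_order=("hse",),
                 second_order=("stress", "anxiety", "depression"),
                 outcome="sleep", covariates=("age", "sex", "education", "conditions"),
                 standardize_covariates=False, candidates=None, nonparallel=None,
                 eliminate_covariates=True, compare_multinomial=True,
                 alpha=0.05, n_boot=1000, ci_level=0.95, fcr_q=0.05,
                 fcr_level=None, restandardize=True, random_state=0):
        self.exposure = exposure
        self.first_order = first_order
        self.second_order = second_order
        self.outcome = outcome
        self.covariates = covariates
        self.standardize_covariates = standardize_covariates
        self.candidates = candidates
        self.nonparallel = nonparallel
        self.eliminate_covariates = eliminate_covariates
        self.compare_multinomial = compare_multinomial
        self.alpha = alpha
        self.n_boot = n_boot
        self.ci_level = ci_level
        self.fcr_q = fcr_q
        self.fcr_level = fcr_level
        self.restandardize = restandardize
        self.random_state = random_state

    # -----------------------------------------------------------------
    def _spec(self) -> MediationSpec:
        return MediationSpec(
            exposure=self.exposure, first_order=tuple(self.first_order),
            second_order=tuple(self.second_order), outcome=self.outcome,
            covariates=tuple(self.covariates))

    def fit(self, data: Dataset | pd.DataFrame, y=None):
        spec = self._spec()
        if isinstance(data, Dataset):
            ds = data
        else:
            roles = {spec.exposure: "exposure", spec.outcome: "outcome"}
            roles.update({m: "mediator1" for m in spec.first_order})
            roles.update({m: "mediator2" for m in spec.second_order})
            roles.update({c: "covariate" for c in spec.covariates})
            ds = Dataset(table=data, roles=roles)
        to_std = [spec.exposure, *spec.mediators]
        if self.standardize_covariates:
            to_std += [c for c in spec.covariates]
        ds = standardize(ds, [c for c in to_std if c not in ds.standardized])
        self.dataset_ = ds
        trace = SelectionTrace()

        all_outcome_preds = [spec.exposure] + list(spec.mediators) + list(spec.covariates)
        if self.compare_multinomial:
            frame = ds.table[[spec.outcome] + all_outcome_preds].dropna()
            sub = Dataset(table=frame, roles={c: ds.roles[c] for c in frame.columns},
                          standardized=ds.standardized & set(frame.columns))
            ordfit = fit_cumulative_logit(sub, spec.outcome, all_outcome_preds,
                                          compute_se=False)
            mnfit = fit_multinomial(sub, spec.outcome, all_outcome_preds)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # non-nesting caveat recorded in trace
                lrt = likelihood_ratio_test(ordfit, mnfit,
                                            labels=("cumulative", "multinomial"))
            self.lrt_multinomial_ = lrt
            trace.record("family:cumulative_vs_multinomial", lrt.chi2, lrt.df, lrt.p,
                         f"preferred {lrt.preferred} (non-nested families; "
                         "LRT on LL difference)")

        if self.nonparallel is not None:
            self.nonparallel_ = tuple(self.nonparallel)
            trace.record("structure", None, None, None,
                         f"non-parallel set fixed by caller: {self.nonparallel_}")
        else:
            cands = list(self.candidates) if self.candidates is not None \
                else list(spec.first_order)
            st = select_nonparallel_structure(ds, spec.outcome, all_outcome_preds,
                                              cands, alpha=self.alpha)
            trace.steps.extend(st.steps)
            self.nonparallel_ = st.final_nonparallel

        # per-equation covariate sets
        eq_specs = _build_equations(spec, None, self.nonparallel_)
        covariate_sets: dict[str, tuple[str, ...]] = {}
        fits: dict[str, object] = {}
        for target, preds, kind in eq_specs:
            focal = [p for p in preds if p not in spec.covariates]
            if self.eliminate_covariates and spec.covariates:
                tr, fit = backward_eliminate_covariates(
                    ds, target, focal, list(spec.covariates), alpha=self.alpha,
                    kind=kind, nonparallel=self.nonparallel_)
                for s in tr.steps:
                    trace.record(f"{target}:{s.action}", s.statistic, s.df, s.p,
                                 s.decision)
                covariate_sets[target] = tr.final_covariates[target]
            else:
                covariate_sets[target] = tuple(spec.covariates)
                if kind == "ols":
                    fit = fit_ols(ds, target, focal + list(spec.covariates))
                else:
                    fit = fit_cumulative_logit(ds, target,
                                               focal + list(spec.covariates),
                                               nonparallel=self.nonparallel_)
            fits[target] = fit
        trace.final_nonparallel = self.nonparallel_
        trace.final_covariates = {k: tuple(v) for k, v in covariate_sets.items()}
        self.covariate_sets_ = covariate_sets
        self.fits_ = fits
        self.trace_ = trace

        # collinearity diagnostics per equation
        self.vif_ = {}
        for target, preds, kind in _build_equations(spec, covariate_sets,
                                                    self.nonparallel_):
            if len(preds) >= 2:
                self.vif_[target] = vif(ds, preds)

        # FDR adjustment pooled over this model's equations (incl. thresholds)
        pooled: dict[tuple[str, str], float] = {}
        for target, fit in fits.items():
            pv = fit.p if isinstance(fit, LinearFit) else fit.p_
            pooled.update({(target, k): v for k, v in pv.items() if np.isfinite(v)})
        adjusted = fdr_adjust(pooled)
        self.p_adjusted_ = adjusted
        for target, fit in fits.items():
            padj = {k: v for (t, k), v in adjusted.items() if t == target}
            if isinstance(fit, LinearFit):
                fit.p_adjusted = padj
            else:
                fit.p_adjusted_ = padj

        # pathway products and bootstrap
        out_fit = fits[spec.outcome]
        paths = enumerate_paths(spec, nonparallel=self.nonparallel_,
                                n_cuts=out_fit.n_cuts_)
        if self.n_boot:
            boot, paths = bootstrap_mediation(
                ds, spec, nonparallel=self.nonparallel_,
                covariate_sets=covariate_sets, B=self.n_boot,
                seed=self.random_state, level=self.ci_level,
                restandardize=self.restandardize, fits=fits, paths=paths)
            self.bootstrap_ = boot
            # FCR: selection = base-level CIs excluding zero, over all
            # reported effect CIs (indirect paths + totals + direct)
            n_total = len(paths)
            n_selected = sum(1 for p in paths if p.significant)
            if self.fcr_level is not None:
                self.fcr_level_ = float(self.fcr_level)
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    self.fcr_level_ = fcr_ci_level(1.0 - self.ci_level,
                                                   n_selected, n_total)
            boot.level_fcr = self.fcr_level_
            for p in paths:
                p.ci = percentile_ci(boot.draws[p.label], self.fcr_level_)
                p.level = self.fcr_level_
                p.significant = not (p.ci[0] <= 0.0 <= p.ci[1])
        else:
            for p in paths:
                if p.is_indirect or p.label == "c_prime":
                    p.estimate = product_of_coefficients(p, fits)
            self.bootstrap_ = None
        self.paths_ = paths
        dec = decompose_effects(paths, fits)
        self.total_ = dec.total
        self.direct_ = dec.direct
        self.total_indirect_ = dec.total_indirect
        self.mediation_ = dec.mediation
        self.suppression_ = dec.suppression
        return self

    # -----------------------------------------------------------------
    def results_frame(self) -> pd.DataFrame:
        """Flat table of pathway effects (label, estimate, SE, LL, UL)."""
        rows = []
        for p in self.paths_:
            lo, hi = p.ci if p.ci is not None else (np.nan, np.nan)
            rows.append({"label": p.label, "description": p.description,
                         "estimate": p.estimate, "se_boot": p.se_boot,
                         "ll": lo, "ul": hi, "level": p.level,
                         "significant": p.significant})
        return pd.DataFrame(rows)
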