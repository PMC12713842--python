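"""Respondent-level data container and descriptive screening.

The unit of analysis is a rectangular table with one row per respondent:
an exposure (e.g. a gratitude sum score), continuous mediators, a 4-level
ordinal outcome coded 0-3, and covariates. Columns carry *roles* so the
modelling layers can find the exposure, mediators, outcome and covariates
without positional conventions, and a record of which columns have been
z-scored.

Screening utilities follow standard practice for mediation pipelines:
pairwise-complete Pearson/Spearman correlation matrices with a
multicollinearity flag at ``|r| > 0.80``, small-sample skewness/kurtosis
diagnostics with their exact standard errors, and a Breusch-Pagan score
test for residual heteroscedasticity.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateColumnError,
    InsufficientDataError,
    SchemaError,
    ValidationError,
)

ROLES = ("exposure", "mediator1", "mediator2", "outcome", "covariate")

#: outcome codes for the 4-level ordinal item ("not at all" .. "nearly every day")
OUTCOME_CODES = (0, 1, 2, 3)

MULTICOLLINEARITY_CUTOFF = 0.80


@dataclass
class Dataset:
    """A typed respondent-level table.

    Parameters
    ----------
    table:
        Numeric DataFrame; missing values are NaN. The outcome column holds
        integer codes 0-3 where present.
    roles:
        Map column name -> one of ``exposure, mediator1, mediator2, outcome,
        covariate``. Columns absent from the map are carried but ignored by
        the modelling layers.
    standardized:
        Names of columns already converted to z-scores.
    """

    table: pd.DataFrame
    roles: dict[str, str]
    standardized: set[str] = field(default_factory=set)

    def __post_init__(self):
        self.table = self.table.copy()
        for name, role in self.roles.items():
            if role not in ROLES:
                raise SchemaError(f"unknown role {role!r} for column {name!r}")
            if name not in self.table.columns:
                raise SchemaError(f"declared column {name!r} missing from table")
        out = self.outcome_column
        if out is not None:
            vals = self.table[out].dropna()
            bad = vals[~vals.isin(OUTCOME_CODES)]
            if len(bad):
                row = int(bad.index[0]) + 1  # 1-based data row
                raise ValidationError(
                    f"outcome {out!r} has value {bad.iloc[0]!r} outside 0-3 in row {row}"
                )
        self.standardized = set(self.standardized)

    # -- convenience accessors -------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.table)

    @property
    def outcome_column(self) -> str | None:
        for name, role in self.roles.items():
            if role == "outcome":
                return name
        return None

    def columns_with_role(self, role: str) -> list[str]:
        return [c for c, r in self.roles.items() if r == role]

    def complete_cases(self, columns) -> pd.DataFrame:
        """Rows complete for *columns* (listwise deletion per equation)."""
        cols = list(columns)
        return self.table.loc[self.table[cols].notna().all(axis=1), cols]


def load_table(path, schema: dict[str, str]) -> Dataset:
    """Read a delimited text file into a :class:`Dataset`.

    ``schema`` maps column names to roles; every schema column must appear in
    the header. Unparseable numeric cells become missing; empty cells and
    ``NA`` are missing. Outcome values are coerced to integer codes and
    validated against 0-3 (the offending 1-based data row is named on error).
    """
    raw = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    missing = [c for c in schema if c not in raw.columns]
    if missing:
        raise SchemaError(f"columns declared in schema but absent from file: {missing}")
    table = raw.apply(lambda s: pd.to_numeric(s, errors="coerce"))
    out = next((c for c, r in schema.items() if r == "outcome"), None)
    if out is not None:
        vals = table[out]
        ok = vals.isna() | vals.isin(OUTCOME_CODES)
        if not ok.all():
            row = int(np.flatnonzero(~ok.to_numpy())[0]) + 1
            raise ValidationError(
                f"outcome {out!r} has value {vals[~ok].iloc[0]!r} outside 0-3 in row {row}"
            )
        table[out] = vals.round().astype("float64")
    return Dataset(table=table, roles=dict(schema))


def standardize(ds: Dataset, columns) -> Dataset:
    """Return a new Dataset with *columns* replaced by z-scores.

    Moments use non-missing entries and the n-1 SD convention. The ordinal
    outcome must not be named (it keeps its category codes). Idempotent
    within floating-point tolerance.
    """
    out = ds.outcome_column
    new = ds.table.copy()
    done = set(ds.standardized)
    for name in columns:
        if name == out:
            raise ValidationError(f"outcome column {name!r} must not be standardized")
        if name not in new.columns:
            raise SchemaError(f"no column {name!r}")
        x = new[name].astype(float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise DegenerateColumnError(f"column {name!r} has zero variance")
        new[name] = (x - x.mean()) / sd
        done.add(name)
    return Dataset(table=new, roles=dict(ds.roles), standardized=done)


@dataclass
class CorrMatrix:
    method: str
    values: pd.DataFrame
    flags: set[frozenset]

    def to_csv(self, path) -> None:
        self.values.to_csv(path)


def correlation_matrix(ds: Dataset, method: str = "pearson", pairs=None) -> CorrMatrix:
    """Pairwise-complete correlation matrix with collinearity flags.

    Cells with fewer than 3 complete pairs are left missing (NaN), never
    reported as zero. Off-diagonal pairs with ``|r| > 0.80`` are flagged.
    ``pairs`` optionally restricts the columns entering the matrix.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    cols = list(pairs) if pairs is not None else [c for c in ds.roles]
    sub = ds.table[cols].astype(float)
    values = sub.corr(method=method, min_periods=3)
    np.fill_diagonal(values.values, 1.0)
    flags = {
        frozenset((a, b))
        for a, b in itertools.combinations(cols, 2)
        if np.isfinite(values.loc[a, b]) and abs(values.loc[a, b]) > MULTICOLLINEARITY_CUTOFF
    }
    return CorrMatrix(method=method, values=values, flags=flags)


@dataclass
class MomentReport:
    n: int
    skewness: float
    se_skewness: float
    kurtosis: float
    se_kurtosis: float

    def to_json(self) -> str:
        return json.dumps(self.__dict__)


def se_skewness(n: int) -> float:
    """Exact small-sample SE of sample skewness under normality."""
    return math.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3)))


def se_kurtosis(n: int) -> float:
    """Exact small-sample SE of sample excess kurtosis under normality."""
    return 2.0 * se_skewness(n) * math.sqrt((n * n - 1.0) / ((n - 3) * (n + 5)))


def moment_diagnostics(values) -> MomentReport:
    """Sample skewness and excess kurtosis with exact small-sample SEs.

    The shape statistics are the plain standardized moments
    (m3 / m2^{3/2} and m4 / m2^2 - 3), so a normal sample has both near 0;
    the SEs use the exact small-sample formulas (asymptotically sqrt(6/n)
    and sqrt(24/n)).
    """
    x = np.asarray(pd.Series(values).dropna(), dtype=float)
    n = len(x)
    if n < 4:
        raise InsufficientDataError(f"need at least 4 non-missing values, got {n}")
    return MomentReport(
        n=n,
        skewness=float(sps.skew(x, bias=True)),
        se_skewness=se_skewness(n),
        kurtosis=float(sps.kurtosis(x, fisher=True, bias=True)),
        se_kurtosis=se_kurtosis(n),
    )


def residual_heteroscedasticity(fit, ds: Dataset | None = None):
    """Breusch-Pagan score test on a fitted linear equation.

    Regresses squared residuals on the fit's predictors; n*R^2 is referred
    to chi-square with p degrees of freedom. Returns ``(statistic, p_value)``.
    A perfectly fit equation (all residuals zero) returns (0.0, 1.0).
    """
    resid = np.asarray(fit.resid, dtype=float)
    exog = np.asarray(fit.exog, dtype=float)
    n, k = exog.shape
    if n - k < 1:
        raise InsufficientDataError("fewer residual degrees of freedom than predictors")
    if np.max(np.abs(resid)) < 1e-10:  # perfectly fit equation
        return 0.0, 1.0
    from statsmodels.stats.diagnostic import het_breuschpagan

    lm, lm_p, _, _ = het_breuschpagan(resid, exog)
    return float(lm), float(lm_p)
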