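"""Confounder screening, BMI-adjusted univariable models, and backward
stepwise multiple regression for weight-change outcomes.

All models are ordinary least squares with classical (homoskedastic)
standard errors and t-based 95% confidence intervals.  Multi-level
categorical predictors are treated as blocks: screening and stepwise
decisions use the joint F-test for the whole variable, mirroring the
"overall p-value" convention of categorical association tables.

Two outcome scales coexist by design: ever/never (binary) predictors are
modelled against total net weight change (kg), while per-30-day categorical
predictors and the stepwise model use weight change per 30 days of
weight-entry span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .errors import CollinearityError, ValidationError


@dataclass
class TermEstimate:
    term: str
    coef: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class ModelFit:
    """A fitted regression: per-term estimates plus model-level metadata."""

    outcome: str
    n: int
    terms: list = field(default_factory=list)           # list[TermEstimate]
    overall_p: dict = field(default_factory=dict)       # variable -> joint p
    adjusted_for: list = field(default_factory=list)
    removal_trace: list = field(default_factory=list)   # [(variable, p), ...]
    not_estimable: list = field(default_factory=list)
    formula: str = ""

    def term(self, name_fragment: str) -> TermEstimate:
        """First term whose name contains ``name_fragment``."""
        for t in self.terms:
            if name_fragment in t.term:
                return t
        raise KeyError(name_fragment)

    def variables(self) -> list:
        return list(self.overall_p)

    def to_dict(self) -> dict:
        return asdict(self)


def _clean_categoricals(data: pd.DataFrame, variables) -> tuple:
    """Drop unused category levels so the design matrix has full rank;
    returns the cleaned frame and the list of dropped (variable, level)."""
    data = data.copy()
    dropped = []
    for var in variables:
        col = data[var]
        if isinstance(col.dtype, pd.CategoricalDtype):
            present = col.cat.remove_unused_categories()
            for lvl in set(col.cat.categories) - set(present.cat.categories):
                dropped.append((var, str(lvl)))
            data[var] = present
    return data, dropped


def _check_rank(result, variables) -> None:
    exog = result.model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        raise CollinearityError(
            f"design matrix rank {rank} < {exog.shape[1]} columns; "
            f"collinear terms among: {list(variables)}")


def _fit(data: pd.DataFrame, outcome: str, variables) -> "smf.ols":
    rhs = " + ".join(variables) if variables else "1"
    model = smf.ols(f"{outcome} ~ {rhs}", data=data)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit()


def _term_pvalues(result, variables) -> dict:
    """Joint (block) p-value per declared variable via Wald F-tests."""
    if not variables:
        return {}
    table = result.wald_test_terms(scalar=True).table
    pcol = next(c for c in table.columns if c.lower().startswith("p"))
    out = {}
    for var in variables:
        matches = [ix for ix in table.index if ix == var]
        if not matches:
            raise ValidationError(f"term {var} not found in fitted model")
        out[var] = float(table.loc[matches[0], pcol])
    return out


def _collect_terms(result, skip_intercept=True) -> list:
    ci = result.conf_int()
    terms = []
    for name in result.params.index:
        if skip_intercept and name == "Intercept":
            continue
        terms.append(TermEstimate(
            term=name, coef=float(result.params[name]),
            ci_low=float(ci.loc[name, 0]), ci_high=float(ci.loc[name, 1]),
            p=float(result.pvalues[name])))
    return terms


def screen_confounders(data: pd.DataFrame, candidates,
                       outcome: str = "net_change_kg",
                       alpha: float = 0.05):
    """Univariable screen: retain candidates associated with the outcome.

    Each candidate is fit alone against the outcome; multi-level
    categoricals are judged by the model's joint F-test.  Candidates with
    overall p below ``alpha`` are retained as adjustment covariates.
    Constant candidates are skipped with a warning.

    Returns ``(retained, pvalues)``.
    """
    retained, pvalues = [], {}
    for var in candidates:
        if data[var].nunique(dropna=True) <= 1:
            warnings.warn(f"confounder candidate {var!r} is constant; skipped")
            continue
        sub, _ = _clean_categoricals(data[[outcome, var]].dropna(), [var])
        result = _fit(sub, outcome, [var])
        p = float(result.f_pvalue)
        pvalues[var] = p
        if p < alpha:
            retained.append(var)
    return retained, pvalues


def fit_univariable_adjusted(data: pd.DataFrame, variable: str,
                             outcome: str,
                             adjust=("baseline_bmi",)) -> ModelFit:
    """OLS of the outcome on one usage variable plus adjustment covariates.

    Reports each non-reference level's coefficient against the reference
    (least-use) level with 95% CI and p-value, plus the variable's joint
    p-value.  Levels with no members are reported as not estimable.
    """
    adjust = [a for a in adjust if a != variable]
    cols = [outcome, variable] + adjust
    sub, dropped = _clean_categoricals(data[cols].dropna(), [variable])
    variables = [variable] + adjust
    result = _fit(sub, outcome, variables)
    _check_rank(result, variables)
    return ModelFit(
        outcome=outcome, n=int(result.nobs),
        terms=_collect_terms(result),
        overall_p=_term_pvalues(result, variables),
        adjusted_for=list(adjust),
        not_estimable=[f"{v}={lvl}" for v, lvl in dropped],
        formula=str(result.model.formula))


def fit_stepwise(data: pd.DataFrame, variables, outcome: str,
                 retain_p: float = 0.20, protected=()) -> ModelFit:
    """Backward stepwise OLS with block tests for categorical variables.

    Starting from the full model, repeatedly remove the single variable
    with the largest joint p-value at or above ``retain_p`` (ties broken by
    removing the variable declared later) and refit, until every remaining
    variable has p below the threshold.  ``protected`` variables are never
    removed.  The removal trace records each removed variable with its
    p-value at removal time.
    """
    variables = list(variables)
    order = {v: i for i, v in enumerate(variables)}
    cols = [outcome] + variables
    sub, dropped = _clean_categoricals(data[cols].dropna(), variables)

    remaining = list(variables)
    trace = []
    result = _fit(sub, outcome, remaining)
    _check_rank(result, remaining)
    while remaining:
        pvals = _term_pvalues(result, remaining)
        removable = {v: p for v, p in pvals.items()
                     if p >= retain_p and v not in protected}
        if not removable:
            break
        worst_p = max(removable.values())
        candidates = [v for v, p in removable.items() if p == worst_p]
        victim = max(candidates, key=lambda v: order[v])
        trace.append((victim, float(worst_p)))
        remaining.remove(victim)
        result = _fit(sub, outcome, remaining)
    return ModelFit(
        outcome=outcome, n=int(result.nobs),
        terms=_collect_terms(result),
        overall_p=_term_pvalues(result, remaining),
        adjusted_for=[],
        removal_trace=trace,
        not_estimable=[f"{v}={lvl}" for v, lvl in dropped],
        formula=str(result.model.formula))
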