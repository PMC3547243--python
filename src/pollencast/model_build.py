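"""Backward stepwise OLS over collinearity-filtered candidate features.

The modelling protocol, per predicted characteristic (season start SS,
season end SE, peak day PD, peak concentration PC):

1. ``collinearity_filter`` greedily retains candidates in order of
   marginal correlation with the target, dropping any candidate whose
   absolute pairwise correlation with an already-retained feature
   exceeds the threshold (default 0.7), so no two strongly
   inter-correlated windows enter one model;
2. ``backward_stepwise`` starts from the full OLS model and repeatedly
   removes the term with the largest p value above ``alpha_remove``
   (default 0.05) until every term is significant or one term remains;
3. models are fitted with or without an intercept; the no-intercept R2
   uses the uncentred total sum of squares and is flagged as such,
   since it is not comparable to intercept-model R2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from pollencast.io_core import ValidationError

logger = logging.getLogger(__name__)


class RankDeficientError(ValidationError):
    """Design matrix is not full column rank."""


def varies(values: pd.Series) -> bool:
    """True when a column has non-negligible variation (relative tolerance).

    Protects selection from pseudo-variation at float precision, e.g. a
    climatologically constant feature whose leap-year recomputation
    differs by 1e-15.
    """
    v = values.dropna()
    if len(v) < 2:
        return False
    return float(v.std()) > 1e-8 * (1.0 + float(v.abs().mean()))


@dataclass
class RegressionModel:
    """A fitted linear model for one season characteristic."""

    target: str
    terms: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float | None  # None for no-intercept models
    r2: float
    t_values: tuple[float, ...]
    p_values: tuple[float, ...]
    n: int
    uncentred_r2: bool = False
    intercept_only: bool = False
    selection_trace: list[dict] = field(default_factory=list, repr=False)

    @property
    def with_intercept(self) -> bool:
        return self.intercept is not None

    def equation(self, digits: int = 2) -> str:
        """Human-readable equation, e.g. ``SS = 61.55 - 1.34*Temp_6 + 0.59*Hum_10``."""
        parts = []
        if self.intercept is not None:
            parts.append(f"{self.intercept:.{digits}f}")
        for name, coef in zip(self.terms, self.coefficients):
            sign = "-" if coef < 0 else "+"
            if not parts:
                parts.append(f"{coef:.{digits}f}*{name}")
            else:
                parts.append(f"{sign} {abs(coef):.{digits}f}*{name}")
        return f"{self.target} = " + " ".join(parts)


def collinearity_filter(
    features: pd.DataFrame,
    target: pd.Series,
    threshold: float = 0.7,
) -> list[str]:
    """Greedy retention of mutually near-uncorrelated candidate features.

    Candidates are visited in decreasing absolute Pearson correlation
    with the target; one is retained only if its absolute pairwise
    correlation with every already-retained feature is <= ``threshold``.
    Constant columns are skipped.
    """
    if features.shape[1] < 1:
        raise ValidationError("collinearity filter needs at least one feature")
    common = features.index.intersection(target.dropna().index)
    feats = features.loc[common]
    y = target.loc[common]
    marginal = {}
    for name in feats.columns:
        col = feats[name].dropna()
        if not varies(col):
            continue
        aligned = y.loc[col.index]
        if not varies(aligned):
            continue
        r = float(np.corrcoef(col, aligned)[0, 1])
        if np.isfinite(r):
            marginal[name] = abs(r)
    order = sorted(marginal, key=lambda k: (-marginal[k], list(feats.columns).index(k)))
    retained: list[str] = []
    for name in order:
        ok = True
        for kept in retained:
            pair = feats[[name, kept]].dropna()
            r = abs(float(np.corrcoef(pair[name], pair[kept])[0, 1]))
            if not np.isfinite(r):
                r = 1.0  # numerically degenerate pair: treat as dependent
            if r > threshold:
                logger.debug("dropping %s (|r|=%.3f with %s)", name, r, kept)
                ok = False
                break
        if ok:
            retained.append(name)
    return retained


def _design(features: pd.DataFrame, with_intercept: bool) -> pd.DataFrame:
    X = features.astype(float)
    if with_intercept:
        X = sm.add_constant(X, prepend=True, has_constant="raise")
    return X


def fit_ols(
    features: pd.DataFrame,
    target: pd.Series,
    with_intercept: bool = True,
) -> RegressionModel:
    """Ordinary least squares on the selected columns.

    R2 is 1 - RSS/TSS with TSS about the mean for intercept models and
    about zero (uncentred) for no-intercept models; standard errors use
    the unbiased residual variance RSS / (n - p).
    """
    data = pd.concat([features, target.rename("__y__")], axis=1).dropna()
    X = _design(data[list(features.columns)], with_intercept)
    y = data["__y__"]
    n, p = X.shape
    if n <= p:
        raise ValidationError(f"n = {n} observations cannot identify {p} parameters")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < p:
        corr = data[list(features.columns)].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax() if len(features.columns) > 1 else tuple(features.columns)
        raise RankDeficientError(
            f"design matrix rank {rank} < {p}; dependent columns near {worst}"
        )
    res = sm.OLS(y, X).fit()
    names = [c for c in X.columns if c != "const"]
    intercept = float(res.params["const"]) if with_intercept else None
    return RegressionModel(
        target=str(target.name or "y"),
        terms=tuple(names),
        coefficients=tuple(float(res.params[c]) for c in names),
        intercept=intercept,
        r2=float(res.rsquared),
        t_values=tuple(float(res.tvalues[c]) for c in names),
        p_values=tuple(float(res.pvalues[c]) for c in names),
        n=n,
        uncentred_r2=not with_intercept,
    )


def backward_stepwise(
    features: pd.DataFrame,
    target: pd.Series,
    alpha_remove: float = 0.05,
    with_intercept: bool = True,
) -> RegressionModel:
    """Backward elimination from the full model by largest p value.

    At each step the term with the largest p exceeding ``alpha_remove``
    is removed (ties broken by smaller absolute t, then by later column
    order) and the model refitted, until all terms are significant or a
    single term remains.  The selection trace (every intermediate
    model) is attached to the returned model.
    """
    candidates = [c for c in features.columns if varies(features[c])]
    if not candidates:
        raise ValidationError("backward stepwise needs at least one varying candidate")
    trace: list[dict] = []
    current = list(candidates)
    while True:
        model = fit_ols(features[current], target, with_intercept)
        trace.append(
            {
                "terms": tuple(current),
                "r2": model.r2,
                "p_values": dict(zip(model.terms, model.p_values)),
                "equation": model.equation(),
            }
        )
        worst = _removal_candidate(model, alpha_remove, list(features.columns))
        if worst is None or len(current) == 1:
            break
        current.remove(worst)
    model.selection_trace = trace
    if len(current) == 1 and model.p_values[0] > alpha_remove:
        logger.warning(
            "%s: single remaining term %s not significant (p=%.3f); kept as the minimal model",
            model.target,
            current[0],
            model.p_values[0],
        )
    return model


def _removal_candidate(
    model: RegressionModel, alpha_remove: float, column_order: list[str]
) -> str | None:
    over = [
        (p, -abs(t), -column_order.index(name), name)
        for name, t, p in zip(model.terms, model.t_values, model.p_values)
        if p > alpha_remove
    ]
    if not over:
        return None
    over.sort(reverse=True)  # largest p; then smallest |t|; then latest column
    return over[0][3]


def intercept_only_model(target: pd.Series, name: str | None = None) -> RegressionModel:
    """Degenerate fallback: predict the training mean (flagged)."""
    y = target.dropna()
    return RegressionModel(
        target=str(name or target.name or "y"),
        terms=(),
        coefficients=(),
        intercept=float(y.mean()),
        r2=0.0,
        t_values=(),
        p_values=(),
        n=len(y),
        intercept_only=True,
    )
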