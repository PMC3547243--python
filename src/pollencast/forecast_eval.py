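"""Hold-out-year prediction and error reporting.

A fitted (or externally supplied printed) regression model is applied
to the feature values of years excluded from fitting; the prediction
error is the signed difference observed - expected.  Day-of-year and
concentration targets are rounded to the nearest integer before
differencing, matching the integer arithmetic of published
observed/expected/difference tables; the raw model output is retained
alongside.

The package ships the published birch study's hold-out table and model
equations (Cracow, fitted 1991-2008, validated 2009-2010) as reference
fixtures: :func:`printed_holdout_table` and :func:`printed_models`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from pollencast.io_core import ValidationError
from pollencast.model_build import RegressionModel


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class PredictionRecord:
    year: int
    target: str
    observed: float
    expected: int  # rounded model output
    expected_raw: float
    difference: float  # observed - expected (after rounding of expected)


def predict(model: RegressionModel, features: Mapping[str, float]) -> float:
    """Raw model output intercept + sum(coefficient * feature value)."""
    value = model.intercept or 0.0
    for name, coef in zip(model.terms, model.coefficients):
        if name not in features or pd.isna(features[name]):
            raise ValidationError(f"missing value for model term {name!r}")
        value += coef * float(features[name])
    return float(value)


def predict_rounded(model: RegressionModel, features: Mapping[str, float]) -> int:
    """Model output rounded to the nearest integer for reporting."""
    return _round_half_up(predict(model, features))


def prediction_error(observed: float, expected: float) -> float:
    """Signed error observed - expected."""
    return observed - expected


def holdout_report(
    models: Iterable[RegressionModel],
    features: pd.DataFrame,
    characteristics: pd.DataFrame,
    holdout_years: Iterable[int],
    training_years: Iterable[int] | None = None,
) -> pd.DataFrame:
    """One record per model x hold-out year.

    Columns: target, year, r2, observed, expected (rounded), raw
    expected and the signed difference.  Hold-out years must be
    disjoint from the fitting years.
    """
    holdout_years = sorted(holdout_years)
    if training_years is not None:
        overlap = set(holdout_years) & set(training_years)
        if overlap:
            raise ValidationError(f"holdout years {sorted(overlap)} overlap training")
    rows = []
    for model in models:
        for year in holdout_years:
            if year not in characteristics.index:
                raise ValidationError(f"no observed characteristics for year {year}")
            observed_raw = float(characteristics.loc[year, model.target])
            observed = _round_half_up(observed_raw)
            feats = features.loc[year].to_dict() if year in features.index else {}
            raw = predict(model, feats)
            expected = _round_half_up(raw)
            rows.append(
                {
                    "target": model.target,
                    "year": year,
                    "r2": model.r2,
                    "observed": observed,
                    "observed_raw": observed_raw,
                    "expected": expected,
                    "expected_raw": raw,
                    "difference": prediction_error(observed, expected),
                }
            )
    return pd.DataFrame(rows)


def _read_packaged_csv(name: str) -> pd.DataFrame:
    with resources.files("pollencast.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def printed_holdout_table() -> pd.DataFrame:
    """The published hold-out table: 8 models x 2 validation years.

    Columns model_id, target, variant, r2, year, observed, expected,
    difference — the printed integer triples, used as a consistency
    fixture (difference = observed - expected must hold in every row).
    """
    return _read_packaged_csv("holdout_table5.csv")


def printed_models() -> dict[str, RegressionModel]:
    """The published model equations as :class:`RegressionModel` objects.

    Only intercept, terms, coefficients and R2 are known from print;
    t/p values are not reconstructed and are left empty.
    """
    df = _read_packaged_csv("printed_models.csv")
    out: dict[str, RegressionModel] = {}
    for _, row in df.iterrows():
        terms = tuple(row["terms"].split(";"))
        coefs = tuple(float(c) for c in str(row["coefficients"]).split(";"))
        out[row["model_id"]] = RegressionModel(
            target=row["target"],
            terms=terms,
            coefficients=coefs,
            intercept=float(row["intercept"]),
            r2=float(row["r2"]),
            t_values=(),
            p_values=(),
            n=18,
        )
    return out
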