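"""End-to-end study replica: data -> features -> seasons -> screening ->
models -> hold-out validation.

``run_study`` sequences the whole analysis on either ingested CSV data
or the synthetic generator: derive predictor features, delimit pollen
seasons (98/95 % method by default), screen features by Spearman rank
correlation on the training years, build backward-stepwise models for
season start (SS), end (SE), peak day (PD) and peak concentration
(PC), and validate them on the held-out final years.  Every decision
point (features dropped, terms removed, fallbacks) is appended to a
machine-readable event log carried on the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from pollencast.io_core import (
    DailyMetSeries,
    DailyPollenSeries,
    ValidationError,
    read_met_csv,
    read_pollen_csv,
)
from pollencast.met_features import DEFAULT_FEATURE_SPEC, WindowSpec, feature_matrix
from pollencast.model_build import (
    RegressionModel,
    backward_stepwise,
    collinearity_filter,
    intercept_only_model,
    varies,
)
from pollencast.season_metrics import METHODS, SeasonDefinition, compare_methods, season_table
from pollencast.stats_screen import screen
from pollencast.forecast_eval import holdout_report
from pollencast.synthetic_data import GeneratorConfig, generate_study

logger = logging.getLogger(__name__)

# season characteristics modelled, by conventional symbol
TARGETS = {
    "SS": "start",
    "SE": "end",
    "PD": "peak_day",
    "PC": "peak_concentration",
}


@dataclass
class PipelineConfig:
    """Everything one study run depends on."""

    pollen_csv: str | Path | None = None
    met_csv: str | Path | None = None
    generator: GeneratorConfig | None = None

    season_method: str = "98/95"
    feature_spec: Sequence[WindowSpec] = DEFAULT_FEATURE_SPEC
    screening_alpha: float = 0.01
    alpha_remove: float = 0.05
    collinearity_threshold: float = 0.7
    n_holdout_years: int = 2
    holdout_years: Sequence[int] | None = None  # default: the last n years
    with_intercept: bool = True
    targets: Mapping[str, str] = field(default_factory=lambda: dict(TARGETS))

    def __post_init__(self) -> None:
        for name, value in (
            ("screening_alpha", self.screening_alpha),
            ("alpha_remove", self.alpha_remove),
            ("collinearity_threshold", self.collinearity_threshold),
        ):
            if not 0.0 < value < 1.0:
                raise ValidationError(f"{name} must be in (0, 1), got {value}")
        if self.season_method not in METHODS:
            raise ValidationError(f"unknown season method {self.season_method!r}")

    @property
    def season_definition(self) -> SeasonDefinition:
        return METHODS[self.season_method]


@dataclass
class StudyReport:
    """Report bundle of one study run."""

    seasons: pd.DataFrame  # per-year season characteristics (all years)
    method_comparison: pd.DataFrame  # V% per method per characteristic
    correlations: pd.DataFrame  # screened significant correlations
    models: dict[str, RegressionModel]
    model_table: pd.DataFrame  # coefficients / R2 / t / p per final model
    holdout: pd.DataFrame  # observed / expected / difference per model x year
    training_years: list[int]
    holdout_years: list[int]
    events: list[dict]  # machine-readable decision trace

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.seasons.to_csv(out / "season_table.csv")
        self.method_comparison.to_csv(out / "method_comparison.csv")
        self.correlations.to_csv(out / "correlation_table.csv", index=False)
        self.model_table.to_csv(out / "model_table.csv", index=False)
        self.holdout.to_csv(out / "holdout_table.csv", index=False)
        with open(out / "decisions.jsonl", "w") as fh:
            for event in self.events:
                fh.write(json.dumps(event) + "\n")


def _load_data(
    config: PipelineConfig,
) -> tuple[dict[int, DailyMetSeries], dict[int, DailyPollenSeries], list[dict]]:
    events: list[dict] = []
    if config.generator is not None:
        met, pollen, truth = generate_study(config.generator)
        events.append(
            {
                "stage": "simulate",
                "n_years": config.generator.n_years,
                "seed": config.generator.seed,
            }
        )
        return met, pollen, events
    if config.pollen_csv is None or config.met_csv is None:
        raise ValidationError("either a generator or both input CSV paths required")
    pollen = read_pollen_csv(config.pollen_csv)
    met = read_met_csv(config.met_csv)
    events.append({"stage": "ingest", "years": sorted(pollen)})
    return met, pollen, events


def _model_table(models: Mapping[str, RegressionModel]) -> pd.DataFrame:
    rows = []
    for key, model in models.items():
        rows.append(
            {
                "target": model.target,
                "terms": ";".join(model.terms),
                "coefficients": ";".join(f"{c:.6g}" for c in model.coefficients),
                "intercept": model.intercept,
                "r2": model.r2,
                "t_values": ";".join(f"{t:.4g}" for t in model.t_values),
                "p_values": ";".join(f"{p:.4g}" for p in model.p_values),
                "n": model.n,
                "intercept_only": model.intercept_only,
                "equation": model.equation(),
            }
        )
    return pd.DataFrame(rows)


def run_study(config: PipelineConfig) -> StudyReport:
    """Run the full analysis and return the report bundle."""
    met, pollen, events = _load_data(config)
    years = sorted(set(met) & set(pollen))
    if config.holdout_years is not None:
        holdout_years = sorted(config.holdout_years)
    else:
        holdout_years = years[-config.n_holdout_years :]
    training_years = [y for y in years if y not in holdout_years]
    missing = set(holdout_years) - set(years)
    if missing:
        raise ValidationError(f"holdout years {sorted(missing)} absent from data")
    if not training_years:
        raise ValidationError("no training years left after removing the holdout")
    events.append({"stage": "split", "training": training_years, "holdout": holdout_years})

    features = feature_matrix(met, config.feature_spec)
    seasons = season_table(pollen, config.season_definition)
    comparison = compare_methods(pollen)
    characteristics = pd.DataFrame(
        {symbol: seasons[col] for symbol, col in config.targets.items()}
    )
    characteristics["SPI"] = seasons["spi"]
    characteristics["duration"] = seasons["duration"]

    train_feats = features.loc[training_years]
    train_chars = characteristics.loc[training_years]

    varying = [c for c in train_feats.columns if varies(train_feats[c])]
    dropped = [c for c in train_feats.columns if c not in varying]
    if dropped:
        events.append({"stage": "screen", "dropped_constant_features": dropped})
    try:
        correlations = screen(
            train_feats[varying] if varying else train_feats,
            train_chars,
            alpha=config.screening_alpha,
        )
    except ValidationError as exc:
        logger.warning("screening skipped: %s", exc)
        events.append({"stage": "screen", "skipped": str(exc)})
        correlations = pd.DataFrame(
            columns=["feature", "characteristic", "rho", "p", "n"]
        )

    models: dict[str, RegressionModel] = {}
    for symbol in config.targets:
        target = train_chars[symbol].rename(symbol)
        candidates = varying
        if not candidates:
            model = intercept_only_model(target, symbol)
            events.append({"stage": "fit", "target": symbol, "fallback": "intercept_only"})
        else:
            kept = collinearity_filter(
                train_feats[candidates], target, config.collinearity_threshold
            )
            events.append(
                {
                    "stage": "collinearity",
                    "target": symbol,
                    "candidates": candidates,
                    "retained": kept,
                }
            )
            if not kept:
                model = intercept_only_model(target, symbol)
                events.append(
                    {"stage": "fit", "target": symbol, "fallback": "intercept_only"}
                )
            else:
                model = backward_stepwise(
                    train_feats[kept],
                    target,
                    alpha_remove=config.alpha_remove,
                    with_intercept=config.with_intercept,
                )
                events.append(
                    {
                        "stage": "fit",
                        "target": symbol,
                        "trace": [
                            {"terms": list(t["terms"]), "r2": t["r2"]}
                            for t in model.selection_trace
                        ],
                    }
                )
        models[symbol] = model

    holdout = holdout_report(
        models.values(),
        features,
        characteristics,
        holdout_years,
        training_years=training_years,
    )
    return StudyReport(
        seasons=seasons,
        method_comparison=comparison,
        correlations=correlations,
        models=models,
        model_table=_model_table(models),
        holdout=holdout,
        training_years=training_years,
        holdout_years=holdout_years,
        events=events,
    )
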