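import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from pollencast.io_core import ValidationError, days_in_year
from pollencast.met_features import daily_indicators
from pollencast.season_metrics import METHODS, season_table
from pollencast.synthetic_data import (
    MONTHLY_TEMP,
    GeneratorConfig,
    daily_climatology,
    generate_met_year,
    generate_pollen_year,
    generate_study,
    hum10_normal,
    true_season_start,
)


def _monthly_means(values: np.ndarray, year: int) -> pd.Series:
    dates = pd.date_range(f"{year}-01-01", periods=days_in_year(year), freq="D")
    return pd.Series(values, index=dates).groupby(dates.month).mean()


def test_zero_noise_monthly_means_match_normals_exactly():
    config = GeneratorConfig(seed=0).zero_noise()
    met = generate_met_year(config, 1995)
    temp = daily_indicators(met)["temperature"].to_numpy()
    monthly = _monthly_means(temp, 1995)
    assert monthly[7] == pytest.approx(19.8, abs=1e-9)  # July normal
    for m in range(1, 13):
        assert monthly[m] == pytest.approx(MONTHLY_TEMP[m - 1], abs=1e-9)


def test_january_coldest_july_warmest():
    config = GeneratorConfig(seed=3)
    met = generate_met_year(config, 2000)
    monthly = _monthly_means(daily_indicators(met)["temperature"].to_numpy(), 2000)
    clim = _monthly_means(daily_climatology(config.monthly_temp, 2000), 2000)
    assert clim.idxmin() == 1 and clim.idxmax() == 7
    assert abs(monthly - clim).max() < 6.0  # anomalies stay weather-sized


def test_same_seed_reproduces_series():
    config = GeneratorConfig(seed=42)
    a = generate_met_year(config, 1993)
    b = generate_met_year(config, 1993)
    pd.testing.assert_frame_equal(a.frame, b.frame)
    pa, ta = generate_pollen_year(a, config)
    pb, tb = generate_pollen_year(b, config)
    pd.testing.assert_series_equal(pa.values, pb.values)
    assert ta == tb


def test_adding_years_never_perturbs_earlier_years():
    small = GeneratorConfig(n_years=5, seed=9)
    large = dataclasses.replace(small, n_years=8)
    met_s, pollen_s, _ = generate_study(small)
    met_l, pollen_l, _ = generate_study(large)
    for year in met_s:
        pd.testing.assert_frame_equal(met_s[year].frame, met_l[year].frame)
        pd.testing.assert_series_equal(pollen_s[year].values, pollen_l[year].values)


def test_generated_years_satisfy_domain_invariants():
    config = GeneratorConfig(seed=13)
    for year in (1992, 1996, 2001, 2007):  # constructor validates all bounds
        met = generate_met_year(config, year)
        f = met.frame
        assert (f["tmin"] <= f["t7"]).all() and (f["t7"] <= f["tmax"]).all()
        assert (f["tmin"] <= f["t19"]).all() and (f["t19"] <= f["tmax"]).all()
        assert len(f) == days_in_year(year)
        pollen, truth = generate_pollen_year(met, config)
        assert (pollen.values.dropna() >= 0).all()
        assert 60 <= truth["true_start"] <= 150


def test_linkage_start_at_zero_temperature():
    """With a1 = -1.51, a2 = 0, no noise and Temp_6 = 0 the true start is
    the intercept 102.94 (day 103 after rounding)."""
    config = dataclasses.replace(
        GeneratorConfig(seed=0).zero_noise(),
        monthly_temp=(0.0,) * 12,
        start_hum_coef=0.0,
    )
    met = generate_met_year(config, 1995)
    assert daily_indicators(met)["temperature"].loc[51:60].mean() == pytest.approx(0.0)
    start = true_season_start(config, met, np.random.default_rng(0))
    assert start == pytest.approx(102.94)
    assert round(start) == 103


def test_spi_scale_honoured_without_dispersion():
    config = dataclasses.replace(
        GeneratorConfig(seed=4).zero_noise(), spi_log_mean=math.log(5000.0)
    )
    met = generate_met_year(config, 1997)
    pollen, _ = generate_pollen_year(met, config)
    spi = season_table({1997: pollen}, METHODS["98/95"]).loc[1997, "spi"]
    assert spi == pytest.approx(5000.0, rel=0.03)  # discretisation only


def test_spi_much_more_variable_than_start():
    from pollencast.season_metrics import coefficient_of_variation

    ratios = []
    for seed in range(6):
        _, pollen, _ = generate_study(GeneratorConfig(n_years=18, seed=100 + seed))
        table = season_table(pollen, METHODS["98/95"])
        ratios.append(
            coefficient_of_variation(table["spi"])
            / coefficient_of_variation(table["start"])
        )
    assert min(ratios) > 3.0


def test_stray_grains_bounded_and_outside_season():
    config = GeneratorConfig(seed=15)
    met = generate_met_year(config, 1994)
    pollen, truth = generate_pollen_year(met, config)
    after = pollen.values.loc[int(truth["true_start"]) + 120 :]
    assert float(after.sum()) <= config.stray_grains * 1.5


def test_truth_sidecar_matches_regression_recovery(default_study):
    """Fitting measured starts on Temp_6/Hum_10 recovers the configured
    linkage slopes to simulation accuracy."""
    from pollencast.met_features import DEFAULT_FEATURE_SPEC, feature_matrix
    from pollencast.model_build import fit_ols

    config, met, pollen, truth = default_study
    feats = feature_matrix(met, DEFAULT_FEATURE_SPEC)[["Temp_6", "Hum_10"]]
    starts = season_table(pollen, METHODS["98/95"])["start"].rename("SS")
    model = fit_ols(feats, starts)
    assert model.coefficients[0] == pytest.approx(config.start_temp_coef, abs=0.5)
    assert model.coefficients[1] == pytest.approx(config.start_hum_coef, abs=0.4)


def test_study_files_written_and_collision_guard(tmp_path):
    config = GeneratorConfig(n_years=3, seed=2, first_year=2001)
    generate_study(config, out_dir=tmp_path)
    names = {p.name for p in tmp_path.iterdir()}
    assert names == {"met.csv", "pollen.csv", "truth.txt"}
    truth_text = (tmp_path / "truth.txt").read_text()
    assert "start_temp_coef = -1.51" in truth_text
    with pytest.raises(ValidationError, match="exists"):
        generate_study(config, out_dir=tmp_path)
    # fixed seed: byte-identical rerun
    before = (tmp_path / "pollen.csv").read_bytes()
    generate_study(config, out_dir=tmp_path, overwrite=True)
    assert (tmp_path / "pollen.csv").read_bytes() == before


def test_invalid_normals_rejected():
    with pytest.raises(ValidationError, match="humidity"):
        GeneratorConfig(monthly_humidity=(105.0,) * 12)
    with pytest.raises(ValidationError):
        GeneratorConfig(n_years=1)


def test_hum10_normal_is_early_april_humidity():
    config = GeneratorConfig(seed=0)
    value = hum10_normal(config, 1995)
    assert 60.0 <= value <= 85.0
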