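import numpy as np
import pandas as pd
import pytest

from pollencast.io_core import ValidationError
from pollencast.model_build import (
    RankDeficientError,
    backward_stepwise,
    collinearity_filter,
    fit_ols,
    intercept_only_model,
    varies,
)


def normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent oracle: solve X'X beta = X'y directly."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def _frame(arr, names):
    return pd.DataFrame(arr, columns=names, index=range(len(arr)))


def test_exact_line_recovered():
    x = np.arange(10.0)
    model = fit_ols(_frame(x[:, None], ["x"]), pd.Series(2 * x + 1, name="y"))
    assert model.coefficients[0] == pytest.approx(2.0, abs=1e-10)
    assert model.intercept == pytest.approx(1.0, abs=1e-10)
    assert model.r2 == pytest.approx(1.0)


def test_orthogonal_target_gives_zero_slope():
    x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    y = np.array([1.0, -1.0, 0.0, -1.0, 1.0])  # even function: zero covariance
    model = fit_ols(_frame(x[:, None], ["x"]), pd.Series(y, name="y"))
    assert model.coefficients[0] == pytest.approx(0.0, abs=1e-12)


def test_matches_normal_equations_oracle():
    rng = np.random.default_rng(17)
    for _ in range(25):
        X = rng.normal(size=(12, 2))
        y = rng.normal(size=12)
        model = fit_ols(_frame(X, ["a", "b"]), pd.Series(y, name="y"))
        design = np.column_stack([np.ones(12), X])
        beta = normal_equations(design, y)
        assert model.intercept == pytest.approx(beta[0], abs=1e-10)
        assert model.coefficients[0] == pytest.approx(beta[1], abs=1e-10)
        assert model.coefficients[1] == pytest.approx(beta[2], abs=1e-10)


def test_residuals_orthogonal_to_design():
    rng = np.random.default_rng(23)
    X = rng.normal(size=(30, 3))
    y = pd.Series(rng.normal(size=30), name="y")
    feats = _frame(X, ["a", "b", "c"])
    model = fit_ols(feats, y)
    fitted = model.intercept + X @ np.array(model.coefficients)
    resid = y.to_numpy() - fitted
    assert abs(resid.sum()) < 1e-8
    for j in range(3):
        assert abs(resid @ X[:, j]) < 1e-8


def test_no_intercept_uncentred_r2_and_df():
    rng = np.random.default_rng(29)
    x = rng.random(15) + 1.0
    y = pd.Series(3.0 * x + rng.normal(0, 0.1, 15), name="y")
    model = fit_ols(_frame(x[:, None], ["x"]), y, with_intercept=False)
    assert model.intercept is None
    assert model.uncentred_r2
    fitted = x * model.coefficients[0]
    rss = ((y.to_numpy() - fitted) ** 2).sum()
    assert model.r2 == pytest.approx(1 - rss / (y.to_numpy() ** 2).sum())
    # standard error from unbiased residual variance with df = n - 1 term
    se = np.sqrt(rss / (15 - 1) / (x @ x))
    assert model.coefficients[0] / se == pytest.approx(model.t_values[0], rel=1e-9)


def test_rank_deficiency_reported():
    x = np.arange(10.0)
    feats = _frame(np.column_stack([x, 2 * x]), ["a", "b"])
    with pytest.raises(RankDeficientError):
        fit_ols(feats, pd.Series(x, name="y"))


def test_collinearity_filter_drops_duplicate():
    rng = np.random.default_rng(31)
    x = rng.normal(size=50)
    feats = _frame(np.column_stack([x, x, rng.normal(size=50)]), ["a", "a2", "c"])
    y = pd.Series(x + rng.normal(0, 0.5, 50), name="y")
    kept = collinearity_filter(feats, y, threshold=0.7)
    assert ("a" in kept) ^ ("a2" in kept)
    assert "c" in kept


def test_collinearity_filter_keeps_independent_noise():
    rng = np.random.default_rng(37)
    feats = _frame(rng.normal(size=(200, 5)), list("abcde"))
    y = pd.Series(rng.normal(size=200), name="y")
    assert len(collinearity_filter(feats, y, threshold=0.7)) == 5


def test_backward_stepwise_removes_noise_keeps_signal():
    rng = np.random.default_rng(41)
    hits = 0
    for _ in range(50):
        x = rng.normal(size=(100, 2))
        y = pd.Series(2.0 * x[:, 0] + rng.normal(size=100), name="y")
        model = backward_stepwise(_frame(x, ["signal", "noise"]), y, alpha_remove=0.05)
        hits += model.terms == ("signal",)
    assert hits >= 45  # noise survives only at the type-I rate


def test_backward_stepwise_keeps_all_informative():
    rng = np.random.default_rng(43)
    x = rng.normal(size=(200, 3))
    y = pd.Series(x @ np.array([1.0, -2.0, 1.5]) + rng.normal(size=200), name="y")
    model = backward_stepwise(_frame(x, ["a", "b", "c"]), y)
    assert set(model.terms) == {"a", "b", "c"}


def test_stepwise_trace_r2_non_increasing():
    rng = np.random.default_rng(47)
    x = rng.normal(size=(25, 4))
    y = pd.Series(x[:, 0] + rng.normal(size=25), name="y")
    model = backward_stepwise(_frame(x, list("abcd")), y, alpha_remove=0.01)
    r2s = [step["r2"] for step in model.selection_trace]
    assert all(r2s[i] >= r2s[i + 1] - 1e-12 for i in range(len(r2s) - 1))
    assert len(model.selection_trace) >= 2  # final and penultimate models exposed


def test_parameter_recovery_exact_without_noise():
    """SS = a - b*Temp_6 + c*Hum_10 with zero noise is recovered exactly."""
    rng = np.random.default_rng(53)
    temp6 = rng.normal(1.0, 3.0, 18)
    hum10 = rng.normal(70.0, 4.0, 18)
    y = pd.Series(102.94 - 1.51 * temp6 + 0.59 * hum10, name="SS")
    feats = _frame(np.column_stack([temp6, hum10]), ["Temp_6", "Hum_10"])
    model = fit_ols(feats, y)
    assert model.coefficients[0] == pytest.approx(-1.51, abs=1e-8)
    assert model.coefficients[1] == pytest.approx(0.59, abs=1e-8)
    assert model.intercept == pytest.approx(102.94, abs=1e-6)


def test_parameter_recovery_noisy_mean_within_2se():
    """Mean coefficients over 200 noisy 18-year fits stay within two
    regression standard errors of the generating values."""
    rng = np.random.default_rng(59)
    coefs, ses = [], []
    for _ in range(200):
        temp6 = rng.normal(1.0, 3.0, 18)
        hum10 = rng.normal(70.0, 4.0, 18)
        y = pd.Series(
            102.94 - 1.51 * temp6 + 0.59 * hum10 + rng.normal(0, 2.0, 18), name="SS"
        )
        feats = _frame(np.column_stack([temp6, hum10]), ["Temp_6", "Hum_10"])
        model = fit_ols(feats, y)
        coefs.append(model.coefficients)
        ses.append([c / t for c, t in zip(model.coefficients, model.t_values)])
    mean = np.array(coefs).mean(axis=0)
    typical_se = np.abs(ses).mean(axis=0)
    assert abs(mean[0] - (-1.51)) < 2 * typical_se[0]
    assert abs(mean[1] - 0.59) < 2 * typical_se[1]


def test_varies_rejects_float_jitter():
    jitter = pd.Series(10.0 + np.array([0.0, 1e-14, -1e-14, 2e-14] * 4))
    assert not varies(jitter)
    assert varies(pd.Series([1.0, 1.1, 0.9, 1.05]))


def test_stepwise_requires_varying_candidates():
    feats = pd.DataFrame({"c": [1.0] * 10})
    with pytest.raises(ValidationError):
        backward_stepwise(feats, pd.Series(np.arange(10.0), name="y"))


def test_intercept_only_model_predicts_mean():
    y = pd.Series([3.0, 5.0, 7.0], name="SS")
    model = intercept_only_model(y)
    assert model.intercept_only
    assert model.intercept == pytest.approx(5.0)
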