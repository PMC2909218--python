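"""Linear, LOESS and quantile normalization against the mean reference."""

import numpy as np
import pandas as pd
import pytest

from twocolorqc import (
    ExpressionMatrix,
    apply_linear,
    apply_loess,
    fit_linear,
    fit_loess,
    mean_reference,
    normalize_matrix,
    quantile_normalize,
)
from tests.conftest import random_matrix


def _matrix(columns: dict, channel="Cy3"):
    return ExpressionMatrix(pd.DataFrame(columns), channel=channel)


# -- mean reference ---------------------------------------------------------


def test_mean_reference_examples():
    m = _matrix({"a": [6.0, 8.0], "b": [8.0, 10.0]})
    np.testing.assert_allclose(mean_reference(m).to_numpy(), [7.0, 9.0])
    m2 = _matrix({"a": [5.0, 6.0], "b": [5.0, 6.0]})
    np.testing.assert_allclose(mean_reference(m2).to_numpy(), [5.0, 6.0])


def test_mean_reference_matches_column_mean_oracle():
    m = random_matrix(300, 20, seed=1)
    oracle = m.values.sum(axis=1) / m.n_arrays
    np.testing.assert_allclose(mean_reference(m).to_numpy(), oracle, atol=1e-12)


def test_mean_reference_requires_two_arrays():
    with pytest.raises(ValueError):
        mean_reference(_matrix({"a": [1.0, 2.0]}))


# -- linear -----------------------------------------------------------------


def test_linear_identity_and_offset():
    x = np.linspace(5, 15, 50)
    m = fit_linear(x, x)
    assert (m.alpha, m.beta) == (pytest.approx(0.0, abs=1e-12),
                                 pytest.approx(1.0, abs=1e-12))
    m2 = fit_linear(x + 0.5, x)
    assert m2.alpha == pytest.approx(0.5, abs=1e-12)
    assert m2.beta == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_allclose(apply_linear(x + 0.5, x, m2), x, atol=1e-12)
    np.testing.assert_allclose(apply_linear(x, x, m), x, atol=1e-12)


def test_linear_matches_closed_form_ols_oracle():
    rng = np.random.default_rng(4)
    x = rng.normal(8, 2, size=400)
    y = 0.7 + 1.2 * x + rng.normal(0, 0.3, size=400)
    model = fit_linear(y, x)
    beta = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
    alpha = y.mean() - beta * x.mean()
    assert model.alpha == pytest.approx(alpha, abs=1e-10)
    assert model.beta == pytest.approx(beta, abs=1e-10)


def test_linear_correction_removes_offset_and_slope():
    rng = np.random.default_rng(5)
    x = rng.normal(9, 2, size=2000)
    y = 1.1 * x - 0.8 + rng.normal(0, 0.2, size=2000)
    corrected = apply_linear(y, x, fit_linear(y, x))
    refit = fit_linear(corrected, x)
    assert refit.beta == pytest.approx(1.0, abs=0.01)
    assert refit.alpha == pytest.approx(0.0, abs=0.1)


def test_linear_zero_variance_reference_fatal():
    with pytest.raises(ValueError, match="zero variance"):
        fit_linear(np.array([1.0, 2.0, 3.0]), np.array([5.0, 5.0, 5.0]))


# -- loess ------------------------------------------------------------------


def test_loess_identity_unchanged():
    x = np.linspace(5, 15, 400)
    model = fit_loess(x, x)
    np.testing.assert_allclose(apply_loess(x, x, model), x, atol=1e-6)


def test_loess_removes_quadratic_bias():
    rng = np.random.default_rng(6)
    x = rng.normal(9, 2, size=3000)
    y = x + 0.05 * (x - x.mean()) ** 2 + rng.normal(0, 0.2, size=3000)
    corrected = apply_loess(y, x, fit_loess(y, x))
    # quadratic refit of the residual-vs-x curvature after correction
    quad = np.polyfit(x, corrected - x, 2)[0]
    assert abs(quad) < 0.005
    assert np.std(corrected - x) < np.std(y - x)


def test_loess_beats_no_correction_on_curved_array():
    """Offset −0.3, slope 0.96, mild curvature: the smooth correction brings
    the array closer to truth than leaving it alone."""
    rng = np.random.default_rng(7)
    truth = rng.normal(9, 2, size=3000)
    c = truth - truth.mean()
    y = truth - 0.3 + (0.96 - 1) * c + 0.02 * c**2 + rng.normal(0, 0.2, size=3000)
    corrected = apply_loess(y, truth, fit_loess(y, truth))
    assert np.abs(corrected - truth).mean() < np.abs(y - truth).mean()


def test_loess_warns_on_empty_segment():
    rng = np.random.default_rng(8)
    x = np.concatenate([rng.normal(5, 0.2, 200), rng.normal(15, 0.2, 200)])
    with pytest.warns(UserWarning, match="empty segment"):
        fit_loess(x.copy(), x, segments=10)


def test_loess_requires_enough_probes():
    x = np.linspace(0, 1, 50)
    with pytest.raises(ValueError, match="at least"):
        fit_loess(x, x, segments=10)


# -- quantile ---------------------------------------------------------------


def test_quantile_examples():
    m = _matrix({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
    out, _ = quantile_normalize(m)
    np.testing.assert_allclose(out.data["a"].to_numpy(), [2.5, 3.5, 4.5])
    np.testing.assert_allclose(out.data["b"].to_numpy(), [2.5, 3.5, 4.5])
    ident = _matrix({"a": [1.0, 5.0], "b": [1.0, 5.0]})
    out2, _ = quantile_normalize(ident)
    np.testing.assert_allclose(out2.values, ident.values, atol=1e-12)


def test_quantile_columns_become_exchangeable():
    m = random_matrix(500, 6, seed=9)
    out, _ = quantile_normalize(m)
    sorted_cols = np.sort(out.values, axis=0)
    for j in range(1, sorted_cols.shape[1]):
        np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0], atol=1e-12)


def test_quantile_ties_stay_tied():
    m = _matrix({"a": [1.0, 1.0, 3.0], "b": [2.0, 5.0, 8.0]})
    out, _ = quantile_normalize(m)
    assert out.data.loc[out.data.index[0], "a"] == out.data.loc[out.data.index[1], "a"]


def test_quantile_matches_naive_oracle():
    m = random_matrix(200, 5, seed=10)
    out, _ = quantile_normalize(m)
    # naive oracle: rank each column, take means of order statistics
    vals = m.values
    template = np.sort(vals, axis=0).mean(axis=1)
    for j in range(vals.shape[1]):
        order = np.argsort(vals[:, j], kind="stable")
        expected = np.empty_like(template)
        expected[order] = template
        np.testing.assert_allclose(out.values[:, j], expected, atol=1e-10)


# -- whole-matrix behaviour --------------------------------------------------


@pytest.mark.parametrize("method", ["linear", "loess", "quantile"])
def test_near_idempotence_on_noiseless_data(method):
    rng = np.random.default_rng(11)
    base = rng.normal(9, 2, size=600)
    cols = {}
    for j, (off, slope) in enumerate([(0.0, 1.0), (0.3, 0.97), (-0.2, 1.04)]):
        cols[f"a{j}"] = base + off + (slope - 1) * (base - base.mean())
    m = ExpressionMatrix(pd.DataFrame(cols, index=[f"P{i}" for i in range(600)]))
    once, _ = normalize_matrix(m, method=method)
    twice, _ = normalize_matrix(once, method=method)
    assert np.abs(twice.values - once.values).max() < 1e-6


def test_loess_recovers_residual_noise_scale(default_dataset, default_matrices):
    """Injected offsets/slopes/curvature removed: post-LOESS genewise SD is
    close to the configured residual noise, and raw > linear > loess."""
    cfg = default_dataset.config
    m3, _ = default_matrices
    lin, _ = normalize_matrix(m3, "linear")
    lo, _ = normalize_matrix(m3, "loess")
    sd_raw = m3.data.std(axis=1, ddof=1).mean()
    sd_lin = lin.data.std(axis=1, ddof=1).mean()
    sd_lo = lo.data.std(axis=1, ddof=1).mean()
    assert sd_lo == pytest.approx(cfg.noise_sd_cy3, rel=0.15)
    assert sd_raw > sd_lin > sd_lo
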