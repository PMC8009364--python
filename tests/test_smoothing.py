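import subprocess
import sys

import numpy as np
import pandas as pd
import pytest

from chronocollide.smoothing import (
    CyclicSmoother,
    cyclic_basis,
    cyclic_knots,
)

PERIOD = 29.53


def _sinusoid(n=300, amplitude=3.0, noise=0.1, seed=1):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, PERIOD, n)
    y = amplitude * np.cos(2 * np.pi * (x - 15) / PERIOD) + rng.normal(0, noise, n)
    return x, y


# -- basis and penalty ------------------------------------------------------


def test_basis_functions_are_periodic():
    knots = cyclic_knots(10, PERIOD)
    X0, _ = cyclic_basis(np.array([0.0]), knots, PERIOD)
    X1, _ = cyclic_basis(np.array([PERIOD]), knots, PERIOD)
    np.testing.assert_allclose(X0, X1, atol=1e-10)


def test_penalty_annihilates_the_constant_function():
    _, S = cyclic_basis(np.linspace(0, PERIOD, 50), cyclic_knots(10, PERIOD), PERIOD)
    ones = np.ones(S.shape[0])
    assert ones @ S @ ones == pytest.approx(0.0, abs=1e-10)
    eigvals = np.linalg.eigvalsh(S)
    assert eigvals.min() > -1e-10  # positive semidefinite


def test_basis_interpolates_at_knots():
    knots = cyclic_knots(10, PERIOD)
    X, _ = cyclic_basis(knots, knots, PERIOD)
    np.testing.assert_allclose(X, np.eye(len(knots)), atol=1e-10)


def test_sine_projects_onto_basis_with_small_residual():
    grid = np.linspace(0, PERIOD, 400, endpoint=False)
    X, _ = cyclic_basis(grid, cyclic_knots(10, PERIOD), PERIOD)
    target = np.sin(2 * np.pi * grid / PERIOD)
    coef, *_ = np.linalg.lstsq(X, target, rcond=None)
    assert np.abs(X @ coef - target).max() < 1e-3


def test_duplicate_knots_rejected():
    with pytest.raises(ValueError, match="knots"):
        cyclic_basis(np.array([1.0]), np.array([0.0, 5.0, 5.0, 10.0]), PERIOD)


# -- penalty limits ---------------------------------------------------------


def test_infinite_lambda_reduces_to_the_mean():
    x, y = _sinusoid()
    res = CyclicSmoother(x, y, k=10, period=PERIOD).fit(lam=np.inf)
    assert res.edf == pytest.approx(0.0, abs=1e-10)
    assert res.deviance_explained == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(res.fittedvalues, y.mean(), atol=1e-10)
    assert res.horizontal_line_test() is False


def test_zero_lambda_interpolates_at_the_knots():
    knots = cyclic_knots(10, PERIOD)
    y = np.sin(2 * np.pi * knots / PERIOD) + 0.3 * np.cos(4 * np.pi * knots / PERIOD)
    res = CyclicSmoother(knots, y, k=10, period=PERIOD).fit(lam=0.0)
    assert res.rss < 1e-16 * res.tss


def test_constant_response_reaches_zero_edf_without_failing():
    x = np.linspace(0, PERIOD, 60, endpoint=False)
    res = CyclicSmoother(x, np.full(60, 2.5), k=10, period=PERIOD).fit()
    assert res.rss == pytest.approx(0.0, abs=1e-18)
    np.testing.assert_allclose(res.fittedvalues, 2.5, atol=1e-8)


# -- fitting ----------------------------------------------------------------


def test_recovers_sinusoid_peak_location():
    x, y = _sinusoid(n=300, amplitude=3.0, noise=0.1, seed=1)
    res = CyclicSmoother(x, y, k=10, period=PERIOD).fit()
    peak = res.peak_location()
    assert min(abs(peak - 15.0), PERIOD - abs(peak - 15.0)) <= 1.0
    assert res.horizontal_line_test() is True
    assert res.deviance_explained > 0.9


def test_fitted_curve_and_bands_are_periodic():
    x, y = _sinusoid(seed=9)
    res = CyclicSmoother(x, y, k=10, period=PERIOD).fit()
    assert res.smooth([0.0])[0] == pytest.approx(res.smooth([PERIOD])[0], abs=1e-9)
    bands = res.bands(np.array([0.0, PERIOD]))
    assert bands.lower.iloc[0] == pytest.approx(bands.lower.iloc[1], abs=1e-9)
    assert bands.upper.iloc[0] == pytest.approx(bands.upper.iloc[1], abs=1e-9)


def test_edf_and_deviance_bounds(annotated):
    res = CyclicSmoother.from_counts(annotated, "moon_day").fit()
    assert 0.0 <= res.edf <= res.ref_df == 8
    assert 0.0 <= res.deviance_explained <= 1.0
    assert res.sigma2 > 0


def test_from_counts_builds_complete_cell_grid(annotated):
    model = CyclicSmoother.from_counts(annotated, "moon_day")
    years = annotated.year.nunique()
    assert len(model.y) == 29 * years
    assert model.y.sum() == annotated.moon_day.notna().sum()
    doy = CyclicSmoother.from_counts(annotated, "day_of_year")
    assert len(doy.y) == 365 * years


def test_more_knots_than_points_rejected():
    with pytest.raises(ValueError, match="observations"):
        CyclicSmoother(np.arange(5.0), np.arange(5.0), k=10, period=PERIOD)


def test_horizontal_line_test_needs_a_dense_grid():
    x, y = _sinusoid(seed=4)
    res = CyclicSmoother(x, y, k=10, period=PERIOD).fit()
    with pytest.raises(ValueError):
        res.horizontal_line_test(n_grid=50)


# -- independent GAM oracle -------------------------------------------------


def test_matches_mgcv_on_shared_data(tmp_path):
    """Same data, same knots: edf, deviance explained and the fitted curve
    must agree with R mgcv's cyclic cubic regression spline under GCV."""
    rng = np.random.default_rng(3)
    x = np.tile(np.arange(1.0, 30.0), 7)
    y = (
        5.0
        + 2.0 * np.cos(2 * np.pi * (x - 15) / 29.0)
        + 0.6 * np.sin(4 * np.pi * x / 29.0)
        + rng.normal(0, 1.0, len(x))
    )
    res = CyclicSmoother(x, y, k=10, period=29.0).fit()
    data = tmp_path / "xy.csv"
    out = tmp_path / "r.csv"
    pd.DataFrame({"x": x, "y": y}).to_csv(data, index=False)
    script = f"""
    suppressMessages(library(mgcv))
    d <- read.csv("{data.as_posix()}")
    fit <- gam(y ~ s(x, bs="cc", k=10), data=d, knots=list(x=seq(0, 29, length=10)))
    pred <- predict(fit, newdata=data.frame(x=1:29))
    write.csv(data.frame(edf=sum(fit$edf[-1]), dev=summary(fit)$dev.expl,
                         x=1:29, fit=pred), "{out.as_posix()}", row.names=FALSE)
    """
    proc = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
    )
    assert proc.returncode == 0, proc.stderr
    ref = pd.read_csv(out)
    assert res.edf == pytest.approx(ref.edf.iloc[0], abs=0.01)
    assert res.deviance_explained == pytest.approx(ref.dev.iloc[0], abs=1e-3)
    ours = res.alpha + res.smooth(np.arange(1.0, 30.0))
    np.testing.assert_allclose(ours, ref.fit.to_numpy(), atol=1e-3)
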