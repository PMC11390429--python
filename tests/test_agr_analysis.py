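"""Average-growth-rate curves, Monte-Carlo bands and delta(t) windows."""

import warnings

import numpy as np
import pytest

from lythrum.agr_analysis import (
    agr_band,
    agr_curve,
    default_grid,
    delta_agr,
    significance_windows,
    simulate_parameter_sets,
)
from lythrum.growth_models import fit_growth_model, get_model

GOMP = {"Asymp": 121.69, "b2": 4.28, "b3": 0.97}
LOGI = {"Asymp": 91.79, "xmid": 39.96, "scal": 29.13}


def test_grid_step_and_range():
    g = default_grid()
    assert g[0] == 0.0 and g[-1] == 150.0
    assert np.allclose(np.diff(g), 0.05)


def test_logistic_agr_peaks_at_quarter_asymp_over_scal():
    peak = agr_curve("logistic", LOGI, [LOGI["xmid"]])[0]
    assert peak == pytest.approx(91.79 / (4 * 29.13), rel=1e-12)
    # and it is the maximum over the season
    grid = default_grid()
    assert agr_curve("logistic", LOGI, grid).max() == pytest.approx(peak, rel=1e-6)


def test_gompertz_agr_vanishes_at_asymptote():
    assert agr_curve("gompertz", GOMP, [1e4])[0] == pytest.approx(0.0, abs=1e-8)


@pytest.mark.parametrize(
    "name, params",
    [
        ("gompertz", GOMP),
        ("logistic", LOGI),
        ("monomolecular", {"Asymp": 100.0, "R0": 5.0, "lrc": np.log(0.05)}),
        ("four_part_logistic", {"A": 3.0, "B": 90.0, "xmid": 45.0, "scal": 20.0}),
    ],
)
def test_agr_integrates_back_to_height_gain(name, params):
    from lythrum.growth_models import evaluate

    grid = default_grid()
    integral = np.trapezoid(agr_curve(name, params, grid), grid)
    gain = evaluate(name, params, 150.0) - evaluate(name, params, 0.0)
    assert integral == pytest.approx(gain, abs=1e-3)


class _FakeFit:
    """Minimal stand-in carrying just what simulate_parameter_sets needs."""

    def __init__(self, model, params, cov):
        self.model = get_model(model)
        self._params = params
        self.mean_cov = np.asarray(cov)
        self.group_mean_cov = {}
        self.messages = []

    def params_vector(self):
        return np.array([self._params[p] for p in self.model.params])


def test_zero_covariance_draws_equal_mean():
    fit = _FakeFit("gompertz", GOMP, np.zeros((3, 3)))
    draws = simulate_parameter_sets(fit, 200, seed=0)
    assert np.allclose(draws, fit.params_vector())


def test_simulate_rejects_bad_nsim():
    fit = _FakeFit("gompertz", GOMP, np.zeros((3, 3)))
    with pytest.raises(ValueError, match="n_sim"):
        simulate_parameter_sets(fit, -5)


def test_draw_mean_tracks_fitted_mean():
    cov = np.diag([3.18**2, 0.07**2, 0.0009**2])
    fit = _FakeFit("gompertz", GOMP, cov)
    draws = simulate_parameter_sets(fit, 1000, seed=1)
    assert draws[:, 0].mean() == pytest.approx(121.69, abs=3 * 3.18 / np.sqrt(1000))


def test_band_zero_width_for_identical_draws():
    draws = np.tile([121.69, 4.28, 0.97], (150, 1))
    band = agr_band(draws, "gompertz")
    assert np.allclose(band.ci_low, band.ci_high)
    assert np.allclose(band.mean, band.ci_low)


def test_band_requires_enough_draws():
    with pytest.raises(ValueError, match="100"):
        agr_band(np.tile([121.69, 4.28, 0.97], (50, 1)), "gompertz")


def test_band_contains_mean_and_shrinks_with_covariance():
    cov = np.diag([4.0, 0.01, 1e-6])
    fit = _FakeFit("gompertz", GOMP, cov)
    draws_full = simulate_parameter_sets(fit, 800, seed=2)
    fit_small = _FakeFit("gompertz", GOMP, cov * 0.25)
    draws_small = simulate_parameter_sets(fit_small, 800, seed=2)
    full = agr_band(draws_full, "gompertz")
    small = agr_band(draws_small, "gompertz")
    assert ((full.ci_low <= full.mean) & (full.mean <= full.ci_high)).all()
    width_full = full.ci_high - full.ci_low
    width_small = small.ci_high - small.ci_low
    assert width_small.mean() < width_full.mean()


def test_delta_agr_zero_for_identical_draw_sets():
    fit = _FakeFit("gompertz", GOMP, np.diag([4.0, 0.01, 1e-6]))
    draws = simulate_parameter_sets(fit, 300, seed=3)
    res = delta_agr(draws, draws.copy(), "gompertz")
    assert np.allclose(res.delta, 0.0)
    assert res.windows == []


def test_delta_agr_asymp_ratio_limit():
    """With outcrossed asymptote 1.2x selfed and identical shape, delta
    equals 1 - 1/1.2 at every time point."""
    selfed = np.tile([100.0, 4.28, 0.97], (200, 1))
    out = np.tile([120.0, 4.28, 0.97], (200, 1))
    res = delta_agr(selfed, out, "gompertz")
    assert np.allclose(res.delta, 1 - 1 / 1.2, rtol=1e-12)
    assert res.windows == [(0.0, 150.0)]


def test_delta_agr_requires_matching_draw_counts():
    a = np.tile([100.0, 4.28, 0.97], (200, 1))
    with pytest.raises(ValueError, match="draw counts"):
        delta_agr(a, a[:100], "gompertz")


def test_significance_windows_are_disjoint_and_ordered():
    grid = np.arange(0.0, 10.5, 0.5)
    lo = np.full_like(grid, -1.0)
    hi = np.full_like(grid, 1.0)
    lo[2:5] = 0.1          # significant: CI above zero
    hi[10:13] = -0.1       # significant: CI below zero
    wins = significance_windows(grid, lo, hi)
    assert wins == [(1.0, 2.0), (5.0, 6.0)]
    flat = [b for w in wins for b in w]
    assert flat == sorted(flat)


def test_pipeline_window_detects_2014_breeding_contrast(default_ds):
    """Default first-season calibration yields an early-starting
    significance window for inbreeding depression in growth rate."""
    h = default_ds.heights[default_ds.heights["year"] == 2014]
    meta = default_ds.plants.set_index("plant_id")["breeding"]
    rng = np.random.default_rng(0)
    draws = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for grp in ("selfed", "outcrossed"):
            sub = h[h["plant_id"].isin(meta[meta == grp].index)]
            fit = fit_growth_model(sub, "gompertz")
            draws[grp] = simulate_parameter_sets(fit, 500, seed=rng)
        res = delta_agr(draws["selfed"], draws["outcrossed"], "gompertz")
    assert res.windows, "expected a significance window"
    t_start, t_end = res.windows[0]
    assert t_start < 20.0            # starts near the beginning of the season
    assert t_end > 40.0              # extends through mid-season
    assert all(0 <= a <= b <= 150 for a, b in res.windows)
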