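"""Growth-curve evaluation, derivatives, fitting and model selection."""

import numpy as np
import pandas as pd
import pytest

from lythrum.growth_models import (
    MODEL_REGISTRY,
    DegenerateSeriesWarning,
    derivative,
    evaluate,
    fit_growth_model,
    get_model,
    select_model,
)

PARAMS = {
    "monomolecular": {"Asymp": 100.0, "R0": 5.0, "lrc": np.log(0.05)},
    "logistic": {"Asymp": 91.79, "xmid": 39.96, "scal": 29.13},
    "gompertz": {"Asymp": 121.69, "b2": 4.28, "b3": 0.97},
    "four_part_logistic": {"A": 3.0, "B": 90.0, "xmid": 45.0, "scal": 20.0},
}


def test_logistic_half_height_at_xmid():
    p = PARAMS["logistic"]
    assert evaluate("logistic", p, p["xmid"]) == pytest.approx(p["Asymp"] / 2)


def test_gompertz_asymptote_and_origin():
    p = PARAMS["gompertz"]
    assert evaluate("gompertz", p, 1e4) == pytest.approx(p["Asymp"], rel=1e-6)
    assert evaluate("gompertz", p, 0.0) == pytest.approx(
        121.69 * np.exp(-4.28), rel=1e-12
    )


def test_four_part_limits():
    p = PARAMS["four_part_logistic"]
    assert evaluate("four_part_logistic", p, 1e4) == pytest.approx(p["B"], rel=1e-6)
    lo = evaluate("four_part_logistic", p, 0.0)
    assert p["A"] < lo < p["B"]


def test_evaluate_rejects_bad_domain_and_negative_time():
    with pytest.raises(ValueError, match="b3"):
        evaluate("gompertz", {"Asymp": 100, "b2": 4, "b3": 1.2}, 5.0)
    with pytest.raises(ValueError, match="non-negative"):
        evaluate("logistic", PARAMS["logistic"], -1.0)
    with pytest.raises(ValueError, match="unknown growth model"):
        evaluate("exponential", {}, 1.0)


@pytest.mark.parametrize("name", list(MODEL_REGISTRY))
def test_closed_form_derivative_matches_numeric(name):
    p = PARAMS[name]
    t = np.linspace(0.5, 149.5, 40)
    h = 1e-5
    numeric = (evaluate(name, p, t + h) - evaluate(name, p, t - h)) / (2 * h)
    closed = derivative(name, p, t)
    assert np.allclose(closed, numeric, rtol=1e-6, atol=1e-8)


def _series(name, params, n_plants=20, days=(7, 28, 49, 70, 91, 112, 133, 150),
            noise=0.0, seed=0, asymp_jitter=0.0):
    spec = get_model(name)
    rng = np.random.default_rng(seed)
    rows = []
    days = np.asarray(days, dtype=float)
    scale = spec.scale_param
    for i in range(n_plants):
        p = dict(params)
        if asymp_jitter:
            p[scale] = p[scale] * rng.lognormal(0, asymp_jitter)
        y = evaluate(name, p, days) + rng.normal(0, noise, len(days))
        rows.append(
            pd.DataFrame(
                {"plant_id": f"P{i:03d}", "year": 2014, "day": days,
                 "height_cm": np.maximum(y, 0.0)}
            )
        )
    return pd.concat(rows, ignore_index=True)


@pytest.mark.parametrize("name", ["gompertz", "logistic"])
def test_zero_noise_recovery(name):
    h = _series(name, PARAMS[name], n_plants=10, asymp_jitter=1e-6)
    fit = fit_growth_model(h, name)
    for p, true in PARAMS[name].items():
        assert fit.params[p] == pytest.approx(true, rel=1e-4)


def test_noisy_gompertz_recovery_within_three_se():
    h = _series("gompertz", PARAMS["gompertz"], n_plants=120, noise=5.0,
                asymp_jitter=0.15, seed=1)
    fit = fit_growth_model(h, "gompertz")
    se = max(fit.se["Asymp"], 1e-6)
    assert abs(fit.params["Asymp"] - 121.69) < 3 * max(se, 3.18)


def test_all_constant_series_is_degenerate_error():
    h = pd.DataFrame(
        {"plant_id": np.repeat(["a", "b"], 4), "year": 2014,
         "day": [1, 2, 3, 4] * 2, "height_cm": 50.0}
    )
    with pytest.warns(DegenerateSeriesWarning):
        with pytest.raises(ValueError, match="non-degenerate"):
            fit_growth_model(h, "gompertz")


def test_too_few_timepoints_error():
    h = pd.DataFrame(
        {"plant_id": ["a", "a"], "year": 2014, "day": [1.0, 2.0],
         "height_cm": [1.0, 2.0]}
    )
    with pytest.raises(ValueError, match="fewer than 3"):
        fit_growth_model(h, "logistic")


def test_covariate_structure_requires_plants_metadata():
    h = _series("gompertz", PARAMS["gompertz"], n_plants=6)
    with pytest.raises(ValueError, match="plants metadata"):
        fit_growth_model(h, "gompertz", covariate_structure="breeding")
    with pytest.raises(ValueError, match="covariate_structure"):
        fit_growth_model(h, "gompertz", covariate_structure="bogus")


def test_breeding_covariate_recovers_group_asymptotes():
    rng = np.random.default_rng(4)
    rows, meta = [], []
    days = np.array([7, 28, 49, 70, 91, 112, 133, 150], dtype=float)
    for i in range(80):
        breeding = "selfed" if i % 2 else "outcrossed"
        a = (110.0 if breeding == "selfed" else 133.0) * rng.lognormal(0, 0.1)
        y = a * np.exp(-4.28 * 0.97**days) + rng.normal(0, 5, len(days))
        rows.append(pd.DataFrame(
            {"plant_id": f"P{i}", "year": 2014, "day": days,
             "height_cm": np.maximum(y, 0)}))
        meta.append({"plant_id": f"P{i}", "breeding": breeding,
                     "competition": "none", "family_id": f"F{i % 10}"})
    fit = fit_growth_model(
        pd.concat(rows, ignore_index=True), "gompertz",
        covariate_structure="breeding", plants=pd.DataFrame(meta),
    )
    gp = fit.group_params.set_index("level")["estimate"]
    assert gp["selfed"] == pytest.approx(110.0, rel=0.05)
    assert gp["outcrossed"] == pytest.approx(133.0, rel=0.05)


def test_select_model_prefers_generating_model_single_replicate():
    h = _series("gompertz", PARAMS["gompertz"], n_plants=100, noise=5.0,
                asymp_jitter=0.15, seed=2)
    best, table = select_model(h)
    assert best.name == "gompertz"
    assert set(table["model"]) == set(MODEL_REGISTRY)
    assert np.isfinite(table["aicc"]).all()


def test_select_model_tie_breaks_by_order():
    h = _series("logistic", PARAMS["logistic"], n_plants=10, noise=1.0,
                asymp_jitter=0.05, seed=3)
    best, table = select_model(h, candidates=["logistic", "logistic"])
    assert best.name == "logistic"
    assert table.attrs.get("tie", False)


def test_covariate_aic_never_worse_than_plain():
    """Adding the generating breeding covariate never worsens the model
    comparison criterion (the profiled likelihood absorbs treatment-level
    asymptote contrasts, so at worst it ties)."""
    h = _series("gompertz", PARAMS["gompertz"], n_plants=40, noise=5.0,
                asymp_jitter=0.15, seed=5)
    meta = pd.DataFrame(
        {"plant_id": [f"P{i:03d}" for i in range(40)],
         "breeding": ["selfed", "outcrossed"] * 20,
         "competition": "none",
         "family_id": [f"F{i % 8}" for i in range(40)]}
    )
    plain = fit_growth_model(h, "gompertz")
    withcov = fit_growth_model(
        h, "gompertz", covariate_structure="breeding", plants=meta
    )
    assert withcov.aic <= plain.aic + 1e-6
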