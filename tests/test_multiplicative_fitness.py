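"""Family-based and resampling lifetime-fitness estimators."""

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from lythrum.multiplicative_fitness import (
    ResamplingConfig,
    family_cumulative,
    family_fitness_table,
    resampling_fitness,
)
from lythrum.synthetic_data import Dataset

from conftest import make_dataset


def _deterministic_dataset(mass_s=2.0, mass_o=4.0, n_fam=6):
    """All plants germinate, survive and flower; masses are constants.

    Every family then has yearly fitness mass_s vs mass_o exactly, so both
    estimators must agree exactly on delta = 1 - mass_s / mass_o.
    """
    years = [2014, 2015, 2016, 2017]
    prows, trows = [], []
    for f in range(n_fam):
        fam = f"F{f}"
        for breeding, mass in (("selfed", mass_s), ("outcrossed", mass_o)):
            for j in range(3):
                pid = f"{fam}-{breeding}-{j}"
                prows.append(
                    {"plant_id": pid, "family_id": fam, "population": "P",
                     "morph": "L", "breeding": breeding, "role": "focal",
                     "competition": "none", "pot_id": f"{fam}-{j}",
                     "block": 0, "germinated": True,
                     "days_to_germination": 7.0, "seedling_survived": True}
                )
                for y in years:
                    trows.append(
                        {"plant_id": pid, "year": y, "alive": True,
                         "flowered": True, "flowering_day": 60.0,
                         "inflorescence_mass_g": mass,
                         "vegetative_mass_g": 1.0}
                    )
    return Dataset(
        plants=pd.DataFrame(prows),
        traits=pd.DataFrame(trows),
        heights=pd.DataFrame(columns=["plant_id", "year", "day", "height_cm"]),
    )


def test_estimators_agree_exactly_on_deterministic_components():
    ds = _deterministic_dataset(mass_s=2.0, mass_o=4.0)
    fam = family_cumulative(ds, n_boot=100, seed=0)
    assert fam.mean_delta == pytest.approx(0.5, abs=1e-12)
    for year, rp in fam.delta_by_year.items():
        assert rp.estimate == pytest.approx(0.5, abs=1e-12)
    res = resampling_fitness(
        ds, ResamplingConfig(n_seeds=50, n_runs=200, rng_seed=0),
        include_competition=False,
    )
    assert res.delta_by_year["cumulative"].estimate == pytest.approx(0.5, abs=1e-12)
    assert res.delta_by_year[2016].estimate == pytest.approx(0.5, abs=1e-12)


def test_component_ratio_propagates_multiplicatively():
    # germination ratio alone sets the yearly delta when all later
    # components are equal
    ds = _deterministic_dataset(mass_s=3.0, mass_o=3.0)
    # mark 1 of 5 extra selfed seeds as failed germination per family:
    # emulate family germination proportions 0.8 (selfed) vs 1.0
    extra = []
    for f in range(6):
        for j, breeding in enumerate(["selfed"] * 2 + ["outcrossed"] * 2):
            extra.append(
                {"plant_id": f"X{f}-{breeding}-{j}", "family_id": f"F{f}",
                 "population": "P", "morph": "L", "breeding": breeding,
                 "role": "seed", "competition": "", "pot_id": "", "block": -1,
                 "germinated": (breeding == "outcrossed" or j > 0),
                 "days_to_germination": np.nan, "seedling_survived": False}
            )
    ds = Dataset(
        plants=pd.concat([ds.plants, pd.DataFrame(extra)], ignore_index=True),
        traits=ds.traits, heights=ds.heights,
    )
    fam = family_fitness_table(ds)
    g = fam[fam["year"] == 2014].groupby("breeding")["germination"].mean()
    expected = 1 - g["selfed"] / g["outcrossed"]
    res = family_cumulative(ds, n_boot=50, seed=0)
    assert res.mean_delta == pytest.approx(expected, abs=1e-12)


def test_mortality_carry_forward_zeroes_later_years():
    ds = _deterministic_dataset()
    # kill everything in 2015: alive False that year, no records after
    t = ds.traits
    t.loc[t["year"] == 2015, ["alive", "flowered"]] = False
    t.loc[t["year"] == 2015, "inflorescence_mass_g"] = np.nan
    t = t[t["year"] <= 2015]
    ds = Dataset(ds.plants, t, ds.heights)
    tab = family_fitness_table(ds)
    later = tab[tab["year"].isin([2016, 2017])]
    assert (later["fitness"].fillna(0) == 0).all()
    # the resampling estimator refuses years whose risk pool is empty
    with pytest.raises(ValueError, match="empty empirical distribution"):
        resampling_fitness(
            ds, ResamplingConfig(n_seeds=10, n_runs=10, rng_seed=0),
            include_competition=False,
        )


def test_family_missing_one_treatment_excluded():
    ds = _deterministic_dataset()
    keep = ~(
        (ds.plants["family_id"] == "F0") & (ds.plants["breeding"] == "selfed")
    )
    plants = ds.plants[keep]
    traits = ds.traits[ds.traits["plant_id"].isin(plants["plant_id"])]
    with pytest.warns(UserWarning, match="F0"):
        res = family_cumulative(Dataset(plants, traits, ds.heights),
                                n_boot=50, seed=0)
    assert res.excluded_families == ["F0"]
    assert res.n_families == 5


def test_resampling_config_validation():
    with pytest.raises(ValueError, match="positive"):
        ResamplingConfig(n_seeds=0)
    with pytest.raises(ValueError, match="positive"):
        ResamplingConfig(n_runs=-1)


def test_null_calibration_cis_cover_zero(null_calib):
    ds = make_dataset(42, null_calib, heights=False)
    fam = family_cumulative(ds, n_boot=500, seed=0)
    rp = fam.delta_by_year["cumulative"]
    assert rp.ci_low <= 0.0 <= rp.ci_high
    res = resampling_fitness(
        ds, ResamplingConfig(n_seeds=246, n_runs=500, rng_seed=0),
        include_competition=False,
    )
    rr = res.delta_by_year["cumulative"]
    assert rr.ci_low <= 0.0 <= rr.ci_high


def test_default_calibration_deltas_within_reported_intervals(default_ds):
    fam = family_cumulative(default_ds, n_boot=500, seed=0)
    assert 0.28 <= fam.delta_by_year["cumulative"].estimate <= 0.69
    assert fam.se_delta > 0
    res = resampling_fitness(
        default_ds, ResamplingConfig(n_seeds=246, n_runs=1000, rng_seed=0),
    )
    assert 0.4 <= res.delta_by_year["cumulative"].estimate <= 0.8
    # no competition effects by default: competitive RP near zero
    for rp in res.competitive.values():
        assert abs(rp.estimate) < 0.35


def test_resampling_deterministic_given_seed(default_ds):
    cfg = ResamplingConfig(n_seeds=50, n_runs=100, rng_seed=9)
    a = resampling_fitness(default_ds, cfg, include_competition=False)
    b = resampling_fitness(default_ds, cfg, include_competition=False)
    assert a.delta_by_year["cumulative"] == b.delta_by_year["cumulative"]
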