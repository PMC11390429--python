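"""Lifetime (multiplicative) fitness estimators.

Per-season fitness of a group is the product

    germination x proportion surviving x proportion flowering x mean
    inflorescence mass of flowering plants

with germination sampled once (first season) and multiplying every later
season, and with mortality carried forward (a dead plant contributes
nothing in later seasons).  Cumulative reproductive success sums the
seasonal terms.

Two estimators of the inbreeding-depression index delta are provided:

* the family-based estimator: delta computed within each maternal family
  from family-mean fitness components, then averaged over families (a mean
  of ratios);
* the resampling estimator: a forward simulation of seed cohorts (default
  246 seeds per breeding treatment, 5000 runs) drawing each life-history
  component with replacement from the observed per-treatment-per-year
  values, with delta computed on run-mean fitness (a ratio of means).

The two agree exactly on deterministic (noise-free) components and may
diverge under family heterogeneity; the divergence direction is reported,
not assumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .metrics import (
    RelativePerformance,
    ZeroFitnessWarning,
    competitive_rp,
    relative_performance,
)
from .synthetic_data import Dataset, YEARS

__all__ = [
    "ResamplingConfig",
    "FamilyCumulativeResult",
    "ResamplingResult",
    "family_fitness_table",
    "family_cumulative",
    "resampling_fitness",
]


@dataclass(frozen=True)
class ResamplingConfig:
    """Cohort size and run count of the resampling estimator."""

    n_seeds: int = 246
    n_runs: int = 5000
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_seeds <= 0 or self.n_runs <= 0:
            raise ValueError("n_seeds and n_runs must be positive")


# ---------------------------------------------------------------------------
# status reconstruction
# ---------------------------------------------------------------------------

def _status_panel(ds: Dataset, years: Sequence[int]) -> pd.DataFrame:
    """Per focal plant and year: present / alive / flowered / mass.

    Dead plants have no trait records after the death year; this
    reconstructs their (dead) status so that survival proportions refer to
    the full non-discarded cohort.  Plants discarded from two-plant pots
    leave the risk set from the discard year on.
    """
    focal = ds.focal_plants()
    t = ds.traits[ds.traits["plant_id"].isin(focal["plant_id"])]
    wide_alive = t.pivot(index="plant_id", columns="year", values="alive")
    wide_flow = t.pivot(index="plant_id", columns="year", values="flowered")
    wide_mass = t.pivot(
        index="plant_id", columns="year", values="inflorescence_mass_g"
    )
    rows = []
    for pid in wide_alive.index:
        dead = False
        discarded = False
        for year in years:
            has_record = year in wide_alive.columns and pd.notna(
                wide_alive.at[pid, year]
            )
            if dead:
                present, alive, flowered, mass = True, False, False, np.nan
            elif not has_record:
                # no record and not dead yet: discarded from this year on
                discarded = True
                present, alive, flowered, mass = False, False, False, np.nan
            else:
                present = not discarded
                alive = bool(wide_alive.at[pid, year])
                flowered = bool(wide_flow.at[pid, year])
                mass = wide_mass.at[pid, year]
                if not alive:
                    dead = True
            rows.append(
                {
                    "plant_id": pid,
                    "year": year,
                    "present": present,
                    "alive": alive,
                    "flowered": flowered,
                    "mass": mass,
                }
            )
    panel = pd.DataFrame(rows)
    meta = focal.set_index("plant_id")
    panel["family_id"] = panel["plant_id"].map(meta["family_id"])
    panel["breeding"] = panel["plant_id"].map(meta["breeding"])
    panel["competition"] = panel["plant_id"].map(meta["competition"])
    return panel


def _family_germination(ds: Dataset) -> pd.DataFrame:
    """Family x breeding germination proportion from the sowing trial."""
    g = (
        ds.plants.groupby(["family_id", "breeding"], observed=True)["germinated"]
        .mean()
        .rename("germination")
        .reset_index()
    )
    return g


# ---------------------------------------------------------------------------
# family-based estimator
# ---------------------------------------------------------------------------

def family_fitness_table(ds: Dataset, years: Sequence[int] = YEARS) -> pd.DataFrame:
    """Per family x breeding x year multiplicative fitness components.

    Columns: germination, p_alive (proportion of the family's focal cohort
    alive), p_flower (proportion of alive plants flowering), mean_mass
    (mean inflorescence mass of flowering plants), fitness (the product),
    plus a ``cumulative`` row summing the yearly fitness.
    """
    panel = _status_panel(ds, years)
    germ = _family_germination(ds).set_index(["family_id", "breeding"])

    rows = []
    for (fam, breeding), sub in panel.groupby(["family_id", "breeding"]):
        g = float(germ.loc[(fam, breeding), "germination"])
        cum = 0.0
        for year in years:
            ysub = sub[sub["year"] == year]
            cohort = ysub[ysub["present"]]
            if len(cohort) == 0:
                rows.append(
                    {
                        "family_id": fam, "breeding": breeding, "year": year,
                        "germination": g, "p_alive": np.nan,
                        "p_flower": np.nan, "mean_mass": np.nan,
                        "fitness": np.nan, "n": 0,
                    }
                )
                continue
            p_alive = cohort["alive"].mean()
            alive = cohort[cohort["alive"]]
            p_flower = alive["flowered"].mean() if len(alive) else 0.0
            flowering = alive[alive["flowered"]]
            mean_mass = flowering["mass"].mean() if len(flowering) else 0.0
            fitness = g * p_alive * p_flower * mean_mass
            cum += fitness
            rows.append(
                {
                    "family_id": fam, "breeding": breeding, "year": year,
                    "germination": g, "p_alive": p_alive,
                    "p_flower": p_flower, "mean_mass": mean_mass,
                    "fitness": fitness, "n": len(cohort),
                }
            )
        rows.append(
            {
                "family_id": fam, "breeding": breeding, "year": "cumulative",
                "germination": g, "p_alive": np.nan, "p_flower": np.nan,
                "mean_mass": np.nan, "fitness": cum, "n": len(sub["plant_id"].unique()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class FamilyCumulativeResult:
    """Family-based multiplicative inbreeding depression."""

    table: pd.DataFrame                    # per family x year fitness + delta
    delta_by_year: dict[object, RelativePerformance]
    mean_delta: float                      # cumulative, mean over families
    se_delta: float
    n_families: int
    excluded_families: list[str]


def _family_deltas(fit_table: pd.DataFrame, year) -> pd.Series:
    """Per-family delta for one year label (or 'cumulative')."""
    sub = fit_table[fit_table["year"] == year]
    wide = sub.pivot(index="family_id", columns="breeding", values="fitness")
    deltas = {}
    for fam, row in wide.iterrows():
        ws, wo = row.get("selfed", np.nan), row.get("outcrossed", np.nan)
        if pd.isna(ws) or pd.isna(wo):
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ZeroFitnessWarning)
            deltas[fam] = relative_performance(ws, wo)
    return pd.Series(deltas, name=f"delta_{year}")


def family_cumulative(
    ds: Dataset,
    years: Sequence[int] = YEARS,
    *,
    n_boot: int = 2000,
    seed: int | None = 0,
) -> FamilyCumulativeResult:
    """Family-based cumulative reproductive success and its delta.

    Per family and breeding treatment, yearly fitness terms are summed
    into cumulative reproductive success; delta is computed within each
    family with the symmetric sign rule and averaged over families.  The
    SE is the standard error of the family-mean deltas and the 95% CI is a
    family-resampling percentile bootstrap.
    """
    table = family_fitness_table(ds, years)
    counts = table.groupby(["family_id", "breeding"]).size().unstack()
    missing = counts.index[counts.isna().any(axis=1)].tolist() if counts.isna().any().any() else []
    if missing:
        warnings.warn(
            f"families missing one breeding treatment excluded: {missing}",
            stacklevel=2,
        )
        table = table[~table["family_id"].isin(missing)]
    n_fam = table["family_id"].nunique()
    if n_fam < 5:
        raise ValueError(
            f"family estimator requires >= 5 complete families, got {n_fam}"
        )

    rng = np.random.default_rng(seed)
    delta_by_year: dict[object, RelativePerformance] = {}
    for year in list(years) + ["cumulative"]:
        deltas = _family_deltas(table, year)
        point = float(deltas.mean())
        fams = deltas.index.to_numpy()
        boots = np.empty(n_boot)
        for b in range(n_boot):
            pick = rng.choice(fams, size=len(fams), replace=True)
            boots[b] = deltas.loc[pick].mean()
        lo, hi = np.percentile(boots, [2.5, 97.5])
        delta_by_year[year] = RelativePerformance(
            estimate=point,
            ci_low=float(lo),
            ci_high=float(hi),
            n_boot=n_boot,
            trait="multiplicative_fitness",
            year=year,
        )
    cum = _family_deltas(table, "cumulative")
    return FamilyCumulativeResult(
        table=table,
        delta_by_year=delta_by_year,
        mean_delta=float(cum.mean()),
        se_delta=float(cum.std(ddof=1) / np.sqrt(len(cum))),
        n_families=n_fam,
        excluded_families=missing,
    )


# ---------------------------------------------------------------------------
# resampling estimator
# ---------------------------------------------------------------------------

def _observed_pools(
    ds: Dataset, group_col: str, years: Sequence[int]
) -> dict[str, dict]:
    """Empirical per-group pools for germination, survival, flowering, mass.

    Survival pools for a year hold the alive/dead outcome of plants at
    risk (alive the previous year, still in the experiment); flowering
    pools hold outcomes of alive plants; mass pools hold the observed
    masses of flowering plants.
    """
    panel = _status_panel(ds, years)
    pools: dict[str, dict] = {}
    if group_col == "breeding":
        groups = ("selfed", "outcrossed")
        germ_src = ds.plants
    else:
        groups = tuple(sorted(panel["competition"].unique()))
        focal = ds.focal_plants()
        germ_src = ds.plants.merge(
            focal[["plant_id", "competition"]].rename(
                columns={"competition": "_comp"}
            ),
            on="plant_id", how="inner",
        ).assign(competition=lambda d: d["_comp"])
    for grp in groups:
        if group_col == "breeding":
            germ = germ_src.loc[germ_src["breeding"] == grp, "germinated"]
        else:
            germ = germ_src.loc[germ_src["competition"] == grp, "germinated"]
        gpanel = panel[panel[group_col] == grp]
        year_pools = {}
        at_risk = None
        for i, year in enumerate(years):
            ysub = gpanel[gpanel["year"] == year].set_index("plant_id")
            cohort = ysub[ysub["present"]]
            if i == 0:
                risk = cohort
            else:
                prev = gpanel[gpanel["year"] == years[i - 1]]
                prev_alive = set(prev.loc[prev["alive"], "plant_id"])
                risk = cohort[cohort.index.isin(prev_alive)]
            surv = risk["alive"].to_numpy(dtype=float)
            alive = cohort[cohort["alive"]]
            flow = alive["flowered"].to_numpy(dtype=float)
            mass = alive.loc[alive["flowered"], "mass"].dropna().to_numpy(float)
            for name, pool in (("survival", surv), ("flowering", flow)):
                if len(pool) == 0:
                    raise ValueError(
                        f"empty empirical distribution for "
                        f"({grp}, {year}, {name})"
                    )
            if len(mass) == 0:
                raise ValueError(
                    f"empty empirical distribution for ({grp}, {year}, mass)"
                )
            year_pools[year] = {"survival": surv, "flowering": flow, "mass": mass}
        pools[grp] = {
            "germination": germ.to_numpy(dtype=float),
            "years": year_pools,
        }
    return pools


@dataclass
class ResamplingResult:
    """Output of the seed-cohort resampling estimator."""

    delta_by_year: dict[object, RelativePerformance]   # years + 'cumulative'
    competitive: dict[str, RelativePerformance]
    run_summary: pd.DataFrame      # per run x group mean fitness values
    config: ResamplingConfig


def _simulate_group(rng, pool, cfg: ResamplingConfig, years):
    """Forward-simulate all runs for one group.

    Returns (yearly_fitness, cum_output): yearly multiplicative fitness per
    run (n_runs, n_years) and run-mean cumulative output per seed.
    """
    n_runs, n_seeds = cfg.n_runs, cfg.n_seeds
    # resampling a 0/1 indicator pool with replacement is a Bernoulli draw
    # at the pool mean; drawn that way for speed
    germ = rng.random((n_runs, n_seeds)) < pool["germination"].mean()
    alive = germ.copy()
    cum_output = np.zeros((n_runs, n_seeds))
    yearly = np.zeros((n_runs, len(years)))
    p_germ = germ.mean(axis=1)
    for j, year in enumerate(years):
        ypool = pool["years"][year]
        surv_draw = rng.random((n_runs, n_seeds)) < ypool["survival"].mean()
        alive &= surv_draw
        flow_draw = rng.random((n_runs, n_seeds)) < ypool["flowering"].mean()
        flowering = alive & flow_draw
        mass_draw = ypool["mass"][
            rng.integers(0, len(ypool["mass"]), size=(n_runs, n_seeds))
        ]
        mass = np.where(flowering, mass_draw, 0.0)
        cum_output += mass
        n_germ = np.maximum(germ.sum(axis=1), 1)
        n_alive = alive.sum(axis=1)
        p_surv = alive.sum(axis=1) / n_germ
        p_flow = np.divide(
            flowering.sum(axis=1), np.maximum(n_alive, 1), dtype=float
        )
        with np.errstate(invalid="ignore"):
            mean_mass = np.where(
                flowering.sum(axis=1) > 0,
                mass.sum(axis=1) / np.maximum(flowering.sum(axis=1), 1),
                0.0,
            )
        yearly[:, j] = p_germ * p_surv * p_flow * mean_mass
    return yearly, cum_output.mean(axis=1)


def _delta_from_runs(w_s_runs, w_o_runs, trait, year) -> RelativePerformance:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ZeroFitnessWarning)
        point = relative_performance(
            float(np.mean(w_s_runs)), float(np.mean(w_o_runs))
        )
        per_run = np.array(
            [
                relative_performance(ws, wo)
                for ws, wo in zip(w_s_runs, w_o_runs)
            ]
        )
    lo, hi = np.percentile(per_run, [2.5, 97.5])
    return RelativePerformance(
        estimate=point,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=len(per_run),
        trait=trait,
        year=year,
    )


def resampling_fitness(
    ds: Dataset,
    config: ResamplingConfig | None = None,
    years: Sequence[int] = YEARS,
    *,
    include_competition: bool = True,
) -> ResamplingResult:
    """Seed-cohort resampling estimator of multiplicative fitness.

    Each run simulates ``n_seeds`` seeds per breeding treatment walking
    germination -> (per year) survival -> flowering -> mass, every
    component drawn with replacement from the observed per-treatment
    values of that year.  Mortality carries forward.  Delta point
    estimates apply the relative-performance index to across-run mean
    fitness; CIs are 2.5/97.5 percentiles of the per-run delta values.
    """
    config = config or ResamplingConfig()
    rng = np.random.default_rng(config.rng_seed)

    pools = _observed_pools(ds, "breeding", years)
    yearly_s, cum_s = _simulate_group(rng, pools["selfed"], config, years)
    yearly_o, cum_o = _simulate_group(rng, pools["outcrossed"], config, years)

    delta_by_year: dict[object, RelativePerformance] = {}
    for j, year in enumerate(years):
        delta_by_year[year] = _delta_from_runs(
            yearly_s[:, j], yearly_o[:, j], "multiplicative_fitness", year
        )
    delta_by_year["cumulative"] = _delta_from_runs(
        cum_s, cum_o, "cumulative_output", "cumulative"
    )

    competitive: dict[str, RelativePerformance] = {}
    run_rows = {
        "run": np.arange(config.n_runs),
        "cum_selfed": cum_s,
        "cum_outcrossed": cum_o,
    }
    if include_competition:
        cpools = _observed_pools(ds, "competition", years)
        cum = {}
        for grp in cpools:
            _, cum[grp] = _simulate_group(rng, cpools[grp], config, years)
        pairs = [
            ("none_vs_scomp", "selfed_competitor", "none"),
            ("none_vs_ocomp", "outcrossed_competitor", "none"),
            ("scomp_vs_ocomp", "outcrossed_competitor", "selfed_competitor"),
        ]
        for label, worse, better in pairs:
            if worse in cum and better in cum:
                competitive[label] = _delta_from_runs(
                    cum[worse], cum[better], "cumulative_output", label
                )
                run_rows[f"cum_{worse}"] = cum[worse]
                run_rows.setdefault(f"cum_{better}", cum[better])
    return ResamplingResult(
        delta_by_year=delta_by_year,
        competitive=competitive,
        run_summary=pd.DataFrame(run_rows),
        config=config,
    )
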