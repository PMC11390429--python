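"""Per-year trait summaries and family-stratified permutation tests.

End-of-season fitness correlates are germination, days to germination,
survival, flowering, flowering day (days since May 11) and inflorescence
mass.  Group summaries are family-weighted (mean over maternal families of
within-family means) with family-bootstrap percentile CIs; inflorescence
mass in the field seasons and flowering day are summarised on the log
scale and back-transformed for reporting.

Hypothesis tests are permutation tests that respect the experimental
blocking: breeding labels are exchangeable within a maternal family
(breeding was assigned within family), competition labels are
exchangeable across pots within a spatial block, and the interaction is
tested by permuting breeding within family-by-competition strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import RelativePerformance, ZeroFitnessWarning, bootstrap_rp, relative_performance
from .synthetic_data import BREEDING, COMPETITION, Dataset, FIELD_YEARS, YEARS

__all__ = [
    "TestResult",
    "trait_values",
    "summarize_traits",
    "permutation_test",
    "germination_endpoints",
]

ENDPOINT_TRAITS = ("survival", "flowered", "flowering_day", "inflorescence_mass")


@dataclass(frozen=True)
class TestResult:
    """A permutation test of one factor on one trait-year."""

    trait: str
    year: int | str | None
    factor: str
    statistic: float
    p_value: float
    n_perm: int


def trait_values(ds: Dataset, trait: str, year: int | None = None) -> pd.DataFrame:
    """Per-focal-plant values of one trait with design metadata.

    Log transforms: ``flowering_day`` is returned as log(days) and
    ``inflorescence_mass`` as log(mass) for field seasons, matching the
    analysis scale; ``days_to_germination`` as log(days + 1).
    """
    focal = ds.focal_plants()
    meta_cols = ["plant_id", "family_id", "breeding", "competition", "block"]
    if trait in ("germination", "days_to_germination", "seedling_survival"):
        src = ds.plants.copy()
        if trait == "germination":
            src["value"] = src["germinated"].astype(float)
        elif trait == "days_to_germination":
            src = src[src["germinated"]]
            src["value"] = np.log(src["days_to_germination"] + 1.0)
        else:
            src = src[src["germinated"]]
            src["value"] = src["seedling_survived"].astype(float)
        return src[["plant_id", "family_id", "breeding", "value"]].dropna(
            subset=["value"]
        )

    if year is None:
        raise ValueError(f"trait {trait!r} requires a year")
    t = ds.traits[ds.traits["year"] == year].merge(
        focal[meta_cols], on="plant_id", how="inner"
    )
    if trait == "survival":
        t["value"] = t["alive"].astype(float)
    elif trait == "flowered":
        t = t[t["alive"]]
        t["value"] = t["flowered"].astype(float)
    elif trait == "flowering_day":
        t = t[t["flowered"]]
        t["value"] = np.log(t["flowering_day"])
    elif trait == "inflorescence_mass":
        t = t[t["flowered"]]
        if year in FIELD_YEARS:
            t["value"] = np.log(t["inflorescence_mass_g"])
        else:
            t["value"] = t["inflorescence_mass_g"]
    else:
        raise ValueError(f"unknown trait {trait!r}")
    return t[meta_cols + ["value"]].dropna(subset=["value"])


def _family_weighted_mean(df: pd.DataFrame) -> float:
    return float(df.groupby("family_id")["value"].mean().mean())


def summarize_traits(
    ds: Dataset,
    traits=ENDPOINT_TRAITS,
    years=YEARS,
    *,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Family-weighted per-treatment-cell trait means with bootstrap CIs.

    One row per trait x year x (breeding x competition) cell.  Log-scale
    traits are back-transformed for reporting (geometric means).  Empty
    cells yield an NA row with a warning.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for trait in traits:
        for year in years:
            vals = trait_values(ds, trait, year)
            log_scale = (
                trait == "flowering_day"
                or (trait == "inflorescence_mass" and year in FIELD_YEARS)
            )
            for breeding in BREEDING:
                for comp in COMPETITION:
                    cell = vals[
                        (vals["breeding"] == breeding)
                        & (vals["competition"] == comp)
                    ]
                    if len(cell) == 0:
                        warnings.warn(
                            f"empty cell {trait}/{year}/{breeding}/{comp}",
                            stacklevel=2,
                        )
                        rows.append(
                            {
                                "trait": trait, "year": year,
                                "breeding": breeding, "competition": comp,
                                "mean": np.nan, "ci_low": np.nan,
                                "ci_high": np.nan, "n": 0,
                            }
                        )
                        continue
                    fam_means = cell.groupby("family_id")["value"].mean()
                    point = float(fam_means.mean())
                    fams = fam_means.to_numpy()
                    idx = rng.integers(0, len(fams), size=(n_boot, len(fams)))
                    boots = fams[idx].mean(axis=1)
                    lo, hi = np.percentile(boots, [2.5, 97.5])
                    if log_scale:
                        point, lo, hi = np.exp([point, lo, hi])
                    rows.append(
                        {
                            "trait": trait, "year": year,
                            "breeding": breeding, "competition": comp,
                            "mean": point, "ci_low": float(lo),
                            "ci_high": float(hi), "n": len(cell),
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

def _breeding_stat_perms(vals: pd.DataFrame, n_perm: int, rng) -> tuple[float, np.ndarray]:
    """Observed and permuted difference of family-mean group means.

    Breeding labels are permuted independently within each family;
    vectorised across permutations.
    """
    fam_codes, _ = pd.factorize(vals["family_id"])
    v = vals["value"].to_numpy(dtype=float)
    is_self = (vals["breeding"] == "selfed").to_numpy()
    n = len(v)
    n_fam = fam_codes.max() + 1

    def family_diffs(selfed_mask: np.ndarray) -> np.ndarray:
        """Per-family X-minus-S differences for (n_perm, n) mask."""
        diffs = np.zeros((selfed_mask.shape[0], n_fam))
        valid = np.ones((selfed_mask.shape[0], n_fam), dtype=bool)
        for f in range(n_fam):
            cols = np.flatnonzero(fam_codes == f)
            sub_mask = selfed_mask[:, cols]
            sub_v = v[cols]
            n_s = sub_mask.sum(axis=1)
            n_x = len(cols) - n_s
            s_sum = sub_mask @ sub_v
            x_sum = sub_v.sum() - s_sum
            ok = (n_s > 0) & (n_x > 0)
            with np.errstate(invalid="ignore", divide="ignore"):
                d = x_sum / np.maximum(n_x, 1) - s_sum / np.maximum(n_s, 1)
            diffs[:, f] = np.where(ok, d, np.nan)
            valid[:, f] = ok
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(diffs, axis=1)

    obs = float(family_diffs(is_self[None, :])[0])

    perm_mask = np.empty((n_perm, n), dtype=bool)
    for f in range(fam_codes.max() + 1):
        cols = np.flatnonzero(fam_codes == f)
        base = is_self[cols]
        keys = rng.random((n_perm, len(cols)))
        order = np.argsort(keys, axis=1)
        perm_mask[:, cols] = base[order]
    perm = family_diffs(perm_mask)
    return obs, perm


def _between_group_ss(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    grand = values.mean()
    ss = 0.0
    for g in range(n_groups):
        m = codes == g
        if m.any():
            ss += m.sum() * (values[m].mean() - grand) ** 2
    return float(ss)


def _competition_stat_perms(vals, n_perm, rng):
    """Between-competition-group SS; labels permuted across pots in block."""
    comp_codes, _ = pd.factorize(vals["competition"])
    v = vals["value"].to_numpy(dtype=float)
    n_groups = comp_codes.max() + 1
    obs = _between_group_ss(v, comp_codes, n_groups)

    blocks = vals["block"].to_numpy()
    perm = np.empty(n_perm)
    for b in range(n_perm):
        new_codes = comp_codes.copy()
        for blk in np.unique(blocks):
            cols = np.flatnonzero(blocks == blk)
            new_codes[cols] = comp_codes[cols][rng.permutation(len(cols))]
        perm[b] = _between_group_ss(v, new_codes, n_groups)
    return obs, perm


def _interaction_stat_perms(vals, n_perm, rng):
    """Interaction SS; breeding permuted within family x competition strata."""
    v = vals["value"].to_numpy(dtype=float)
    breeding = (vals["breeding"] == "selfed").to_numpy()
    comp_codes, _ = pd.factorize(vals["competition"])
    strata, _ = pd.factorize(
        vals["family_id"].astype(str) + "/" + vals["competition"].astype(str)
    )

    def inter_ss(is_self):
        grand = v.mean()
        ss = 0.0
        for c in np.unique(comp_codes):
            for s in (False, True):
                m = (comp_codes == c) & (is_self == s)
                if not m.any():
                    continue
                cell = v[m].mean()
                row = v[is_self == s].mean()
                col = v[comp_codes == c].mean()
                ss += m.sum() * (cell - row - col + grand) ** 2
        return float(ss)

    obs = inter_ss(breeding)
    perm = np.empty(n_perm)
    for b in range(n_perm):
        new = breeding.copy()
        for st in np.unique(strata):
            cols = np.flatnonzero(strata == st)
            new[cols] = breeding[cols][rng.permutation(len(cols))]
        perm[b] = inter_ss(new)
    return obs, perm


def permutation_test(
    ds: Dataset,
    trait: str,
    year: int | None,
    factor: str = "breeding",
    *,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = 0,
) -> TestResult:
    """Family/block-stratified permutation test of one design factor.

    The breeding statistic is the difference of family-mean group means
    (two-sided); competition and interaction use between-group /
    interaction sums of squares.  ``p = (1 + #{|stat*| >= |stat|}) /
    (1 + n_perm)``.
    """
    if n_perm < 999:
        raise ValueError("n_perm must be at least 999")
    vals = trait_values(ds, trait, year)
    rng = np.random.default_rng(seed)
    if factor == "breeding":
        if vals["breeding"].nunique() < 2:
            raise ValueError("breeding factor is constant")
        obs, perm = _breeding_stat_perms(vals, n_perm, rng)
        exceed = np.sum(np.abs(perm) >= abs(obs) - 1e-12)
    elif factor == "competition":
        if vals["competition"].nunique() < 2:
            raise ValueError("competition factor is constant")
        obs, perm = _competition_stat_perms(vals, n_perm, rng)
        exceed = np.sum(perm >= obs - 1e-12)
    elif factor == "interaction":
        if vals["breeding"].nunique() < 2 or vals["competition"].nunique() < 2:
            raise ValueError("interaction requires both factors to vary")
        obs, perm = _interaction_stat_perms(vals, n_perm, rng)
        exceed = np.sum(perm >= obs - 1e-12)
    else:
        raise ValueError(f"unknown factor {factor!r}")
    p = (1.0 + float(exceed)) / (1.0 + n_perm)
    return TestResult(
        trait=trait, year=year, factor=factor,
        statistic=float(obs), p_value=float(p), n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# germination endpoints
# ---------------------------------------------------------------------------

def _delta_statistic(trait: str):
    """Family-weighted delta statistic for the bootstrap machinery."""

    def stat(df: pd.DataFrame) -> float:
        means = (
            df.groupby(["breeding", "family_id"], observed=True)["value"]
            .mean()
            .groupby("breeding")
            .mean()
        )
        return relative_performance(
            means.get("selfed", np.nan), means.get("outcrossed", np.nan)
        )

    return stat


def germination_endpoints(
    ds: Dataset,
    *,
    n_boot: int = 2000,
    n_perm: int = 999,
    seed: int | None = 0,
) -> dict[str, dict]:
    """Delta estimates and breeding tests for the germination-trial traits.

    Covers germination frequency, days to germination (log(days + 1)
    scale) and survival of germinated seedlings.  Each entry carries a
    family-bootstrap :class:`RelativePerformance` and a within-family
    permutation :class:`TestResult`.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for trait in ("germination", "days_to_germination", "seedling_survival"):
        vals = trait_values(ds, trait)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ZeroFitnessWarning)
            rp = bootstrap_rp(
                vals,
                _delta_statistic(trait),
                n_boot=n_boot,
                seed=rng,
                trait=trait,
            )
        test = permutation_test(
            ds, trait, None, "breeding", n_perm=n_perm, seed=rng
        )
        out[trait] = {"delta": rp, "test": test}
    return out
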