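"""Asymptotic growth curves, per-plant fitting and AIC model selection.

Four classical height-growth models are supported, all parameterised on
days ``t`` since the common spring reference date (May 11):

* monomolecular:       ``y = Asymp + (R0 - Asymp) * exp(-exp(lrc) * t)``
* logistic:            ``y = Asymp / (1 + exp((xmid - t) / scal))``
* gompertz:            ``y = Asymp * exp(-b2 * b3**t)``
* four_part_logistic:  ``y = A + (B - A) / (1 + exp((xmid - t) / scal))``

``Asymp`` (or ``B``) is the plateau height in cm, reached late in the
season; the remaining parameters control the height at transplant and the
timing/steepness of growth.

Fitting is a two-stage estimator for repeated measures: stage 1 fits each
plant by nonlinear least squares, stage 2 aggregates the per-plant
parameter estimates with design-based precision weights (per treatment
level when a covariate structure is requested, with maternal family as a
blocking factor in the reported standard errors).  The empirical
between-plant parameter covariance, scaled to the mean, stands in for the
random-effect covariance of a full mixed model.

Model comparison uses a profiled Gaussian likelihood in which every plant
carries one free asymptote-like scale (profiled in closed form) while the
shape parameters are shared, mirroring the per-plant grouping of a
nonlinear mixed model and giving all candidate curves identical per-plant
flexibility; selection is by small-sample corrected AIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares
from scipy.special import expit

__all__ = [
    "GrowthModelSpec",
    "GrowthFit",
    "MODEL_REGISTRY",
    "get_model",
    "evaluate",
    "derivative",
    "fit_growth_model",
    "select_model",
    "DegenerateSeriesWarning",
]


class DegenerateSeriesWarning(UserWarning):
    """A constant (flat) height series was excluded from fitting."""


# ---------------------------------------------------------------------------
# model definitions
# ---------------------------------------------------------------------------

def _mono_f(t, Asymp, R0, lrc):
    return Asymp + (R0 - Asymp) * np.exp(-np.exp(lrc) * t)


def _mono_d(t, Asymp, R0, lrc):
    k = np.exp(lrc)
    return (Asymp - R0) * k * np.exp(-k * t)


def _mono_jac(t, Asymp, R0, lrc):
    e = np.exp(-np.exp(lrc) * t)
    return np.stack(
        [1.0 - e, e, (R0 - Asymp) * e * (-t * np.exp(lrc))], axis=-1
    )


def _logi_f(t, Asymp, xmid, scal):
    # numerically stable sigmoid parameterisation
    return Asymp * expit((t - xmid) / scal)


def _logi_d(t, Asymp, xmid, scal):
    s = expit((t - xmid) / scal)
    return Asymp / scal * s * (1.0 - s)


def _logi_jac(t, Asymp, xmid, scal):
    s = expit((t - xmid) / scal)
    sd = s * (1.0 - s)
    return np.stack(
        [
            s,
            -Asymp * sd / scal,
            Asymp * sd * (xmid - t) / scal**2,
        ],
        axis=-1,
    )


def _gomp_f(t, Asymp, b2, b3):
    return Asymp * np.exp(-b2 * b3**t)


def _gomp_d(t, Asymp, b2, b3):
    return -Asymp * b2 * np.log(b3) * b3**t * np.exp(-b2 * b3**t)


def _gomp_jac(t, Asymp, b2, b3):
    p = b3**t
    e = np.exp(-b2 * p)
    return np.stack(
        [e, -Asymp * p * e, -Asymp * b2 * t * b3 ** (t - 1.0) * e], axis=-1
    )


def _four_f(t, A, B, xmid, scal):
    return A + (B - A) * expit((t - xmid) / scal)


def _four_d(t, A, B, xmid, scal):
    s = expit((t - xmid) / scal)
    return (B - A) / scal * s * (1.0 - s)


def _four_jac(t, A, B, xmid, scal):
    s = expit((t - xmid) / scal)
    sd = s * (1.0 - s)
    return np.stack(
        [
            1.0 - s,
            s,
            -(B - A) * sd / scal,
            (B - A) * sd * (xmid - t) / scal**2,
        ],
        axis=-1,
    )


def _init_mono(t, y):
    asymp = 1.05 * np.max(y)
    return [asymp, max(float(np.min(y)), 0.0), np.log(0.05)]


def _half_time(t, y, target):
    """First time at which y crosses target (linear interpolation)."""
    above = y >= target
    if not above.any():
        return float(np.median(t))
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    t0, t1 = t[i - 1], t[i]
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return float(t1)
    return float(t0 + (target - y0) * (t1 - t0) / (y1 - y0))


def _init_logi(t, y):
    asymp = 1.05 * np.max(y)
    xmid = _half_time(t, y, asymp / 2.0)
    scal = max((np.max(t) - np.min(t)) / 4.0, 1.0)
    return [asymp, xmid, scal]


def _init_gomp(t, y):
    asymp = 1.05 * np.max(y)
    b3 = 0.95
    y0 = max(float(y[np.argmin(t)]), 0.1)
    frac = min(max(y0 / asymp, 1e-3), 0.99)
    b2 = -np.log(frac) / b3 ** float(np.min(t))
    return [asymp, min(b2, 50.0), b3]


def _init_four(t, y):
    asymp = 1.05 * np.max(y)
    a = max(float(np.min(y)), 0.0)
    xmid = _half_time(t, y, (asymp + a) / 2.0)
    scal = max((np.max(t) - np.min(t)) / 4.0, 1.0)
    return [a, asymp, xmid, scal]


@dataclass(frozen=True)
class GrowthModelSpec:
    """A growth-curve family: closed forms plus fitting heuristics."""

    name: str
    params: tuple[str, ...]
    fn: Callable
    deriv: Callable
    jac: Callable
    init: Callable
    lower: tuple[float, ...]
    upper: tuple[float, ...]
    scale_param: str = "Asymp"   # the linear asymptote-like parameter

    @property
    def k(self) -> int:
        return len(self.params)

    def check_domain(self, values: Sequence[float]) -> None:
        for name, v, lo, hi in zip(self.params, values, self.lower, self.upper):
            if not np.isfinite(v) or v <= lo or v >= hi:
                raise ValueError(
                    f"{self.name}: parameter {name}={v} outside domain "
                    f"({lo}, {hi})"
                )

    def in_domain(self, values: np.ndarray) -> np.ndarray:
        """Vectorised domain mask for draws of shape (n, k)."""
        values = np.asarray(values, dtype=float)
        ok = np.isfinite(values).all(axis=-1)
        for j, (lo, hi) in enumerate(zip(self.lower, self.upper)):
            ok &= (values[..., j] > lo) & (values[..., j] < hi)
        return ok


_BIG = 1e6

# registry order is the deterministic tie-break order for model selection
MODEL_REGISTRY: dict[str, GrowthModelSpec] = {
    "monomolecular": GrowthModelSpec(
        "monomolecular", ("Asymp", "R0", "lrc"),
        _mono_f, _mono_d, _mono_jac, _init_mono,
        (0.0, -1e-9, -20.0), (_BIG, _BIG, 5.0),
    ),
    "logistic": GrowthModelSpec(
        "logistic", ("Asymp", "xmid", "scal"),
        _logi_f, _logi_d, _logi_jac, _init_logi,
        (0.0, -300.0, 0.1), (_BIG, 600.0, 300.0),
    ),
    "gompertz": GrowthModelSpec(
        "gompertz", ("Asymp", "b2", "b3"),
        _gomp_f, _gomp_d, _gomp_jac, _init_gomp,
        (0.0, 0.0, 0.0), (_BIG, 100.0, 1.0),
    ),
    "four_part_logistic": GrowthModelSpec(
        "four_part_logistic", ("A", "B", "xmid", "scal"),
        _four_f, _four_d, _four_jac, _init_four,
        (-1e-9, 0.0, -300.0, 0.1), (_BIG, _BIG, 600.0, 300.0),
        scale_param="B",
    ),
}


def get_model(name: str | GrowthModelSpec) -> GrowthModelSpec:
    if isinstance(name, GrowthModelSpec):
        return name
    try:
        return MODEL_REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown growth model {name!r}; choose from "
            f"{sorted(MODEL_REGISTRY)}"
        ) from None


def _params_vector(model: GrowthModelSpec, params) -> list[float]:
    if isinstance(params, Mapping):
        return [float(params[p]) for p in model.params]
    return [float(v) for v in params]


def evaluate(model, params, t):
    """Height (cm) of the growth curve at days ``t`` (vectorised)."""
    spec = get_model(model)
    vec = _params_vector(spec, params)
    spec.check_domain(vec)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    return spec.fn(t, *vec)


def derivative(model, params, t):
    """Instantaneous growth rate dy/dt (cm/day) at days ``t``."""
    spec = get_model(model)
    vec = _params_vector(spec, params)
    spec.check_domain(vec)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    return spec.deriv(t, *vec)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

COVARIATE_STRUCTURES = ("none", "breeding", "competition", "breeding_x_competition")


@dataclass
class GrowthFit:
    """Result of fitting one growth model to a cohort of height series."""

    model: GrowthModelSpec
    params: dict[str, float]
    se: dict[str, float]
    mean_cov: np.ndarray            # covariance of the population mean vector
    between_cov: np.ndarray         # between-plant parameter covariance
    loglik: float
    aic: float
    aicc: float
    n_obs: int
    n_plants: int
    n_converged: int
    sigma: float
    covariate_structure: str = "none"
    covariate_params: tuple[str, ...] = ()
    group_params: pd.DataFrame | None = None   # (param, level, estimate, se)
    group_mean_cov: dict[str, np.ndarray] = field(default_factory=dict)
    per_plant: pd.DataFrame | None = None
    messages: list[str] = field(default_factory=list)

    n_profiled: int = 0

    @property
    def k(self) -> int:
        """Parameter count of the AIC likelihood: per-plant asymptote
        scales, shared shape parameters, and the residual variance."""
        return self.n_profiled + (self.model.k - 1) + 1

    def params_vector(self) -> np.ndarray:
        return np.array([self.params[p] for p in self.model.params])

    def group_vector(self, level: str) -> np.ndarray:
        """Full parameter vector with covariate params at ``level``."""
        vec = self.params_vector().copy()
        if self.group_params is None:
            return vec
        sub = self.group_params[self.group_params["level"] == level]
        for _, row in sub.iterrows():
            j = self.model.params.index(row["param"])
            vec[j] = row["estimate"]
        return vec


def _fit_one_plant(spec: GrowthModelSpec, t, y):
    """Stage-1 NLS for one plant.  Returns (params, JtJinv_diag) or None."""
    p0 = spec.init(t, y)
    lo = np.array(spec.lower)
    hi = np.array(spec.upper)
    p0 = np.clip(p0, lo + 1e-6, hi - 1e-6)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                spec.fn, t, y, p0=p0, jac=spec.jac,
                bounds=(lo, hi), method="trf", maxfev=200 * (spec.k + 1),
            )
    except (RuntimeError, ValueError):
        return None
    if not spec.in_domain(popt[None, :])[0]:
        return None
    J = spec.jac(t, *popt)
    try:
        cov_unit = np.linalg.inv(J.T @ J + 1e-10 * np.eye(spec.k))
    except np.linalg.LinAlgError:
        return None
    resid = y - spec.fn(t, *popt)
    dof = max(len(t) - spec.k, 1)
    return popt, np.diag(cov_unit), float(resid @ resid), dof


def _level_column(plants: pd.DataFrame, structure: str) -> pd.Series:
    if structure == "breeding":
        return plants["breeding"].astype(str)
    if structure == "competition":
        return plants["competition"].astype(str)
    if structure == "breeding_x_competition":
        return plants["breeding"].astype(str) + ":" + plants["competition"].astype(str)
    raise ValueError(f"unknown covariate structure {structure!r}")


def fit_growth_model(
    heights: pd.DataFrame,
    model: str | GrowthModelSpec,
    covariate_structure: str = "none",
    plants: pd.DataFrame | None = None,
    covariate_params: Sequence[str] = ("Asymp",),
) -> GrowthFit:
    """Fit one growth model to a cohort of per-plant height series.

    Parameters
    ----------
    heights
        Long table with columns ``plant_id``, ``day`` and ``height_cm``
        for a single season.
    covariate_structure
        ``none`` fits a single population curve; ``breeding``,
        ``competition`` or ``breeding_x_competition`` additionally estimate
        treatment-level values of ``covariate_params`` (by default the
        asymptote).  Requires ``plants`` metadata with ``plant_id``,
        ``breeding``, ``competition`` and ``family_id`` columns.
    """
    spec = get_model(model)
    if covariate_structure not in COVARIATE_STRUCTURES:
        raise ValueError(
            f"covariate_structure must be one of {COVARIATE_STRUCTURES}"
        )
    if covariate_structure != "none" and plants is None:
        raise ValueError("plants metadata required for covariate structures")
    covariate_params = tuple(
        p for p in covariate_params if p in spec.params
    ) if covariate_structure != "none" else ()
    messages: list[str] = []

    counts = heights.groupby("plant_id")["day"].count()
    too_few = counts[counts < 3]
    if len(too_few):
        raise ValueError(
            f"plants with fewer than 3 timepoints: {sorted(too_few.index)[:10]}"
        )

    # stage 1: per-plant nonlinear least squares
    rows = []
    series: dict = {}
    rss_tot = 0.0
    dof_tot = 0
    n_degenerate = 0
    for pid, sub in heights.groupby("plant_id"):
        t = sub["day"].to_numpy(dtype=float)
        y = sub["height_cm"].to_numpy(dtype=float)
        if np.ptp(y) < 1e-9:
            n_degenerate += 1
            warnings.warn(
                f"constant height series for plant {pid!r} excluded",
                DegenerateSeriesWarning,
                stacklevel=2,
            )
            continue
        res = _fit_one_plant(spec, t, y)
        if res is None:
            rows.append({"plant_id": pid, "converged": False})
            continue
        popt, unit_var, rss, dof = res
        rss_tot += rss
        dof_tot += dof
        series[pid] = t
        row = {"plant_id": pid, "converged": True, "_rss": rss, "_dof": dof}
        row.update({p: v for p, v in zip(spec.params, popt)})
        rows.append(row)
    per_plant = pd.DataFrame(rows)
    n_plants = len(counts) - n_degenerate
    if n_plants == 0:
        raise ValueError(f"{spec.name}: no usable (non-degenerate) series")
    ok = per_plant[per_plant["converged"]] if len(per_plant) else per_plant
    n_converged = len(ok)
    if n_converged < 0.5 * n_plants or n_converged < 2:
        raise ValueError(
            f"{spec.name}: stage-1 fits converged for only {n_converged} of "
            f"{n_plants} plants"
        )

    sigma2_pool = rss_tot / max(dof_tot, 1)
    est = ok[list(spec.params)].to_numpy(dtype=float)
    # design-based per-plant variances: pooled residual variance times
    # (J'J)^-1 with the Jacobian evaluated at common (population-mean)
    # parameters, so a plant's weight reflects its measurement design only
    # and cannot correlate with its own estimate
    pop0 = est.mean(axis=0)
    unit = np.empty_like(est)
    eye = 1e-10 * np.eye(spec.k)
    for r, pid in enumerate(ok["plant_id"]):
        J = spec.jac(series[pid], *pop0)
        unit[r] = np.diag(np.linalg.inv(J.T @ J + eye))
    var = np.maximum(sigma2_pool * unit, 1e-12)
    w = 1.0 / var

    # stage 2: precision-weighted aggregation
    pop = np.sum(w * est, axis=0) / np.sum(w, axis=0)
    between_cov = np.cov(est, rowvar=False, ddof=1)
    between_cov = np.atleast_2d(between_cov)
    mean_cov = between_cov / n_converged
    se = {
        p: float(np.sqrt(max(mean_cov[j, j], 0.0)))
        for j, p in enumerate(spec.params)
    }
    params = {p: float(v) for p, v in zip(spec.params, pop)}

    group_params = None
    group_mean_cov: dict[str, np.ndarray] = {}
    level_of: pd.Series | None = None
    if covariate_structure != "none":
        meta = plants.set_index("plant_id")
        level_of = _level_column(meta, covariate_structure)
        ok = ok.assign(
            _level=ok["plant_id"].map(level_of),
            _family=ok["plant_id"].map(meta["family_id"]),
        )
        missing = ok["_level"].isna()
        if missing.any():
            raise ValueError(
                f"plants metadata missing for {int(missing.sum())} plants"
            )
        grows = []
        dropped = []
        for level, lsub in ok.groupby("_level"):
            lest = lsub[list(spec.params)].to_numpy(dtype=float)
            if len(lest) < 2:
                dropped.append(level)
                continue
            lw = w[(ok["_level"] == level).to_numpy()]
            lpop = np.sum(lw * lest, axis=0) / np.sum(lw, axis=0)
            # family-blocked SE: variance of family means within the level
            fam_means = (
                lsub.groupby("_family")[list(spec.params)].mean().to_numpy(float)
            )
            n_fam = len(fam_means)
            if n_fam > 1:
                lvl_cov = np.atleast_2d(np.cov(fam_means, rowvar=False, ddof=1)) / n_fam
            else:
                lvl_cov = np.atleast_2d(np.cov(lest, rowvar=False, ddof=1)) / len(lest)
            group_mean_cov[str(level)] = lvl_cov
            for j, p in enumerate(spec.params):
                if p in covariate_params:
                    grows.append(
                        {
                            "param": p,
                            "level": str(level),
                            "estimate": float(lpop[j]),
                            "se": float(np.sqrt(max(lvl_cov[j, j], 0.0))),
                            "n": int(len(lest)),
                        }
                    )
        if dropped:
            messages.append(
                f"covariate dropped for underpopulated levels: {dropped}"
            )
        if grows:
            group_params = pd.DataFrame(grows)
        else:
            messages.append(
                "covariate structure dropped entirely (convergence fallback)"
            )
            covariate_structure = "none"
            covariate_params = ()

    # stage 3: profiled random-asymptote likelihood for AIC
    loglik, aic, sigma, n_profiled = _profiled_loglik(spec, heights, params)
    k_lik = n_profiled + (spec.k - 1) + 1
    aicc = _aicc(aic, k_lik, len(heights))

    fit = GrowthFit(
        model=spec,
        params=params,
        se=se,
        mean_cov=mean_cov,
        between_cov=between_cov,
        loglik=loglik,
        aic=aic,
        aicc=aicc,
        n_obs=len(heights),
        n_plants=n_plants,
        n_converged=n_converged,
        sigma=sigma,
        covariate_structure=covariate_structure,
        covariate_params=tuple(covariate_params),
        group_params=group_params,
        group_mean_cov=group_mean_cov,
        per_plant=per_plant,
        messages=messages,
        n_profiled=n_profiled,
    )
    return fit


def _shape_decomposition(spec: GrowthModelSpec):
    """Split a model into y = c(t; phi) + a * u(t; phi).

    ``a`` is the plant-level asymptote-like scale (``Asymp`` or ``B``) and
    ``phi`` the shared shape parameters, enabling closed-form profiling of
    one scale per plant.
    """
    if spec.name == "monomolecular":
        def cu(t, phi):
            R0, lrc = phi
            e = np.exp(-np.exp(lrc) * t)
            return R0 * e, 1.0 - e
    elif spec.name == "logistic":
        def cu(t, phi):
            xmid, scal = phi
            return np.zeros_like(t), expit((t - xmid) / scal)
    elif spec.name == "gompertz":
        def cu(t, phi):
            b2, b3 = phi
            return np.zeros_like(t), np.exp(-b2 * b3**t)
    elif spec.name == "four_part_logistic":
        def cu(t, phi):
            A, xmid, scal = phi
            s = expit((t - xmid) / scal)
            return A * (1.0 - s), s
    else:  # pragma: no cover - registry is closed
        raise ValueError(spec.name)
    return cu


def _profiled_loglik(spec, heights, params):
    """Gaussian log-likelihood with per-plant asymptote scales.

    Each plant carries its own asymptote-like scale (profiled in closed
    form); the remaining shape parameters are shared across plants and
    optimised by least squares.  This mirrors the per-plant grouping of a
    mixed-effects growth model and puts all candidate models on the same
    per-plant flexibility (one free scale per plant), so their AICs are
    comparable.  Returns (loglik, aic, sigma, n_plants_used).
    """
    codes, _ = pd.factorize(heights["plant_id"])
    t = heights["day"].to_numpy(dtype=float)
    y = heights["height_cm"].to_numpy(dtype=float)
    # keep plants with >= 3 points and non-constant series
    n_per = np.bincount(codes)
    ymin = np.full(codes.max() + 1, np.inf)
    ymax = np.full(codes.max() + 1, -np.inf)
    np.minimum.at(ymin, codes, y)
    np.maximum.at(ymax, codes, y)
    keep_plant = (n_per >= 3) & ((ymax - ymin) > 1e-9)
    mask = keep_plant[codes]
    codes = pd.factorize(heights.loc[mask, "plant_id"])[0]
    t, y = t[mask], y[mask]
    n = len(y)
    n_plants = codes.max() + 1

    cu = _shape_decomposition(spec)
    shape_names = [p for p in spec.params if p != spec.scale_param]
    idx = [spec.params.index(p) for p in shape_names]
    phi0 = np.array([params[p] for p in shape_names], dtype=float)
    lo = np.array([spec.lower[j] for j in idx]) + 1e-9
    hi = np.array([spec.upper[j] for j in idx]) - 1e-9

    def residuals(phi):
        c, u = cu(t, phi)
        r = y - c
        su2 = np.bincount(codes, u * u, minlength=n_plants)
        sur = np.bincount(codes, u * r, minlength=n_plants)
        a = np.divide(sur, su2, out=np.zeros_like(sur), where=su2 > 1e-12)
        return r - a[codes] * u

    # second start from the data-driven init on the pooled series to
    # guard against local minima of the shape parameters
    alt = spec.init(t, y)
    phi_alt = np.array([alt[j] for j in idx], dtype=float)
    best_rvec = None
    for start in (phi0, phi_alt):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = least_squares(
                    residuals, np.clip(start, lo, hi), bounds=(lo, hi),
                    method="trf", max_nfev=200,
                )
            rvec = res.fun
        except ValueError:
            rvec = residuals(np.clip(start, lo, hi))
        if best_rvec is None or rvec @ rvec < best_rvec @ best_rvec:
            best_rvec = rvec
    rvec = best_rvec
    sigma2 = max(float(rvec @ rvec) / n, 1e-12)
    loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    k = n_plants + len(shape_names) + 1
    aic = 2.0 * k - 2.0 * loglik
    return float(loglik), float(aic), float(np.sqrt(sigma2)), int(n_plants)


def _aicc(aic: float, k: int, n: int) -> float:
    """Small-sample corrected AIC.  The correction matters here because
    the per-plant asymptote scales make k a sizeable fraction of n."""
    if n - k - 1 <= 0:
        return float("inf")
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def select_model(
    heights: pd.DataFrame,
    candidates: Sequence[str | GrowthModelSpec] | None = None,
    **fit_kwargs,
) -> tuple[GrowthModelSpec, pd.DataFrame]:
    """Fit all candidate models and select the one with the lowest AICc.

    The small-sample corrected criterion is used because the per-plant
    asymptote scales of the comparison likelihood make the parameter
    count a sizeable fraction of the observation count; the table reports
    plain AIC alongside.  Failed fits enter the table with ``+inf`` and
    the failure reason.  Ties are broken deterministically by registry
    order (the order of ``candidates``).
    """
    if candidates is None:
        candidates = list(MODEL_REGISTRY)
    rows = []
    fits: dict[str, GrowthFit] = {}
    for cand in candidates:
        spec = get_model(cand)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", DegenerateSeriesWarning)
                fit = fit_growth_model(heights, spec, **fit_kwargs)
            fits[spec.name] = fit
            rows.append(
                {
                    "model": spec.name,
                    "aicc": fit.aicc,
                    "aic": fit.aic,
                    "loglik": fit.loglik,
                    "k": fit.k,
                    "n_converged": fit.n_converged,
                    "reason": "",
                }
            )
        except ValueError as exc:
            rows.append(
                {
                    "model": spec.name,
                    "aicc": np.inf,
                    "aic": np.inf,
                    "loglik": -np.inf,
                    "k": get_model(cand).k + 1,
                    "n_converged": 0,
                    "reason": str(exc),
                }
            )
    table = pd.DataFrame(rows)
    if not np.isfinite(table["aicc"]).any():
        raise ValueError("all candidate growth models failed to fit")
    best_idx = int(np.argmin(table["aicc"].to_numpy()))  # first minimum wins
    best = get_model(table.loc[best_idx, "model"])
    n_best = int((table["aicc"] == table.loc[best_idx, "aicc"]).sum())
    if n_best > 1:
        table.attrs["tie"] = True
    table.attrs["best"] = best.name
    table.attrs["fits"] = fits
    return best, table
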