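"""Relative-performance statistics for selfed/outcrossed comparisons.

The central quantity is the symmetric relative-performance index used to
express inbreeding depression (delta).  For selfed performance ``w_s`` and
outcrossed performance ``w_o``::

    delta = 1 - w_s / w_o    if w_o > w_s   (positive: outcrossed better)
    delta = w_o / w_s - 1    if w_s > w_o   (negative, symmetric branch)
    delta = 0                if w_s == w_o

The index is bounded in [-1, 1], antisymmetric under exchange of the two
groups and invariant to rescaling both performances by a common positive
factor.  The same index applied to competition environments (no competitor,
selfed competitor, outcrossed competitor) yields the competitive
relative-performance (RP) family.

Confidence intervals are percentile bootstrap intervals resampling maternal
families with replacement, which respects the family-level blocking of the
experimental design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "relative_performance",
    "competitive_rp",
    "bootstrap_rp",
    "RelativePerformance",
    "ZeroFitnessWarning",
]


class ZeroFitnessWarning(UserWarning):
    """Raised when both groups have zero performance and delta defaults to 0."""


@dataclass(frozen=True)
class RelativePerformance:
    """A delta/RP estimate with a family-bootstrap percentile 95% CI."""

    estimate: float
    ci_low: float
    ci_high: float
    n_boot: int
    trait: str = ""
    year: int | str | None = None
    comparison: str = "selfed_vs_outcrossed"

    def covers_zero(self) -> bool:
        return self.ci_low <= 0.0 <= self.ci_high


def relative_performance(w_s: float, w_o: float) -> float:
    """Symmetric relative performance (inbreeding depression) of two groups.

    Parameters
    ----------
    w_s, w_o
        Non-negative mean performance of the selfed and outcrossed group.

    Returns
    -------
    float
        ``1 - w_s/w_o`` when the outcrossed group performs better,
        ``w_o/w_s - 1`` when the selfed group performs better, 0 on a tie.
        If exactly one group has zero performance the index saturates at
        +1 (selfed zero) or -1 (outcrossed zero).
    """
    w_s = float(w_s)
    w_o = float(w_o)
    if not (np.isfinite(w_s) and np.isfinite(w_o)):
        raise ValueError("performance values must be finite")
    if w_s < 0 or w_o < 0:
        raise ValueError(
            f"performance values must be non-negative, got w_s={w_s}, w_o={w_o}"
        )
    if w_s == w_o:
        if w_s == 0.0:
            warnings.warn(
                "both groups have zero performance; delta set to 0",
                ZeroFitnessWarning,
                stacklevel=2,
            )
        return 0.0
    if w_o > w_s:
        # saturates at +1 when w_s == 0
        return 1.0 - w_s / w_o
    return w_o / w_s - 1.0


def competitive_rp(
    w_none: float, w_scomp: float, w_ocomp: float
) -> dict[str, float]:
    """Pairwise relative performance across competition environments.

    Positive values mean the first-listed (less competed) group performed
    better, mirroring the sign convention of :func:`relative_performance`
    with the less-competed group in the role of the outcrossed group.

    Returns a mapping with keys ``none_vs_scomp``, ``none_vs_ocomp`` and
    ``scomp_vs_ocomp``.
    """
    return {
        "none_vs_scomp": relative_performance(w_scomp, w_none),
        "none_vs_ocomp": relative_performance(w_ocomp, w_none),
        "scomp_vs_ocomp": relative_performance(w_ocomp, w_scomp),
    }


def bootstrap_rp(
    data: pd.DataFrame,
    statistic: Callable[[pd.DataFrame], float],
    *,
    family_col: str = "family_id",
    n_boot: int = 2000,
    seed: int | np.random.Generator | None = None,
    trait: str = "",
    year: int | str | None = None,
    comparison: str = "selfed_vs_outcrossed",
) -> RelativePerformance:
    """Family-stratified bootstrap of a relative-performance statistic.

    Families are resampled with replacement; every row belonging to a
    sampled family enters the resample (once per time the family is drawn).
    The point estimate is ``statistic(data)`` on the original table and the
    CI is the 2.5/97.5 percentile interval over ``n_boot`` resamples.

    Parameters
    ----------
    data
        Table with a ``family_col`` column; passed (resampled) to
        ``statistic``.
    statistic
        Callable mapping a table to a scalar delta/RP value.  Resamples on
        which the statistic raises ``ValueError`` or returns NaN are
        discarded; if every resample is degenerate an error naming the trait
        is raised.
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    families = data[family_col].unique()
    if len(families) < 5:
        raise ValueError(
            f"family bootstrap requires >= 5 families, got {len(families)}"
        )
    rng = np.random.default_rng(seed)
    point = float(statistic(data))

    by_family = {f: sub for f, sub in data.groupby(family_col, observed=True)}
    draws = np.empty(n_boot)
    n_ok = 0
    for b in range(n_boot):
        picked = rng.choice(families, size=len(families), replace=True)
        resample = pd.concat([by_family[f] for f in picked], ignore_index=True)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ZeroFitnessWarning)
                val = float(statistic(resample))
        except ValueError:
            continue
        if np.isfinite(val):
            draws[n_ok] = val
            n_ok += 1
    if n_ok == 0:
        raise ValueError(
            f"all bootstrap resamples degenerate for trait {trait!r}"
        )
    lo, hi = np.percentile(draws[:n_ok], [2.5, 97.5])
    return RelativePerformance(
        estimate=point,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        trait=trait,
        year=year,
        comparison=comparison,
    )
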