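"""Temporal-stability statistics for community time series.

Definitions
-----------
Temporal variability of a community is the coefficient of variation (CV) of
total density across sampling occasions, ``sd(total) / mean(total)``; its
reciprocal is temporal stability.  Community-wide synchrony is

    phi = Var(sum_i x_i) / (sum_i sd(x_i))**2

which equals 1 when all species fluctuate in perfect proportion and 0 when
species fluctuations cancel exactly (constant total); asynchrony is
``1 - phi``.  Dominance is the time-averaged relative abundance of the most
abundant species.

All standard deviations and variances use the sample (n-1) denominator.
With only six sampling occasions the choice is material; the sample form is
the conventional one in the community-stability literature, and phi is
invariant to the choice as long as numerator and denominator agree.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np

from .domain_model import CommunityTimeSeries, Origin

__all__ = [
    "UndefinedMetricError",
    "temporal_variability",
    "temporal_stability",
    "population_variability",
    "synchrony",
    "asynchrony",
    "dominance",
    "richness",
]


class UndefinedMetricError(ValueError):
    """A stability metric is undefined for the given series (e.g. zero mean)."""


def _as_series(totals) -> np.ndarray:
    x = np.asarray(totals, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"expected a 1-d series, got shape {x.shape}")
    if x.size < 2:
        raise UndefinedMetricError("variability needs at least 2 sampling occasions")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    return x


def temporal_variability(totals) -> float:
    """Coefficient of variation of a density series (sample SD / mean).

    Raises
    ------
    UndefinedMetricError
        If the series mean is <= 0 (undefined CV) or has < 2 points.
    """
    x = _as_series(totals)
    mean = x.mean()
    if mean <= 0:
        raise UndefinedMetricError(f"undefined CV: series mean {mean} <= 0")
    return float(x.std(ddof=1) / mean)


def temporal_stability(totals) -> float:
    """Reciprocal CV.  A constant series has infinite stability and raises."""
    cv = temporal_variability(totals)
    if cv == 0:
        raise UndefinedMetricError("infinite stability: series is constant (CV = 0)")
    return 1.0 / cv


def population_variability(series: CommunityTimeSeries) -> dict[str, float | None]:
    """Per-species CV with the same formula as the community-level CV.

    Species whose density is 0 at every occasion map to ``None`` (CV
    undefined at zero mean) rather than raising.
    """
    out: dict[str, float | None] = {}
    for i, sp in enumerate(series.species_names):
        x = series.density[i]
        if x.mean() <= 0:
            out[sp] = None
        else:
            out[sp] = float(x.std(ddof=1) / x.mean())
    return out


def synchrony(series: CommunityTimeSeries) -> float:
    """Community-wide synchrony phi = Var(total) / (sum of species SDs)^2.

    Bounded in [0, 1] by the Cauchy-Schwarz inequality.  Requires at least
    one species with nonzero SD and >= 2 sampling occasions.
    """
    if series.n_days < 2:
        raise UndefinedMetricError("synchrony needs at least 2 sampling occasions")
    sds = series.density.std(axis=1, ddof=1)
    denom = sds.sum() ** 2
    if denom == 0:
        raise UndefinedMetricError("synchrony undefined (zero denominator): all species constant")
    var_total = series.total_density().var(ddof=1)
    phi = float(var_total / denom)
    # guard against roundoff just past the analytic bounds
    return min(max(phi, 0.0), 1.0)


def asynchrony(series: CommunityTimeSeries) -> float:
    """Species asynchrony 1 - phi, in [0, 1]; 1 means fluctuations cancel."""
    return 1.0 - synchrony(series)


def dominance(series: CommunityTimeSeries, species: str = "auto") -> tuple[float, str]:
    """Time-averaged relative abundance of a (dominant) species.

    With ``species="auto"`` the dominant species is the argmax of
    time-averaged relative abundance (ties broken lexicographically by
    name).  Days with zero total density are excluded with a warning; if
    every day has zero total the metric is undefined.

    Returns
    -------
    (fraction, species_name)
    """
    totals = series.total_density()
    keep = totals > 0
    if not keep.all():
        dropped = [series.sampling_days[j] for j in np.nonzero(~keep)[0]]
        warnings.warn(
            f"microcosm {series.microcosm_id!r}: excluding days {dropped} with zero total density",
            stacklevel=2,
        )
    if not keep.any():
        raise UndefinedMetricError("dominance undefined: total density is zero on every day")
    rel = series.density[:, keep] / totals[keep]
    mean_rel = rel.mean(axis=1)

    if species == "auto":
        best = np.max(mean_rel)
        candidates = [series.species_names[i] for i in np.nonzero(mean_rel == best)[0]]
        chosen = min(candidates)
    else:
        if species not in series.species_names:
            raise KeyError(f"species {species!r} not present in microcosm {series.microcosm_id!r}")
        chosen = species
    idx = series.species_names.index(chosen)
    return float(mean_rel[idx]), chosen


def richness(series: CommunityTimeSeries, residents_only: bool = True) -> int:
    """Number of species detected (density > 0 on >= 1 occasion).

    By default counts resident species only — richness of the *resident*
    community, with introduced invaders excluded.  Detection is cumulative
    over occasions.
    """
    count = 0
    for i, sp in enumerate(series.species_names):
        if residents_only and series.origin[sp] is not Origin.RESIDENT:
            continue
        if np.any(series.density[i] > 0):
            count += 1
    return count
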