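"""Cosinor rhythmometry, morning-vs-night deltas, and group statistics.

Single-component cosinor: least-squares fit of

    y(t) = M + A·cos(2π(t − φ)/P)

with fixed period P (24 h by default).  Through the linearization
``y = M + β1·cos(ωt) + β2·sin(ωt)`` the fit is ordinary least squares with
a closed-form solution: amplitude A = √(β1² + β2²) and acrophase
φ = atan2(β2, β1)/ω (mod P).  Rhythmicity is decided by the zero-amplitude
F test (2 numerator degrees of freedom); a metric is called rhythmic when
p < 0.05.

Also provides the morning-vs-night delta (mean over 6 AM–noon minus mean
over midnight–6 AM, from 3-h bin means), one-way ANOVA / unpaired t group
comparisons, and the echocardiographic fractional-shortening formula
FS = (LVEDD − LVESD)/LVEDD × 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DesignError, InsufficientDataError, ParameterError


@dataclass
class CosinorFit:
    """Parameters of a fixed-period cosinor fit."""

    mesor: float
    amplitude: float
    acrophase: float     # clock-hours in [0, period)
    period: float        # hours
    p_rhythm: float      # zero-amplitude F-test p-value
    rss: float           # residual sum of squares
    f_statistic: float
    n: int

    @property
    def rhythmic(self) -> bool:
        return self.p_rhythm < 0.05


@dataclass
class DeltaMetric:
    """Morning (6 AM–noon) minus night (midnight–6 AM) metric contrast."""

    metric: str
    morning_mean: float
    night_mean: float

    @property
    def delta(self) -> float:
        return self.morning_mean - self.night_mean


@dataclass
class GroupComparison:
    """One-way ANOVA (>=3 groups) or unpaired t test (2 groups)."""

    test: str            # "anova" or "t"
    statistic: float
    p_value: float
    group_means: list[float]
    group_sems: list[float]
    group_ns: list[int]


def cosinor_fit(times_h, values, period: float = 24.0) -> CosinorFit:
    """Fit a fixed-period cosine to (time, value) pairs by least squares."""
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size:
        raise ParameterError("times and values must have equal length")
    if t.size < 6:
        raise InsufficientDataError("cosinor needs >= 6 time points")
    if np.ptp(t) < period - 1e-9 and np.ptp(t % period) < 1e-9:
        raise DesignError("all times equal modulo the period: degenerate design")
    omega = 2.0 * np.pi / period
    X = np.column_stack([np.ones_like(t), np.cos(omega * t), np.sin(omega * t)])
    if np.linalg.matrix_rank(X) < 3:
        raise DesignError("degenerate cosinor design (collinear regressors)")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    mesor, b1, b2 = beta
    amplitude = float(np.hypot(b1, b2))
    acrophase = float((np.arctan2(b2, b1) / omega) % period)
    # zero-amplitude F test: compare against the mesor-only model
    rss0 = float(np.sum((y - y.mean()) ** 2))
    dof_res = t.size - 3
    if dof_res <= 0:
        raise InsufficientDataError("not enough points for the rhythm test")
    if rss0 <= 1e-12 * max(1.0, abs(float(y.mean()))) ** 2:
        # constant input: no variance to explain, no rhythm
        f_stat, p = 0.0, 1.0
    elif rss <= 0:  # perfect fit
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = ((rss0 - rss) / 2.0) / (rss / dof_res)
        p = float(stats.f.sf(f_stat, 2, dof_res))
    return CosinorFit(float(mesor), amplitude, acrophase, period, p,
                      rss, float(f_stat), int(t.size))


def delta_metric(bin_means: dict[float, float], metric: str = "") -> DeltaMetric:
    """Morning−night contrast from 3-h bin means keyed by bin start hour.

    Morning = mean of the [6,9) and [9,12) bins; night = mean of [0,3) and
    [3,6).
    """
    needed = (0.0, 3.0, 6.0, 9.0)
    missing = [b for b in needed if b not in bin_means]
    if missing:
        raise ParameterError(f"missing 3-h bins starting at {missing}")
    morning = float(np.mean([bin_means[6.0], bin_means[9.0]]))
    night = float(np.mean([bin_means[0.0], bin_means[3.0]]))
    return DeltaMetric(metric, morning, night)


def group_compare(*groups) -> GroupComparison:
    """Unpaired t test for 2 groups, one-way ANOVA for 3 or more."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ParameterError("need at least 2 groups")
    if any(a.size < 2 for a in arrs):
        raise InsufficientDataError("every group needs n >= 2")
    means = [float(a.mean()) for a in arrs]
    sems = [float(stats.sem(a)) for a in arrs]
    ns = [int(a.size) for a in arrs]
    if len(arrs) == 2:
        t, p = stats.ttest_ind(arrs[0], arrs[1])
        return GroupComparison("t", float(t), float(p), means, sems, ns)
    f, p = stats.f_oneway(*arrs)
    return GroupComparison("anova", float(f), float(p), means, sems, ns)


def fractional_shortening(lvedd: float, lvesd: float) -> float:
    """LV fractional shortening in percent: (LVEDD − LVESD)/LVEDD × 100."""
    if not lvedd > lvesd > 0:
        raise ParameterError(
            f"require LVEDD > LVESD > 0, got LVEDD={lvedd}, LVESD={lvesd}"
        )
    return (lvedd - lvesd) / lvedd * 100.0
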