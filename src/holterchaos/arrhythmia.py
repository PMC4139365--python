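"""Ventricular-arrhythmia quantitation and time-of-day statistics.

A VT episode is a maximal run of 3 or more consecutive ventricular (``V``)
beats; all beats of such a run count as VT beats.  ``V`` beats in runs of
length 1 or 2 (singlets, couplets) count as PVCs.  The three totals are
therefore disjoint.  Episode timing is the time of the first beat of the
run.  Non-uniform circadian timing is tested with a χ² goodness-of-fit
test on quartile (6-h) counts against a uniform expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .beats import BeatStream
from .errors import ParameterError

QUARTILE_EDGES_H = (0.0, 6.0, 12.0, 18.0, 24.0)


@dataclass
class ArrhythmiaCounts:
    """PVC / VT totals and their per-window breakdown.

    ``per_window`` maps window start hour -> (pvc, vt_episodes, vt_beats).
    """

    pvc_count: int
    vt_episode_count: int
    vt_beat_count: int
    bin_h: float
    per_window: dict[float, tuple[int, int, int]] = field(default_factory=dict)

    def quartile_counts(self, what: str = "pvc") -> np.ndarray:
        """Counts per 6-h quartile for ``what`` in {pvc, vt_episodes, vt_beats}."""
        idx = {"pvc": 0, "vt_episodes": 1, "vt_beats": 2}[what]
        out = np.zeros(4, dtype=int)
        for start, triple in self.per_window.items():
            out[int(start // 6) % 4] += triple[idx]
        return out

    def to_frame(self, record_id: str = "rec") -> pd.DataFrame:
        rows = [
            {"recording": record_id, "window_start_h": s,
             "pvc": c[0], "vt_episodes": c[1], "vt_beats": c[2]}
            for s, c in sorted(self.per_window.items())
        ]
        return pd.DataFrame(rows)


@dataclass
class TimingTestResult:
    """χ² goodness-of-fit test of uniform event timing over 4 quartiles."""

    observed: np.ndarray
    chi2_statistic: float
    dof: int
    p_value: float
    morning_fold: float  # count[6,12) / count[0,6); nan if undefined
    morning_fold_defined: bool
    low_count_warning: bool


def _v_runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive V beats as (start_index, length)."""
    isv = np.asarray(labels) == "V"
    if not isv.any():
        return []
    padded = np.concatenate(([False], isv, [False])).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def classify_ventricular(stream: BeatStream, bin_h: float = 6.0) -> ArrhythmiaCounts:
    """Count PVCs, VT episodes and VT beats, binned by time of day.

    Each run (or isolated PVC) is assigned to the clock window containing
    its first beat.
    """
    if bin_h <= 0 or abs(24.0 / bin_h - round(24.0 / bin_h)) > 1e-9:
        raise ParameterError(f"bin width {bin_h} h does not divide 24 h")
    n_win = int(round(24.0 / bin_h))
    clock = stream.clock_h if len(stream) else np.empty(0)
    per_window = {k * bin_h: [0, 0, 0] for k in range(n_win)}
    pvc = vt_epi = vt_beats = 0
    for start, length in _v_runs(stream.labels):
        w = per_window[(int(clock[start] // bin_h) % n_win) * bin_h]
        if length >= 3:
            vt_epi += 1
            vt_beats += length
            w[1] += 1
            w[2] += length
        else:
            pvc += length
            w[0] += length
    return ArrhythmiaCounts(
        pvc_count=pvc,
        vt_episode_count=vt_epi,
        vt_beat_count=vt_beats,
        bin_h=bin_h,
        per_window={k: tuple(v) for k, v in per_window.items()},
    )


def chi2_uniformity(per_quartile_counts) -> TimingTestResult:
    """χ² test of the 4 quartile counts against a uniform distribution.

    Expected count is total/4 per bin; the statistic is Σ(O−E)²/E on 3
    degrees of freedom.  With total < 8 the expected count per bin drops
    below 2 and the asymptotic test is unreliable; the result then carries
    ``low_count_warning``.
    """
    obs = np.asarray(per_quartile_counts, dtype=float)
    if obs.shape != (4,):
        raise ParameterError("expected exactly 4 quartile counts")
    total = obs.sum()
    if total < 1:
        raise ParameterError("need at least one event for the timing test")
    chi2, p = stats.chisquare(obs)
    defined = obs[0] > 0
    fold = float(obs[1] / obs[0]) if defined else float("nan")
    return TimingTestResult(
        observed=obs.astype(int),
        chi2_statistic=float(chi2),
        dof=3,
        p_value=float(p),
        morning_fold=fold,
        morning_fold_defined=bool(defined),
        low_count_warning=bool(total < 8),
    )


def fold_change(per_quartile_counts) -> dict[str, float]:
    """Quartile-on-preceding-quartile count ratios.

    Returns one fold per quartile (``fold_00_06`` compares [0,6) with the
    cyclically preceding [18,24)).  ``morning_fold`` is the [6,12)/[0,6)
    ratio.  A zero denominator yields NaN, never an exception.
    """
    obs = np.asarray(per_quartile_counts, dtype=float)
    if obs.shape != (4,):
        raise ParameterError("expected exactly 4 quartile counts")
    names = ["fold_00_06", "fold_06_12", "fold_12_18", "fold_18_24"]
    out: dict[str, float] = {}
    for q, name in enumerate(names):
        prev = obs[(q - 1) % 4]
        out[name] = float(obs[q] / prev) if prev > 0 else float("nan")
    out["morning_fold"] = out["fold_06_12"]
    return out
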