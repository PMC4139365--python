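"""Nonlinear dynamics of the NN series.

Three complexity/fractality indices computed on the beat-to-beat interval
sequence:

* **Detrended fluctuation analysis (DFA).**  The mean-subtracted series is
  integrated, divided into non-overlapping boxes of size n, linearly
  detrended per box, and the RMS fluctuation F(n) is compared with n on
  log-log axes.  The short-term exponent α1 uses box sizes 4 ≤ n ≤ 16,
  the long-term exponent α2 uses 16 ≤ n ≤ 64.  Uncorrelated noise gives
  α ≈ 0.5, 1/f noise α ≈ 1, Brownian motion α ≈ 1.5.  At box sizes this
  small the naive log-log slope is biased (the per-box line fit absorbs a
  size-dependent share of the fluctuation: for white noise
  E[F²(n)] ∝ (n² − 4)/n, whose local slope at n = 4–16 is well above ½),
  so the exponents are estimated by matching the measured fluctuation
  curve against the exact expectation E[F²(n)] of a Gaussian process with
  an f^(−β) power spectrum, β = 2α − 1; the naive slopes are kept as
  diagnostics.

* **Correlation dimension (Grassberger–Procaccia).**  The series is delay-
  embedded in m dimensions; the correlation integral C(r) — the fraction
  of vector pairs closer than r, excluding temporally adjacent pairs
  (Theiler window) — is computed over a threshold grid, and CD is the
  slope of log C(r) vs log r over the small-r scaling region.

* **Shannon entropy of recurrence line lengths.**  From the recurrence
  matrix of the embedded series at a fixed threshold, diagonal line
  segments of length ≥ lmin are collected; with p(ℓ) the fraction of lines
  of length ℓ, SE = −Σ p(ℓ)·log2 p(ℓ) in bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .errors import DegenerateSeriesError, InsufficientDataError, ParameterError

DFA_SHORT_RANGE = (4, 16)
DFA_LONG_RANGE = (16, 64)


@dataclass
class DFAResult:
    alpha1: float            # finite-size-matched short-range exponent
    alpha2: float            # finite-size-matched long-range exponent
    slope_alpha1: float      # naive log F vs log n slope, 4 <= n <= 16
    slope_alpha2: float      # naive slope, 16 <= n <= 64
    r2_alpha1: float         # r^2 of the naive short-range slope fit
    r2_alpha2: float
    scales: np.ndarray
    fluctuations: np.ndarray


@dataclass
class CDResult:
    cd: float
    scaling_range: tuple[float, float]  # (r_low, r_high) of the fitted region
    thresholds: np.ndarray
    corr_integral: np.ndarray
    n_fit_points: int
    reliable: bool
    m: int
    tau: int


@dataclass
class SEResult:
    se_bits: float          # nan if no lines found (undefined, not 0)
    n_lines: int
    line_length_counts: dict[int, int] = field(default_factory=dict)
    threshold: float = float("nan")
    m: int = 10
    tau: int = 1
    lmin: int = 2

    @property
    def defined(self) -> bool:
        return self.n_lines > 0


@dataclass
class NonlinearResult:
    """Bundle of all nonlinear indices for one window."""

    dfa_alpha1: float
    dfa_alpha2: float
    cd: float
    se: float
    dfa: DFAResult | None = None
    cd_detail: CDResult | None = None
    se_detail: SEResult | None = None


# ---------------------------------------------------------------------------
# DFA


def _dfa_fluctuation(y: np.ndarray, n: int) -> float:
    """RMS fluctuation of the integrated series in boxes of size n.

    Boxes that would not fill the series tail are discarded.
    """
    nb = y.size // n
    seg = y[: nb * n].reshape(nb, n).T  # n x nb
    design = np.vstack([np.arange(n, dtype=float), np.ones(n)]).T
    coef, *_ = np.linalg.lstsq(design, seg, rcond=None)
    resid = seg - design @ coef
    return float(np.sqrt(np.mean(resid**2)))


def _log_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    lx, ly = np.log(x), np.log(y)
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = np.sum((ly - pred) ** 2)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(r2)


# Finite-size expected fluctuations for the exponent-matching estimator.
# Reference model: periodic Gaussian process with power spectrum f^(-beta),
# beta = 2*alpha - 1, on an NREF-point frequency grid.  Small-box DFA of
# such a process has an exactly computable E[F^2(n)]; matching the measured
# curve to this family removes the small-box detrending bias of the naive
# log-log slope.
_NREF = 8192
_ALPHA_GRID = np.round(np.arange(0.025, 1.976, 0.025), 4)


@lru_cache(maxsize=None)
def _powerlaw_autocov(beta: float, kmax: int = 64) -> np.ndarray:
    f = np.fft.rfftfreq(_NREF)[1:]
    p = f ** (-beta)
    k = np.arange(kmax + 1)
    return (p[None, :] * np.cos(2.0 * np.pi * np.outer(k, f))).sum(axis=1)


@lru_cache(maxsize=None)
def _expected_f2(alpha: float, n: int) -> float:
    gam = _powerlaw_autocov(round(2.0 * alpha - 1.0, 4))
    k = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    cov_x = gam[k]
    t_mat = np.tril(np.ones((n, n)))
    cov_y = t_mat @ cov_x @ t_mat.T
    j = np.arange(n, dtype=float)
    design = np.vstack([j, np.ones(n)]).T
    hat = design @ np.linalg.inv(design.T @ design) @ design.T
    m_mat = np.eye(n) - hat
    return float(np.trace(m_mat @ cov_y @ m_mat.T) / n)


def _match_alpha(scales: np.ndarray, fluct: np.ndarray) -> float:
    """alpha minimizing the intercept-free misfit of log F to log sqrt(E[F^2])."""
    log_f = np.log(fluct)
    costs = np.empty(_ALPHA_GRID.size)
    for i, a in enumerate(_ALPHA_GRID):
        log_k = 0.5 * np.log([_expected_f2(float(a), int(n)) for n in scales])
        r = log_f - log_k
        costs[i] = float(np.sum((r - r.mean()) ** 2))
    i = int(np.argmin(costs))
    if 0 < i < costs.size - 1:  # parabolic refinement between grid points
        c0, c1, c2 = costs[i - 1 : i + 2]
        denom = c0 - 2 * c1 + c2
        if denom > 0:
            step = 0.5 * (c0 - c2) / denom
            return float(_ALPHA_GRID[i] + np.clip(step, -1, 1) * 0.025)
    return float(_ALPHA_GRID[i])


def dfa(
    nn_values,
    scales_short: tuple[int, int] = DFA_SHORT_RANGE,
    scales_long: tuple[int, int] = DFA_LONG_RANGE,
    n_scales: int = 24,
) -> DFAResult:
    """Detrended fluctuation analysis with short- and long-range exponents.

    ``alpha1``/``alpha2`` are finite-size-matched estimates (see module
    docstring); ``slope_alpha1``/``slope_alpha2`` are the naive log-log
    regression slopes over the same box ranges.
    """
    x = np.asarray(nn_values, dtype=float)
    min_len = 4 * scales_long[1]
    if x.size < min_len:
        raise InsufficientDataError(
            f"DFA needs >= {min_len} samples (4x largest box), got {x.size}"
        )
    if np.ptp(x) == 0:
        raise DegenerateSeriesError("constant series: DFA fluctuation is zero")
    y = np.cumsum(x - x.mean())
    scales = np.unique(
        np.round(np.geomspace(scales_short[0], scales_long[1], n_scales)).astype(int)
    )
    fluct = np.array([_dfa_fluctuation(y, int(n)) for n in scales])
    if np.any(fluct == 0):
        raise DegenerateSeriesError("zero fluctuation at some scale")
    sel1 = (scales >= scales_short[0]) & (scales <= scales_short[1])
    sel2 = (scales >= scales_long[0]) & (scales <= scales_long[1])
    s1, r2_1 = _log_slope(scales[sel1], fluct[sel1])
    s2, r2_2 = _log_slope(scales[sel2], fluct[sel2])
    a1 = _match_alpha(scales[sel1], fluct[sel1])
    a2 = _match_alpha(scales[sel2], fluct[sel2])
    return DFAResult(a1, a2, s1, s2, r2_1, r2_2, scales, fluct)


# ---------------------------------------------------------------------------
# Delay embedding + correlation dimension


def embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Delay-embedding matrix: row i is (x_i, x_{i+tau}, ..., x_{i+(m-1)tau})."""
    x = np.asarray(x, dtype=float)
    n_vec = x.size - (m - 1) * tau
    if n_vec < 2:
        raise InsufficientDataError("series too short for this embedding")
    idx = np.arange(n_vec)[:, None] + np.arange(m)[None, :] * tau
    return x[idx]


def correlation_integral(
    vectors: np.ndarray, thresholds: np.ndarray, theiler: int, block: int = 256
) -> np.ndarray:
    """C(r): fraction of vector pairs (|i−j| > theiler) with distance < r.

    Euclidean distances, computed blockwise to bound memory; counts are
    accumulated into the threshold grid as a cumulative histogram.
    """
    n = vectors.shape[0]
    edges = np.concatenate(([0.0], thresholds))
    counts = np.zeros(thresholds.size, dtype=np.int64)
    n_pairs = 0
    for i0 in range(0, n, block):
        i1 = min(i0 + block, n)
        for i in range(i0, i1):
            j0 = i + theiler + 1
            if j0 >= n:
                continue
            d = np.sqrt(np.sum((vectors[j0:] - vectors[i]) ** 2, axis=1))
            counts += np.histogram(d, bins=edges)[0]
            n_pairs += n - j0
    if n_pairs == 0:
        raise InsufficientDataError("Theiler window leaves no eligible pairs")
    return np.cumsum(counts) / n_pairs


def correlation_dimension(
    nn_values,
    m: int = 10,
    tau: int = 1,
    thresholds: np.ndarray | None = None,
    theiler: int | None = None,
    fit_c_range: tuple[float, float] = (1e-3, 0.1),
    min_pairs_per_point: int = 10,
) -> CDResult:
    """Grassberger–Procaccia correlation dimension of the embedded series.

    The slope of log C(r) vs log r is fitted over the small-r scaling
    region, delimited by correlation-integral values ``fit_c_range`` (and
    by requiring at least ``min_pairs_per_point`` pairs behind each point).
    The default threshold grid spans [0.01, 2]·√m·SD geometrically.  When
    fewer than 3 grid points fall in the scaling region the fit falls back
    to the widest usable region and the result is flagged unreliable.
    """
    x = np.asarray(nn_values, dtype=float)
    if m < 2:
        raise ParameterError("embedding dimension m must be >= 2")
    if np.ptp(x) == 0:
        raise DegenerateSeriesError("constant series has no attractor geometry")
    vec = embed(x, m, tau)
    if vec.shape[0] < 500:
        raise InsufficientDataError(
            f"need >= 500 embedded vectors, got {vec.shape[0]}"
        )
    if theiler is None:
        theiler = m * tau
    sd = x.std()
    if thresholds is None:
        r0 = np.sqrt(m) * sd
        thresholds = np.geomspace(0.01 * r0, 2.0 * r0, 40)
    thresholds = np.asarray(thresholds, dtype=float)
    c = correlation_integral(vec, thresholds, theiler)
    n_vec = vec.shape[0]
    eligible_pairs = (n_vec - theiler - 1) * (n_vec - theiler) // 2
    c_floor = max(fit_c_range[0], min_pairs_per_point / eligible_pairs)
    sel = (c >= c_floor) & (c <= fit_c_range[1]) & (c > 0)
    reliable = int(sel.sum()) >= 3
    if not reliable:
        sel = (c > min_pairs_per_point / eligible_pairs) & (c < 0.5)
        if int(sel.sum()) < 2:
            raise DegenerateSeriesError(
                "no usable scaling region in the correlation integral"
            )
    slope, _ = _log_slope(thresholds[sel], c[sel])
    r_sel = thresholds[sel]
    return CDResult(
        cd=slope,
        scaling_range=(float(r_sel[0]), float(r_sel[-1])),
        thresholds=thresholds,
        corr_integral=c,
        n_fit_points=int(sel.sum()),
        reliable=reliable,
        m=m,
        tau=tau,
    )


# ---------------------------------------------------------------------------
# Recurrence Shannon entropy


def _diagonal_line_lengths(
    vec: np.ndarray, threshold: float, lmin: int
) -> dict[int, int]:
    """Lengths of diagonal recurrence lines (offsets >= 1), length >= lmin."""
    n = vec.shape[0]
    counts: dict[int, int] = {}
    for d in range(1, n):
        rec = np.sum((vec[: n - d] - vec[d:]) ** 2, axis=1) <= threshold**2
        if not rec.any():
            continue
        padded = np.concatenate(([False], rec, [False])).astype(np.int8)
        dd = np.diff(padded)
        lengths = np.flatnonzero(dd == -1) - np.flatnonzero(dd == 1)
        for ell in lengths[lengths >= lmin]:
            counts[int(ell)] = counts.get(int(ell), 0) + 1
    return counts


def shannon_entropy(
    nn_values,
    m: int = 10,
    tau: int = 1,
    threshold: float | None = None,
    lmin: int = 2,
) -> SEResult:
    """Shannon entropy (bits) of the recurrence diagonal line-length histogram.

    Recurrence: embedded vectors closer (Euclidean) than ``threshold``
    (default √m·SD of the series).  Only off-diagonal lines are counted,
    and each maximal diagonal run of length ≥ lmin contributes one line of
    its full length.  If no line is found the entropy is undefined and
    reported as NaN with ``defined == False`` — never as 0.
    """
    x = np.asarray(nn_values, dtype=float)
    vec = embed(x, m, tau)
    if vec.shape[0] < 200:
        raise InsufficientDataError(
            f"need >= 200 embedded vectors, got {vec.shape[0]}"
        )
    if threshold is None:
        if np.ptp(x) == 0:
            raise DegenerateSeriesError("constant series: recurrence threshold undefined")
        threshold = float(np.sqrt(m) * x.std())
    counts = _diagonal_line_lengths(vec, float(threshold), lmin)
    total = sum(counts.values())
    if total == 0:
        return SEResult(float("nan"), 0, {}, float(threshold), m, tau, lmin)
    p = np.array(list(counts.values()), dtype=float) / total
    se = float(-np.sum(p * np.log2(p)) + 0.0)
    return SEResult(se, total, counts, float(threshold), m, tau, lmin)


def entropy_from_line_counts(counts: dict[int, int]) -> float:
    """SE (bits) from a line-length histogram: −Σ p·log2 p, p = count/total."""
    total = sum(counts.values())
    if total == 0:
        return float("nan")
    p = np.array(list(counts.values()), dtype=float) / total
    return float(-np.sum(p[p > 0] * np.log2(p[p > 0])) + 0.0)


# ---------------------------------------------------------------------------
# Window-level driver


def subsample(x: np.ndarray, max_points: int) -> np.ndarray:
    """Uniform subsampling to at most ``max_points`` (keeps temporal order)."""
    x = np.asarray(x)
    if x.size <= max_points:
        return x
    idx = np.linspace(0, x.size - 1, max_points).round().astype(int)
    return x[np.unique(idx)]


def nonlinear_summary(
    nn_values,
    m: int = 10,
    tau: int = 1,
    lmin: int = 2,
    max_points: int = 5000,
) -> NonlinearResult:
    """DFA α1/α2, CD and SE for one window's NN sequence.

    Beyond ``max_points`` intervals the sequence is uniformly subsampled to
    bound the O(N²) pair computations.  Indices that cannot be computed
    (too short, degenerate) are NaN.
    """
    x = subsample(np.asarray(nn_values, dtype=float), max_points)
    a1 = a2 = cd_v = se_v = float("nan")
    dfa_res = cd_res = se_res = None
    try:
        dfa_res = dfa(x)
        a1, a2 = dfa_res.alpha1, dfa_res.alpha2
    except (InsufficientDataError, DegenerateSeriesError):
        pass
    try:
        cd_res = correlation_dimension(x, m=m, tau=tau)
        cd_v = cd_res.cd
    except (InsufficientDataError, DegenerateSeriesError):
        pass
    try:
        se_res = shannon_entropy(x, m=m, tau=tau, lmin=lmin)
        se_v = se_res.se_bits
    except (InsufficientDataError, DegenerateSeriesError):
        pass
    return NonlinearResult(a1, a2, cd_v, se_v, dfa_res, cd_res, se_res)
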