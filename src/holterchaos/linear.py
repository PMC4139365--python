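"""Time-domain HRV and autoregressive spectral analysis.

Frequency-domain analysis follows the standard tachogram pipeline: the
irregularly sampled NN series is cubic-spline resampled onto a uniform
4-Hz grid, mean-removed, an AR model is fitted by Burg's method (default
order 16), and band powers are integrated from the model spectrum over the
low-frequency band [0.04, 0.15) Hz (mainly sympathetic) and high-frequency
band [0.15, 0.40) Hz (parasympathetic/respiratory).  LF/HF indexes
sympathovagal balance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from statsmodels.regression.linear_model import burg

from .beats import NNSeries, TICK_S
from .errors import ARFitError, InsufficientDataError, SpectralWindowError

LF_BAND_HZ = (0.04, 0.15)
HF_BAND_HZ = (0.15, 0.40)


@dataclass
class TimeDomainResult:
    """Classical time-domain HRV markers for one NN series."""

    mean_hr: float   # beats/min
    mean_rr: float   # ms
    sdnn: float      # ms
    cv: float        # percent, = sdnn/mean_rr*100
    rmssd: float     # ms
    n_pairs: int     # successive pairs used for rMSSD


@dataclass
class SpectralResult:
    """AR power spectral density of the RR tachogram plus band powers."""

    freqs_hz: np.ndarray
    psd: np.ndarray          # ms^2/Hz
    lf_power: float          # ms^2
    hf_power: float          # ms^2
    lf_hf_ratio: float
    ar_order: int


def time_domain(nn: NNSeries) -> TimeDomainResult:
    """Mean HR/RR, SDNN, CV and rMSSD for an NN series.

    rMSSD uses only successive pairs of intervals that were adjacent in the
    source recording (the closing beat of one opening the next); pairs
    broken by ectopic exclusions are skipped.
    """
    if len(nn) < 2:
        raise InsufficientDataError("time-domain HRV needs >= 2 NN intervals")
    x = nn.nn_ms
    mean_rr = float(np.mean(x))
    sdnn = float(np.std(x, ddof=1))
    gaps = np.abs(np.diff(nn.onsets_s) - x[:-1] / 1000.0)
    adjacent = gaps <= TICK_S + 1e-9
    diffs = np.diff(x)[adjacent]
    rmssd = float(np.sqrt(np.mean(diffs**2))) if diffs.size else float("nan")
    return TimeDomainResult(
        mean_hr=60000.0 / mean_rr,
        mean_rr=mean_rr,
        sdnn=sdnn,
        cv=sdnn / mean_rr * 100.0,
        rmssd=rmssd,
        n_pairs=int(diffs.size),
    )


def resample_tachogram(
    nn: NNSeries, fs: float = 4.0, max_gap_s: float = 10.0
) -> tuple[np.ndarray, float]:
    """Evenly resample the NN tachogram for spectral analysis.

    Cubic-spline interpolation of (onset time, NN) onto a uniform grid of
    ``floor(span*fs)+1`` points at ``fs`` Hz, then mean removal.  A gap
    between retained intervals longer than ``max_gap_s`` (typically from a
    burst of excluded ectopy) makes spline values inside the gap pure
    invention, so the series is rejected for spectral use.
    """
    if len(nn) < 10:
        raise InsufficientDataError("resampling needs >= 10 NN intervals")
    t = nn.onsets_s
    span = t[-1] - t[0]
    if span < 60.0:
        raise InsufficientDataError("resampling needs >= 60 s of data")
    if np.max(np.diff(t)) > max_gap_s:
        raise SpectralWindowError(
            f"gap of {np.max(np.diff(t)):.1f} s > {max_gap_s} s: "
            "window unusable for spectra"
        )
    grid = t[0] + np.arange(int(np.floor(span * fs)) + 1) / fs
    sig = CubicSpline(t, nn.nn_ms)(grid)
    return sig - sig.mean(), fs


def ar_psd(
    signal: np.ndarray,
    fs: float,
    order: int = 16,
    n_freq: int = 1024,
    lf_band: tuple[float, float] = LF_BAND_HZ,
    hf_band: tuple[float, float] = HF_BAND_HZ,
) -> SpectralResult:
    """Burg AR spectrum of an evenly sampled tachogram with LF/HF powers.

    The PSD of an AR(p) model with one-step-prediction coefficients a_k and
    innovation variance s2 is ``s2 / fs / |1 − Σ a_k e^{−i2πfk/fs}|²``,
    evaluated on an ``n_freq``-point grid over [0, fs/2].  Band powers are
    trapezoidal integrals over the half-open LF and HF bands.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size <= 3 * order:
        raise InsufficientDataError(
            f"signal length {signal.size} <= 3*order ({3 * order})"
        )
    coefs, sigma2 = burg(signal, order=order, demean=True)
    roots = np.roots(np.concatenate(([1.0], -coefs)))
    if np.any(np.abs(roots) >= 1.0):
        raise ARFitError(
            f"unstable AR({order}) fit: max pole modulus "
            f"{np.max(np.abs(roots)):.6f} >= 1"
        )
    freqs = np.linspace(0.0, fs / 2.0, n_freq)
    k = np.arange(1, order + 1)
    denom = 1.0 - np.exp(-2j * np.pi * np.outer(freqs / fs, k)) @ coefs
    psd = sigma2 / fs / np.abs(denom) ** 2

    def band_power(lo: float, hi: float) -> float:
        sel = (freqs >= lo) & (freqs < hi)
        return float(np.trapezoid(psd[sel], freqs[sel]))

    lf = band_power(*lf_band)
    hf = band_power(*hf_band)
    return SpectralResult(
        freqs_hz=freqs,
        psd=psd,
        lf_power=lf,
        hf_power=hf,
        lf_hf_ratio=lf / hf if hf > 0 else float("inf"),
        ar_order=order,
    )


def window_spectral(
    nn: NNSeries,
    fs: float = 4.0,
    order: int = 16,
    segment_s: float = 300.0,
) -> SpectralResult | None:
    """Average LF/HF band powers over 5-min sub-segments of a window.

    Short-term spectral HRV assumes stationarity, so the window's NN series
    is cut into ``segment_s`` stretches by onset time; each usable segment
    is resampled and Burg-fitted, and band powers are averaged.  Returns
    None when no segment is usable (all too short or gapped).
    """
    t0 = nn.onsets_s[0] if len(nn) else 0.0
    edges = np.arange(t0, (nn.onsets_s[-1] if len(nn) else t0) + segment_s, segment_s)
    lf_list, hf_list, psds = [], [], []
    freqs = None
    for lo in edges:
        sel = (nn.onsets_s >= lo) & (nn.onsets_s < lo + segment_s)
        if int(sel.sum()) < 10:
            continue
        sub = NNSeries(nn.onsets_s[sel], nn.nn_ms[sel], nn.source_id,
                       nn.start_clock_h)
        try:
            sig, _ = resample_tachogram(sub, fs=fs)
            res = ar_psd(sig, fs, order=order)
        except (InsufficientDataError, SpectralWindowError, ARFitError):
            continue
        lf_list.append(res.lf_power)
        hf_list.append(res.hf_power)
        psds.append(res.psd)
        freqs = res.freqs_hz
    if not lf_list:
        return None
    lf, hf = float(np.mean(lf_list)), float(np.mean(hf_list))
    return SpectralResult(
        freqs_hz=freqs,
        psd=np.mean(psds, axis=0),
        lf_power=lf,
        hf_power=hf,
        lf_hf_ratio=lf / hf if hf > 0 else float("inf"),
        ar_order=order,
    )
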