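"""Synthetic 24-hour Holter beat-stream generator.

Emulates the statistical structure of a conscious-animal 24-h Holter
recording: a circadian (≈24-h cosine) heart-rate rhythm, respiratory and
baroreflex sinus-rhythm modulation in the HF and LF bands, fractal
(1/f-like) beat-to-beat variability with a configurable DFA scaling
exponent, and ventricular ectopy (isolated PVCs and VT runs) whose rate
follows a morning-peaked circadian profile.

Beat timing uses integral pulse frequency modulation (IPFM): an
instantaneous rate m(t) [beats/s] is integrated and a beat is emitted each
time the integral crosses the next integer.  This is the standard
generative model linking modulation frequencies in m(t) to spectral peaks
of the resulting RR tachogram.  Timestamps are quantized to the 1/125-s
Holter digitization grid.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import yaml

from .beats import BeatStream, quantize_times, write_beats  # noqa: F401 (re-export)
from .errors import ConfigurationError, ParameterError, SaturationError

__all__ = [
    "SimConfig",
    "generate_fractal_noise",
    "generate_beat_times",
    "inject_ectopy",
    "simulate",
    "write_beats",
]


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the synthetic Holter generator.

    Parameters
    ----------
    duration_h : float
        Recording length in hours.
    hr_mesor : float
        Rhythm-adjusted mean heart rate, beats/min.
    hr_circ_amplitude : float
        Amplitude of the 24-h cosine HR rhythm, beats/min.
    hr_acrophase : float
        Clock hour in [0, 24) at which the HR rhythm peaks.
    lf_freq, lf_depth : float
        Low-frequency (baroreflex, ~0.1 Hz) rate modulation: frequency in
        Hz and fractional depth of the mean rate.
    hf_freq, hf_depth : float
        High-frequency (respiratory, ~0.25 Hz) modulation.
    lf_circ_frac : float
        Circadian gating of the LF depth: the instantaneous LF depth is
        ``lf_depth * (1 + lf_circ_frac * cos(2π(t_clock − hr_acrophase)/24))``,
        clipped at zero.  0 (default) gives a constant LF depth; values in
        (0, 1] produce a daytime rise in sympathetically mediated LF power
        and hence a morning rise in LF/HF.
    fractal_alpha : float
        Target DFA scaling exponent of the fractal rate component, in (0, 2).
    fractal_sd : float
        SD of the fractal rate component, beats/min.
    pvc_base_rate : float
        Baseline isolated-PVC rate, events/hour.
    pvc_morning_fold : float
        Peak/baseline ratio of the circadian ectopy profile (half-wave-
        rectified cosine); 1 means uniform.
    pvc_acrophase : float
        Clock hour at which the ectopy rate peaks.
    vt_rate : float
        VT-episode rate, episodes/hour (same circadian profile as PVCs).
    vt_len_min, vt_len_max : int
        Run length (beats) of injected VT episodes, uniform on the range.
    start_clock_h : float
        Wall-clock hour of recording start (0 = midnight).
    seed : int
        Master seed; sub-processes draw from independent child generators.
    """

    duration_h: float = 24.0
    hr_mesor: float = 104.0
    hr_circ_amplitude: float = 10.0
    hr_acrophase: float = 12.0
    lf_freq: float = 0.10
    lf_depth: float = 0.03
    hf_freq: float = 0.25
    hf_depth: float = 0.03
    lf_circ_frac: float = 0.0
    fractal_alpha: float = 0.9
    fractal_sd: float = 6.0
    pvc_base_rate: float = 0.0
    pvc_morning_fold: float = 1.0
    pvc_acrophase: float = 9.0
    vt_rate: float = 0.0
    vt_len_min: int = 3
    vt_len_max: int = 8
    start_clock_h: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hr_mesor > self.hr_circ_amplitude >= 0:
            raise ParameterError("require hr_mesor > hr_circ_amplitude >= 0")
        for name in ("lf_depth", "hf_depth"):
            v = getattr(self, name)
            if not 0 <= v < 0.5:
                raise ParameterError(f"{name} must be in [0, 0.5)")
        if not 0 < self.fractal_alpha < 2:
            raise ParameterError("fractal_alpha must be in (0, 2)")
        for name in ("pvc_base_rate", "vt_rate", "fractal_sd",
                     "pvc_morning_fold", "duration_h"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.vt_len_min < 3:
            raise ParameterError("vt_len_min must be >= 3 (VT definition)")
        if self.vt_len_max < self.vt_len_min:
            raise ParameterError("vt_len_max must be >= vt_len_min")
        for name in ("hr_acrophase", "pvc_acrophase", "start_clock_h"):
            if not 0 <= getattr(self, name) < 24:
                raise ParameterError(f"{name} must be in [0, 24)")

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


def generate_fractal_noise(
    n: int, alpha: float, sd: float = 1.0, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Zero-mean noise of length ``n`` with DFA scaling exponent ``alpha``.

    Spectral synthesis: amplitudes shaped as f^(−β/2) with β = 2·alpha − 1
    (so the power spectrum follows f^(−β)), phases uniform on [0, 2π),
    inverse real FFT, then rescaled to sample SD ``sd``.  alpha = 0.5 gives
    white noise (β = 0); alpha = 1 gives classic 1/f noise.
    """
    if not 0 < alpha < 2:
        raise ParameterError(f"alpha must be in (0, 2), got {alpha}")
    if n < 256:
        raise ParameterError(f"need n >= 256 samples, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    beta = 2.0 * alpha - 1.0
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, freqs.size)
    spec = amp * np.exp(1j * phases)
    spec[0] = 0.0
    if n % 2 == 0:  # Nyquist bin must be real for a real signal
        spec[-1] = amp[-1] * np.cos(phases[-1])
    x = np.fft.irfft(spec, n)
    x -= x.mean()
    s = x.std()
    if s > 0:
        x *= sd / s
    return x


def _instantaneous_rate(config: SimConfig, t_s: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Instantaneous beat rate m(t) in beats/s on the time grid ``t_s``."""
    t_clock = (config.start_clock_h + t_s / 3600.0) % 24.0
    omega = 2.0 * np.pi / 24.0
    hr = config.hr_mesor + config.hr_circ_amplitude * np.cos(
        omega * (t_clock - config.hr_acrophase)
    )
    lf_depth_t = config.lf_depth * np.clip(
        1.0 + config.lf_circ_frac * np.cos(omega * (t_clock - config.hr_acrophase)),
        0.0, None,
    )
    mod = (
        1.0
        + lf_depth_t * np.sin(2.0 * np.pi * config.lf_freq * t_s)
        + config.hf_depth * np.sin(2.0 * np.pi * config.hf_freq * t_s)
    )
    rate = hr * mod / 60.0
    if config.fractal_sd > 0:
        # fractal component synthesized at 1 Hz and interpolated: autonomic
        # drive to the sinus node is band-limited, not beat-to-beat white
        fs_noise = 1.0
        n_noise = max(256, int(np.ceil(t_s[-1] * fs_noise)) + 2)
        noise = generate_fractal_noise(
            n_noise, config.fractal_alpha, config.fractal_sd, rng
        )
        rate = rate + np.interp(t_s, np.arange(n_noise) / fs_noise, noise) / 60.0
    return rate


def generate_beat_times(config: SimConfig) -> BeatStream:
    """Generate an all-normal beat stream by IPFM.

    The running integral of m(t) is computed on a 0.1-s grid; beat k is
    placed where the integral crosses k (linear interpolation between grid
    points), then quantized to the 1/125-s grid.
    """
    rng = np.random.default_rng(config.seed)
    child_rate, _ = rng.spawn(2)
    duration_s = config.duration_h * 3600.0
    dt = 0.1
    t_edges = np.arange(dt, duration_s + dt / 2, dt)
    rate = _instantaneous_rate(config, t_edges - dt / 2, child_rate)
    if np.any(rate <= 0):
        raise ConfigurationError(
            "instantaneous rate non-positive: modulation depths / fractal_sd "
            "too large for hr_mesor"
        )
    integral = np.cumsum(rate) * dt
    n_beats = int(np.floor(integral[-1]))
    k = np.arange(1, n_beats + 1, dtype=float)
    beat_t = np.interp(k, np.concatenate(([0.0], integral)),
                       np.concatenate(([0.0], t_edges)))
    beat_t = quantize_times(beat_t)
    # quantization can merge beats closer than one tick; keep the first
    keep = np.concatenate(([True], np.diff(beat_t) > 0))
    beat_t = beat_t[keep]
    labels = np.full(beat_t.size, "N", dtype="U1")
    return BeatStream(
        beat_t, labels,
        record_id=f"sim{config.seed}",
        start_clock_h=config.start_clock_h,
        duration_s=duration_s,
    )


def ectopy_rate_profile(t_clock: np.ndarray | float, base_rate: float,
                        fold: float, acrophase: float) -> np.ndarray:
    """Circadian ectopy rate r(t_clock) in events/hour.

    Half-wave-rectified cosine bump on a uniform floor:
    ``r = base * (1 + (fold − 1) * max(0, cos(2π(t_clock − acrophase)/24)))``.
    The single ``fold`` parameter is the peak/floor ratio.
    """
    t_clock = np.asarray(t_clock, dtype=float)
    bump = np.clip(np.cos(2.0 * np.pi * (t_clock - acrophase) / 24.0), 0.0, None)
    return base_rate * (1.0 + (fold - 1.0) * bump)


def _poisson_event_times(rng: np.random.Generator, config: SimConfig,
                         base_rate: float) -> np.ndarray:
    """Inhomogeneous-Poisson event times (s) by thinning."""
    if base_rate <= 0:
        return np.empty(0)
    duration_s = config.duration_h * 3600.0
    rmax = base_rate * max(1.0, config.pvc_morning_fold)
    n_cand = rng.poisson(rmax * config.duration_h)
    cand = np.sort(rng.uniform(0.0, duration_s, n_cand))
    t_clock = (config.start_clock_h + cand / 3600.0) % 24.0
    r = ectopy_rate_profile(t_clock, base_rate, config.pvc_morning_fold,
                            config.pvc_acrophase)
    accept = rng.uniform(0.0, rmax, n_cand) < r
    return cand[accept]


def inject_ectopy(stream: BeatStream, config: SimConfig) -> BeatStream:
    """Superimpose PVCs and VT episodes on an all-normal beat stream.

    Isolated PVCs replace a normal beat with a ``V`` beat at a shortened
    coupling interval (60 % of the local RR); the following beat is left in
    place, producing the compensatory pause.  VT episodes relabel a run of
    consecutive beats (length uniform on [vt_len_min, vt_len_max]) as ``V``
    without moving them, so timestamps never reorder and the recording
    duration is unchanged.  Event times follow the circadian profile of
    :func:`ectopy_rate_profile`.
    """
    if np.any(stream.labels != "N"):
        raise ParameterError("inject_ectopy expects an all-N stream")
    rng = np.random.default_rng(config.seed)
    _, child_ect = rng.spawn(2)

    expected = (config.pvc_base_rate + config.vt_rate *
                (config.vt_len_min + config.vt_len_max) / 2.0) * config.duration_h
    if expected > 0.3 * len(stream):
        raise SaturationError(
            f"requested ectopy (~{expected:.0f} beats) denser than 30% of the "
            f"{len(stream)} underlying beats"
        )

    times = stream.times_s.copy()
    labels = stream.labels.copy()
    n = times.size

    vt_starts = _poisson_event_times(child_ect, config, config.vt_rate)
    pvc_times = _poisson_event_times(child_ect, config, config.pvc_base_rate)

    for t_ev in vt_starts:
        i = int(np.searchsorted(times, t_ev))
        length = int(child_ect.integers(config.vt_len_min, config.vt_len_max + 1))
        if i < 2 or i + length + 1 >= n:
            continue
        if np.all(labels[i - 1 : i + length + 1] == "N"):
            labels[i : i + length] = "V"

    for t_ev in pvc_times:
        i = int(np.searchsorted(times, t_ev))
        if i < 2 or i + 2 >= n:
            continue
        if not np.all(labels[i - 1 : i + 2] == "N"):
            continue
        local_rr = times[i] - times[i - 1]
        new_t = quantize_times(times[i - 1] + 0.6 * local_rr)
        if new_t <= times[i - 1] or new_t >= times[i + 1]:
            continue
        times[i] = new_t
        labels[i] = "V"

    return BeatStream(times, labels, stream.record_id,
                      stream.start_clock_h, stream.duration_s)


def simulate(config: SimConfig) -> BeatStream:
    """Generate a complete synthetic recording (beat timing + ectopy)."""
    stream = generate_beat_times(config)
    if config.pvc_base_rate > 0 or config.vt_rate > 0:
        stream = inject_ectopy(stream, config)
    return stream
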