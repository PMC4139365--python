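"""Synthetic Holter generator: fractal noise, IPFM timing, ectopy injection."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

from holterchaos import (
    SimConfig,
    build_nn,
    generate_beat_times,
    generate_fractal_noise,
    inject_ectopy,
    read_beats,
    segment,
    write_beats,
)
from holterchaos.errors import ConfigurationError, ParameterError, SaturationError
from holterchaos.nonlinear import dfa
from holterchaos.synthetic import ectopy_rate_profile


def spectral_slope(x):
    """Log-log slope of the periodogram (excluding DC), for beta checks."""
    f = np.fft.rfftfreq(x.size)[1:]
    p = np.abs(np.fft.rfft(x))[1:] ** 2
    # average periodogram in log-spaced bins to tame scatter
    edges = np.geomspace(f[0], f[-1], 25)
    fb, pb = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (f >= lo) & (f < hi)
        if sel.sum() >= 2:
            fb.append(np.mean(f[sel]))
            pb.append(np.mean(p[sel]))
    return np.polyfit(np.log(fb), np.log(pb), 1)[0]


class TestFractalNoise:
    @pytest.mark.parametrize("alpha,beta", [(0.5, 0.0), (1.0, -1.0)])
    def test_spectrum_follows_power_law(self, alpha, beta):
        slopes = [spectral_slope(generate_fractal_noise(4096, alpha, 1.0, s))
                  for s in range(5)]
        assert np.mean(slopes) == pytest.approx(beta, abs=0.15)

    def test_zero_mean_and_unit_sd(self):
        x = generate_fractal_noise(4096, 0.8, 2.5, 3)
        assert x.mean() == pytest.approx(0.0, abs=1e-9)
        assert x.std() == pytest.approx(2.5, rel=1e-9)

    def test_dfa_recovers_configured_alpha(self):
        est = [dfa(generate_fractal_noise(8192, 0.8, 1.0, s)).alpha1
               for s in range(20)]
        assert np.mean(est) == pytest.approx(0.8, abs=0.05)

    @pytest.mark.parametrize("bad", [{"alpha": 0.0}, {"alpha": 2.0}, {"n": 100}])
    def test_parameter_errors(self, bad):
        kw = {"n": 4096, "alpha": 0.8, **bad}
        with pytest.raises(ParameterError):
            generate_fractal_noise(kw["n"], kw["alpha"])


class TestIPFM:
    def test_constant_rate_gives_exact_1000ms_intervals(self):
        cfg = SimConfig(duration_h=0.5, hr_mesor=60, hr_circ_amplitude=0,
                        lf_depth=0, hf_depth=0, fractal_sd=0)
        s = generate_beat_times(cfg)
        rr = np.diff(s.times_s) * 1000.0
        assert np.all(rr == 1000.0)
        assert len(s) == 1800

    def test_beat_count_matches_rate_integral(self):
        cfg = SimConfig(duration_h=1.0, hr_mesor=90, hr_circ_amplitude=8,
                        hr_acrophase=12, lf_depth=0.02, hf_depth=0.03,
                        fractal_sd=0)
        s = generate_beat_times(cfg)
        rate_bpm = lambda t: (90 + 8 * np.cos(2 * np.pi * (t / 3600 - 12) / 24)) * (
            1 + 0.02 * np.sin(2 * np.pi * 0.10 * t)
            + 0.03 * np.sin(2 * np.pi * 0.25 * t))
        expected = quad(lambda t: rate_bpm(t) / 60.0, 0, 3600, limit=2000)[0]
        assert abs(len(s) - expected) <= 1.5  # +-1 beat, plus quantization

    def test_zero_modulation_series_is_periodic(self):
        cfg = SimConfig(duration_h=0.25, hr_mesor=75, hr_circ_amplitude=0,
                        lf_depth=0, hf_depth=0, fractal_sd=0)
        rr = np.diff(generate_beat_times(cfg).times_s)
        assert np.ptp(rr) <= 1.0 / 125.0 + 1e-12

    def test_morning_hr_exceeds_night_with_afternoon_acrophase(self):
        cfg = SimConfig(duration_h=24, hr_mesor=90, hr_circ_amplitude=10,
                        hr_acrophase=15, lf_depth=0, hf_depth=0, fractal_sd=0)
        s = generate_beat_times(cfg)
        nn = build_nn(s)
        win = segment(s, nn, 6.0)
        hr = [60000.0 / np.mean(w.nn_ms) for w in win]
        assert hr[1] > hr[0]  # [6,12) vs [0,6)

    def test_hf_modulation_puts_dominant_ar_peak_in_hf_band(self):
        from holterchaos.linear import ar_psd, resample_tachogram

        cfg = SimConfig(duration_h=1.0, hr_mesor=90, hr_circ_amplitude=0,
                        lf_depth=0, hf_depth=0.05, fractal_sd=0)
        nn = build_nn(generate_beat_times(cfg))
        sig, fs = resample_tachogram(nn)
        res = ar_psd(sig, fs)
        peak = res.freqs_hz[np.argmax(res.psd)]
        assert 0.15 <= peak < 0.40
        assert abs(peak - 0.25) < 0.03

    def test_timestamps_on_125hz_grid(self):
        cfg = SimConfig(duration_h=0.5, seed=5)
        t = generate_beat_times(cfg).times_s
        assert np.allclose(t * 125.0, np.round(t * 125.0), atol=1e-6)

    def test_excessive_depth_raises_configuration_error(self):
        cfg = SimConfig(duration_h=0.5, hr_mesor=40, hr_circ_amplitude=0,
                        lf_depth=0.45, hf_depth=0.45, fractal_sd=30.0)
        with pytest.raises(ConfigurationError):
            generate_beat_times(cfg)


class TestEctopyInjection:
    def test_zero_rates_identity(self, quiet_stream):
        cfg = SimConfig(duration_h=2.0, pvc_base_rate=0, vt_rate=0, seed=11)
        out = inject_ectopy(quiet_stream, cfg)
        assert np.array_equal(out.times_s, quiet_stream.times_s)
        assert np.array_equal(out.labels, quiet_stream.labels)

    def test_degenerate_vt_length_gives_exact_runs(self, quiet_stream):
        cfg = SimConfig(duration_h=2.0, vt_rate=3.0, vt_len_min=5,
                        vt_len_max=5, seed=11)
        out = inject_ectopy(quiet_stream, cfg)
        lab = out.labels
        isv = np.concatenate(([0], (lab == "V").astype(int), [0]))
        d = np.diff(isv)
        lengths = np.flatnonzero(d == -1) - np.flatnonzero(d == 1)
        assert lengths.size > 0
        assert np.all(lengths == 5)

    def test_injection_preserves_order_and_duration(self, quiet_stream):
        cfg = SimConfig(duration_h=2.0, pvc_base_rate=30, vt_rate=2, seed=11)
        out = inject_ectopy(quiet_stream, cfg)
        assert np.all(np.diff(out.times_s) > 0)
        assert len(out) == len(quiet_stream)
        assert out.duration_s == quiet_stream.duration_s
        assert out.times_s[0] == quiet_stream.times_s[0]
        assert out.times_s[-1] == quiet_stream.times_s[-1]

    def test_pvc_has_short_coupling_and_compensatory_pause(self, quiet_stream):
        cfg = SimConfig(duration_h=2.0, pvc_base_rate=20, seed=11)
        out = inject_ectopy(quiet_stream, cfg)
        i = int(np.flatnonzero(out.labels == "V")[0])
        rr = np.diff(out.times_s)
        # coupling interval shorter than the following pause
        assert rr[i - 1] < rr[i]

    def test_quartile_fold_matches_analytic_profile(self, quiet_stream):
        base, fold, acro = 20.0, 2.5, 9.0
        analytic = (quad(lambda t: ectopy_rate_profile(t, base, fold, acro), 6, 12)[0]
                    / quad(lambda t: ectopy_rate_profile(t, base, fold, acro), 0, 6)[0])
        counts = np.zeros(2)
        cfg24 = SimConfig(duration_h=24, hr_mesor=95, hr_circ_amplitude=0,
                          lf_depth=0, hf_depth=0, fractal_sd=0)
        stream = generate_beat_times(cfg24)
        for s in range(30):
            cfg = SimConfig(duration_h=24, pvc_base_rate=base,
                            pvc_morning_fold=fold, pvc_acrophase=acro, seed=s)
            out = inject_ectopy(stream, cfg)
            clock = out.clock_h[out.labels == "V"]
            counts[0] += np.sum(clock < 6)
            counts[1] += np.sum((clock >= 6) & (clock < 12))
        empirical = counts[1] / counts[0]
        assert empirical == pytest.approx(analytic, rel=0.12)

    def test_saturation_error(self, quiet_stream):
        cfg = SimConfig(duration_h=2.0, pvc_base_rate=3000, seed=1)
        with pytest.raises(SaturationError):
            inject_ectopy(quiet_stream, cfg)


class TestRoundTrip:
    def test_empty_stream_header_only(self, tmp_path):
        from holterchaos.beats import BeatStream

        p = write_beats(BeatStream(np.empty(0), np.empty(0, dtype="U1")),
                        tmp_path / "empty.csv")
        assert p.read_text().strip() == "time_s,label"
        assert len(read_beats(p)) == 0

    def test_three_beat_round_trip(self, tmp_path):
        from holterchaos.beats import BeatStream

        s = BeatStream(np.array([0.0, 0.8, 1.6]), np.array(["N", "V", "N"]))
        p = write_beats(s, tmp_path / "b.csv")
        assert len(p.read_text().strip().splitlines()) == 4
        back = read_beats(p)
        assert np.array_equal(back.times_s, s.times_s)
        assert np.array_equal(back.labels, s.labels)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_generated_stream_round_trips_exactly(self, tmp_path, seed):
        cfg = SimConfig(duration_h=0.05, hr_mesor=100, fractal_sd=5.0,
                        fractal_alpha=0.9, seed=seed)
        s = generate_beat_times(cfg)
        p = write_beats(s, tmp_path / f"rt{seed % 7}.csv")
        back = read_beats(p)
        assert np.array_equal(back.times_s, s.times_s)
        assert np.array_equal(back.labels, s.labels)
        assert np.allclose(back.times_s * 125, np.round(back.times_s * 125))


class TestSimConfig:
    @pytest.mark.parametrize("kw", [
        {"hr_mesor": 10, "hr_circ_amplitude": 20},
        {"lf_depth": 0.6},
        {"fractal_alpha": 2.5},
        {"vt_len_min": 2},
        {"vt_len_max": 2, "vt_len_min": 5},
        {"hr_acrophase": 24.0},
        {"pvc_base_rate": -1},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ParameterError):
            SimConfig(**kw)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimConfig(hr_mesor=88.0, fractal_alpha=0.7, seed=9)
        p = cfg.to_yaml(tmp_path / "sim.yaml")
        assert SimConfig.from_yaml(p) == cfg
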