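"""DFA, correlation dimension and recurrence Shannon entropy."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from holterchaos import correlation_dimension, dfa, shannon_entropy
from holterchaos.errors import DegenerateSeriesError, InsufficientDataError
from holterchaos.nonlinear import (
    correlation_integral,
    embed,
    entropy_from_line_counts,
)


# ---------------------------------------------------------------------------
# independent brute-force references (intentionally naive O(N^2) loops)


def brute_correlation_integral(x, m, tau, thresholds, theiler):
    vec = [x[i : i + m * tau : tau] for i in range(len(x) - (m - 1) * tau)]
    n = len(vec)
    counts = np.zeros(len(thresholds))
    pairs = 0
    for i in range(n):
        for j in range(i + theiler + 1, n):
            d = np.sqrt(np.sum((np.asarray(vec[i]) - np.asarray(vec[j])) ** 2))
            pairs += 1
            for k, r in enumerate(thresholds):
                if d < r:
                    counts[k] += 1
    return counts / pairs


def brute_diagonal_line_counts(x, m, tau, threshold, lmin):
    vec = [x[i : i + m * tau : tau] for i in range(len(x) - (m - 1) * tau)]
    n = len(vec)
    rec = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            d = np.sqrt(np.sum((np.asarray(vec[i]) - np.asarray(vec[j])) ** 2))
            rec[i, j] = d <= threshold
    counts = {}
    for off in range(1, n):
        run = 0
        for i in range(n - off):
            if rec[i, i + off]:
                run += 1
            else:
                if run >= lmin:
                    counts[run] = counts.get(run, 0) + 1
                run = 0
        if run >= lmin:
            counts[run] = counts.get(run, 0) + 1
    return counts


# ---------------------------------------------------------------------------


class TestDFA:
    def test_white_noise_alpha_half(self):
        est = [dfa(np.random.default_rng(s).normal(size=8192)).alpha1
               for s in range(20)]
        assert np.mean(est) == pytest.approx(0.5, abs=0.05)

    def test_integrated_white_noise_alpha_three_halves(self):
        est = [dfa(np.cumsum(np.random.default_rng(s).normal(size=8192))).alpha1
               for s in range(20)]
        assert np.mean(est) == pytest.approx(1.5, abs=0.1)

    def test_long_range_exponent_of_white_noise(self):
        est = [dfa(np.random.default_rng(s).normal(size=8192)).alpha2
               for s in range(20)]
        assert np.mean(est) == pytest.approx(0.5, abs=0.05)

    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            dfa(np.full(1000, 800.0))

    def test_too_short_series(self):
        with pytest.raises(InsufficientDataError):
            dfa(np.random.default_rng(0).normal(size=100))

    @pytest.mark.parametrize("a,b", [(3.0, 0.0), (-2.0, 700.0)])
    def test_affine_invariance(self, a, b):
        x = np.random.default_rng(1).normal(size=2048)
        r1, r2 = dfa(x), dfa(a * x + b)
        assert r1.alpha1 == pytest.approx(r2.alpha1, abs=1e-9)
        assert r1.alpha2 == pytest.approx(r2.alpha2, abs=1e-9)

    def test_alpha1_tracks_generator_exponent_monotonically(self):
        from holterchaos import generate_fractal_noise

        alphas = [0.5, 0.75, 1.0, 1.25, 1.5]
        means = []
        for a in alphas:
            est = [dfa(generate_fractal_noise(4096, a, 1.0, s)).alpha1
                   for s in range(10)]
            means.append(np.mean(est))
        rho = spearmanr(alphas, means).statistic
        assert rho > 0.9


class TestCorrelationDimension:
    def test_sinusoid_is_one_dimensional(self):
        x = np.sin(0.3 * np.arange(2000))
        res = correlation_dimension(x, m=10)
        assert res.cd == pytest.approx(1.0, abs=0.15)

    def test_iid_noise_fills_embedding_space(self):
        x = np.random.default_rng(0).normal(size=2000)
        res = correlation_dimension(x, m=3)
        assert res.cd >= 2.5

    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            correlation_dimension(np.full(1500, 5.0), m=3)

    def test_correlation_integral_monotone_in_r(self):
        x = np.random.default_rng(2).normal(size=800)
        res = correlation_dimension(x, m=3)
        assert np.all(np.diff(res.corr_integral) >= 0)

    def test_matches_brute_force_on_small_series(self):
        x = np.random.default_rng(3).normal(size=300)
        m, tau = 3, 1
        theiler = m * tau
        thresholds = np.geomspace(0.3, 4.0, 8)
        vec = embed(x, m, tau)
        fast = correlation_integral(vec, thresholds, theiler)
        slow = brute_correlation_integral(x, m, tau, thresholds, theiler)
        assert np.allclose(fast, slow, atol=1e-12)


class TestShannonEntropy:
    def test_concentrated_histogram_zero_bits(self):
        assert entropy_from_line_counts({5: 42}) == 0.0

    def test_uniform_over_eight_lengths_three_bits(self):
        counts = {l: 7 for l in range(2, 10)}
        assert entropy_from_line_counts(counts) == pytest.approx(3.0)

    def test_exact_match_with_brute_force_reference(self):
        x = np.random.default_rng(4).normal(size=500)
        m, tau, lmin = 3, 1, 2
        thr = np.sqrt(m) * x.std() * 0.5
        res = shannon_entropy(x, m=m, tau=tau, threshold=thr, lmin=lmin)
        ref_counts = brute_diagonal_line_counts(x, m, tau, thr, lmin)
        assert res.line_length_counts == ref_counts
        assert res.se_bits == pytest.approx(entropy_from_line_counts(ref_counts),
                                            abs=1e-12)

    def test_periodic_vs_noise_direction_follows_reference(self):
        n = 500
        periodic = np.sin(0.3 * np.arange(n))
        noise = np.random.default_rng(5).normal(size=n)
        kw = dict(m=5, tau=1, lmin=2)
        se_p = shannon_entropy(periodic, threshold=np.sqrt(5) * periodic.std(), **kw)
        se_n = shannon_entropy(noise, threshold=np.sqrt(5) * noise.std(), **kw)
        ref_p = entropy_from_line_counts(
            brute_diagonal_line_counts(periodic, 5, 1,
                                       np.sqrt(5) * periodic.std(), 2))
        ref_n = entropy_from_line_counts(
            brute_diagonal_line_counts(noise, 5, 1,
                                       np.sqrt(5) * noise.std(), 2))
        assert (se_p.se_bits > se_n.se_bits) == (ref_p > ref_n)

    def test_no_lines_is_undefined_not_zero(self):
        x = np.random.default_rng(6).normal(size=300)
        res = shannon_entropy(x, m=3, threshold=1e-9, lmin=2)
        assert not res.defined
        assert np.isnan(res.se_bits)


class TestGeneratorSweep:
    def test_measured_alpha1_increases_with_configured_alpha(self):
        """Persistence of the simulated beat stream carries through the
        full stream -> NN -> DFA path over the physiological exponent range
        (above alpha ~1 the 8-ms timing grid floors the small-scale
        fluctuations and the mapping saturates)."""
        from holterchaos import SimConfig, build_nn, generate_beat_times

        alphas = [0.3, 0.475, 0.65, 0.825, 1.0]
        means = []
        for a in alphas:
            vals = []
            for s in range(10):
                cfg = SimConfig(duration_h=1.0, hr_mesor=95,
                                hr_circ_amplitude=0, lf_depth=0.01,
                                hf_depth=0.01, fractal_alpha=a,
                                fractal_sd=5.0, seed=s)
                nn = build_nn(generate_beat_times(cfg))
                vals.append(dfa(nn.nn_ms).alpha1)
            means.append(np.mean(vals))
        assert spearmanr(alphas, means).statistic > 0.9
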