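# Methods

This note documents the models, estimators and parameter choices behind
`holterchaos`, what the synthetic generator does and does not emulate,
and the numerical conventions a user should know before trusting a
number.

## Input model

A recording is an ordered list of beats: time in seconds from recording
start and one label per beat (`N` sinus, `V` ventricular, `A` atrial,
`X` artifact). Times are strictly increasing and live on a 1/125-s grid,
the digitization step of typical Holter hardware; all synthetic
timestamps are quantized to that grid. The wall-clock hour of each beat
is `(start_clock_h + t/3600) mod 24`, with recordings starting at
midnight by default.

## NN-series construction

HRV is computed on normal-to-normal intervals only. An RR interval is
retained iff both bounding beats are `N` and its duration is inside
configurable physiological bounds (default 200–3000 ms). Both intervals
adjacent to an ectopic or artifact beat are therefore removed — an
ectopic beat corrupts the interval it closes (premature coupling) and
the one it opens (compensatory pause). Removed intervals are dropped,
never interpolated: time-domain and nonlinear statistics see only
measured intervals, and spectral analysis handles irregular sampling by
its own resampling step. The exclusion log (count per reason) is kept on
the series and surfaced by the pipeline, because silent mass exclusion
is the main failure mode of automated HRV.

Windows are clock-aligned and half-open: `[start, end)` with an interval
assigned to the window containing its onset; 3-h bins for metric time
courses, 6-h quartiles for event-timing statistics, so "morning" is
exactly [6, 12) and "night" [0, 6).

## Time- and frequency-domain HRV

SDNN is the sample standard deviation (ddof = 1) of the NN intervals in
a window; CV = SDNN/meanRR·100; rMSSD uses only successive interval
pairs that were adjacent in the source stream (a pair straddling an
exclusion gap is skipped; the count of pairs used is reported).

Spectral analysis follows standard tachogram practice, declared here
because the underlying conventions are not unique:

* cubic-spline interpolation of (onset, NN) onto a uniform 4-Hz grid
  (Nyquist 2 Hz comfortably covers the 0.4-Hz HF edge), mean removed;
* windows are analysed in 5-min sub-segments (short-term stationarity),
  whose LF/HF band powers are averaged; a sub-segment containing an
  inter-onset gap > 10 s is unusable (spline values inside such a gap
  are invention) and is skipped;
* an AR model is fitted by Burg's method, order 16 by default (order and
  sampling rate are exposed in the config); the model spectrum
  `s²/(fs·|1 − Σ aₖ e^(−2πifk/fs)|²)` is evaluated on a 1024-point grid
  over [0, fs/2] — dense enough that narrow AR peaks are integrated
  accurately — and fits with poles on or outside the unit circle raise a
  diagnostic error rather than returning a spectrum;
* band powers are trapezoidal integrals over half-open bands
  LF [0.04, 0.15) and HF [0.15, 0.40) Hz (no double counting at 0.15).

A Parseval-style property (total spectral integral ≈ signal variance
within 10 %) is enforced in the tests for well-conditioned fits.

## DFA and the finite-size-matched exponent

F(n) is computed the standard way: integrate the mean-subtracted series,
cut into non-overlapping boxes of size n (partial tail boxes discarded),
least-squares line detrend per box, RMS over all boxes. Box sizes are
log-spaced integers, α1 over 4 ≤ n ≤ 16 and α2 over 16 ≤ n ≤ 64.

At boxes this small the naive log F–log n slope is a biased estimator of
the scaling exponent: the per-box line fit absorbs a size-dependent
share of the fluctuation. For white noise the expectation is exactly
E[F²(n)] = σ²(n² − 4)/(15n), whose local log-log slope over n = 4–16 is
≈ 0.6, not the asymptotic ½ — a naive-slope α1 of white noise reads
≈ 0.59. `holterchaos` therefore estimates the exponent by matching the
measured log F(n) curve (free intercept) against the exactly computable
finite-size expectation of a Gaussian process with power spectrum f^(−β),
β = 2α − 1, over a grid of α with parabolic refinement. This estimator
recovers α within ±0.01 on synthesized f^(−β) noise across α ∈ (0.4, 1.5)
and gives 0.50 on white noise and ≈ 1.45 on integrated white noise
(n = 8192, 20 seeds). The naive slopes and their r² are reported as
diagnostics alongside.

Two caveats. The match family covers α in [0.025, 1.975]; series whose
fluctuation curve falls outside the family's shape (strong short-period
oscillation in the tachogram, e.g. dominant respiratory rhythm with
little noise) minimize at the grid boundary and are reported there —
such series are genuinely anti-persistent at the short-range scales, but
the single-α summary fits them poorly (see the naive slope in the
diagnostics). DFA is affine-invariant: α is unchanged under y → a·y + b.
Constant series raise a degenerate-series error rather than returning 0.

## Correlation dimension

Grassberger–Procaccia on the delay-embedded NN sequence: embedding
dimension m = 10, delay τ = 1, Euclidean distances, Theiler window m·τ
(temporally adjacent pairs excluded from counting). C(r) is accumulated
blockwise as a cumulative histogram over a geometric threshold grid
spanning [0.01, 2]·√m·SD (40 points). CD is the slope of log C(r) vs
log r over the small-r scaling region, delimited by
C(r) ∈ [10⁻³, 10⁻¹] and by requiring ≥ 10 pairs behind each fitted
point; if fewer than 3 grid points qualify the fit falls back to the
widest usable region and the result is flagged unreliable. The small-r
convention follows the standard prescription (slope taken where r is
small and pair counts still large): a noise-free limit cycle reads
CD ≈ 1, iid noise at m = 3 reads close to 3 within finite-sample bias.

## Recurrence Shannon entropy

From the same embedding, the recurrence criterion is Euclidean distance
≤ r with r = √m·SD by default (the common RQA radius convention for
this embedding family); diagonal lines of length ≥ lmin = 2 are
collected from all off-main diagonals, each maximal run contributing one
line of its full length. With p(ℓ) the fraction of lines of length ℓ,
SE = −Σ p(ℓ)·log₂ p(ℓ) in bits. SE is bounded by log₂(#distinct
lengths); a concentrated histogram gives 0 bits, uniform over 8 lengths
gives 3 bits. When no line is found the entropy is undefined and
reported as missing — never as 0, which would mean "perfectly regular".
The optimized implementation is held to exact agreement with a naive
O(N²) recurrence-matrix enumeration in the tests.

Nonlinear metrics are computed once per 3-h window on at most 5000 NN
intervals (uniform-stride subsampling beyond that) to bound the O(N²)
pair computations. Striding partially decoheres oscillations with
periods of a few beats; a contiguous-block alternative was considered
and rejected because it would make the "window" metric represent only
part of the window.

## Cosinor, deltas and group statistics

Rhythmicity of a metric's 24-h time course (3-h bin means at bin
midpoints) is tested by single-component cosinor with the period fixed
at 24 h: y(t) = M + A·cos(2π(t − φ)/24), fitted through the linearization
y = M + β₁cos ωt + β₂sin ωt by ordinary least squares, so the solution
is closed-form with no optimizer convergence ambiguity. A = √(β₁² + β₂²),
φ = atan2(β₂, β₁)/ω mod 24. The rhythm decision uses the zero-amplitude
F test (2 numerator dof against the constant model); "rhythmic" means
p < 0.05. The test is exactly sized under Gaussian noise (verified by
simulation); constant input returns amplitude 0 and p = 1. Fits are
time-shift equivariant (acrophase shifts, nothing else changes).

Morning−night contrast: Δ = mean of the [6,9) and [9,12) bin means minus
mean of the [0,3) and [3,6) bin means, computed per recording and then
compared across groups (unpaired t for two groups, one-way ANOVA for
more; means ± SEM reported).

Event timing: quartile counts are tested against uniformity with
Pearson's χ² (3 dof). Totals below 8 flag the asymptotic test as
unreliable (expected count < 2 per bin). The χ² ranking of outcomes
agrees closely, but not exactly, with the exact multinomial
likelihood-ratio ranking (Spearman ρ ≈ 0.97 over all compositions of
small totals) — they are different statistics, and the package uses χ².
Fold changes with a zero denominator are NaN-flagged, never raised.

Fractional shortening is the exact formula (LVEDD − LVESD)/LVEDD·100,
with LVESD ≥ LVEDD rejected as a physiology violation.

## The synthetic generator

Beat timing uses integral pulse frequency modulation: a beat is emitted
whenever the running integral of the instantaneous rate m(t) [beats/s]
crosses the next integer. IPFM is the standard generative link between
modulations of an input rate and spectral peaks of the output tachogram,
which is exactly the property the spectral tests need. m(t) combines:

* a 24-h cosine HR rhythm (mesor, amplitude in bpm, acrophase in clock
  hours);
* sinusoidal LF (0.10 Hz) and HF (0.25 Hz) fractional modulations; the
  LF depth can be circadian-gated (`lf_circ_frac`) to produce a daytime
  sympathetic rise and hence a morning LF/HF surge;
* a fractal component with power spectrum f^(−β), β = 2α − 1, synthesized
  spectrally (shaped amplitudes, uniform random phases, inverse FFT,
  rescaled to `fractal_sd` bpm) at 1 Hz and interpolated onto the
  integration grid — autonomic drive to the sinus node is band-limited,
  not beat-to-beat white.

The IPFM integral is accumulated on a 0.1-s grid with linear
interpolation at integer crossings, so the beat count over any interval
equals the rate integral within ±1 beat; timestamps are then quantized
to 1/125 s. A configuration whose rate touches zero raises an error
rather than silently rectifying.

Ectopy is superimposed on the all-normal stream by an inhomogeneous
Poisson process (thinning) with rate
r(t) = base·(1 + (fold − 1)·max(0, cos(2π(t − acrophase)/24))): a
half-wave-rectified cosine bump on a uniform floor, smooth and
analytically integrable, with a single fold parameter (peak/floor). Note
the realized quartile-count ratio [6,12)/[0,6) is a fixed function of
the fold parameter (≈ 1.84 at fold 2.5; fold ≈ 4.46 yields a realized
quartile ratio of 2.5). Isolated PVCs replace a normal beat with a `V`
beat at 60 % of the local RR (shortened coupling) while the next beat
stays put (compensatory pause) — the signature the exclusion logic must
recognise. VT episodes relabel a run of existing beats (length uniform
on [vt_len_min, vt_len_max], ≥ 3 by definition) without moving them.
Injection therefore never reorders timestamps and never changes the
recording duration. One master seed drives independent child generators
for the fractal component and the ectopy process.

### Reference cohorts

`cohorts.py` freezes two conditions used by the example pipeline, the
tests and the acceptance script. Baseline: 104 bpm mesor, 10 bpm
circadian amplitude at acrophase 12 h (morning−night ΔHR ≈ 12 bpm),
LF/HF depths 0.03 with strong LF gating, fractal α 0.9 at 6 bpm, no
ectopy. CHF: 87 bpm mesor (sinus-node dysfunction), amplitude 4.8
(ΔHR ≈ 6 bpm), reduced and nearly un-gated LF (blunted sympathovagal
oscillation), whitened and reduced fractal variability (α 0.46,
1.75 bpm), PVCs at 6/h with the morning profile (realized quartile fold
≈ 2.5) and VT at 0.5/h. These choices make the two cohorts separate in
the clinically expected directions on every reported index: lower ΔHR
and ΔLF/HF, lower α1/α2, lower correlation dimension, lower recurrence
entropy, and a χ²-significant morning ectopy surge in CHF.

### What the generator does not emulate

* Beat-to-beat dynamics are stochastic, not low-dimensional: the
  correlation dimension of simulated windows sits near 6–7 (noise-driven)
  instead of the 1–2 reported for real canine RR series, and recurrence
  entropies sit near 3.5–4 bits. Directional contrasts between cohorts
  are meaningful; absolute CD/SE levels are not calibrated to dogs.
* The stream-level DFA dial is faithful (monotone, near-unit slope) for
  configured α ∈ [0.3, 1.0]; above ≈ 1 the mapping saturates because the
  8-ms timing grid floors the small-scale fluctuations and the
  modulation is band-limited. The noise series itself recovers α within
  ±0.05 over the whole (0, 2) range.
* VT runs carry no rate acceleration (they are relabeled beats), atrial
  ectopy is only a label, and there is no QRS morphology, respiration
  signal or activity covariate.
* Ectopy density interacts with the NN exclusion rule: each PVC removes
  two NN intervals, so heavy ectopy thins and slightly whitens the NN
  series. Cohort ectopy rates were chosen low enough that this effect
  does not dominate the nonlinear indices.

## Problem sizes and determinism

Estimator oracles run at n = 8192 with 20 seeds (DFA), n = 2000 points
(CD), and 500-point series for the exact brute-force comparisons; test
calibrations use 500–2000 Monte-Carlo replicates; the cohort contrast
uses 4 recordings per group at full 24-h length. These sizes put every
Monte-Carlo tolerance at ≥ 2–3 standard errors while keeping the whole
suite desk-scale. All randomness flows from explicit seeds (the
acceptance script derives independent child streams from its `--seed`),
and a pipeline run is byte-reproducible given its config and seed.
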