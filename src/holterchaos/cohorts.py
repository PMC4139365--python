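"""Reference study cohorts for the synthetic generator.

Two named 24-h recording conditions used by the example pipeline, the test
suite and the acceptance script:

* ``baseline``: a healthy conscious dog — mean HR ≈ 104 bpm with a ≈10-bpm
  circadian swing peaking at noon (morning−night ΔHR ≈ 12 bpm), LF and HF
  sinus modulation with a daytime LF rise (morning LF/HF surge), strongly
  persistent fractal variability, and no ventricular ectopy.

* ``chf``: chronic heart failure — lower mean HR (87 bpm, sinus-node
  dysfunction), flattened circadian amplitude (ΔHR ≈ 6 bpm), reduced and
  un-gated LF drive (blunted sympathovagal oscillation, lower LF/HF),
  reduced and whitened fractal variability (loss of fractal persistence
  and of beat-stream complexity), and a morning-peaked burden of PVCs and
  VT episodes.

The ectopy profile parameter is the peak/floor ratio of the instantaneous
event rate; ``chf`` uses 4.46 so that the realized quartile count ratio
(6 AM–noon vs midnight–6 AM) of the half-wave-rectified-cosine profile is
≈2.5, the canonical morning-surge fold for PVCs.
"""

from __future__ import annotations

from .synthetic import SimConfig

__all__ = ["baseline_config", "chf_config"]


def baseline_config(seed: int = 0) -> SimConfig:
    """Healthy-condition generator settings (no ectopy)."""
    return SimConfig(
        hr_mesor=104.0,
        hr_circ_amplitude=10.0,
        hr_acrophase=12.0,
        lf_depth=0.03,
        hf_depth=0.03,
        lf_circ_frac=0.8,
        fractal_alpha=0.9,
        fractal_sd=6.0,
        seed=seed,
    )


def chf_config(seed: int = 0) -> SimConfig:
    """Chronic-heart-failure generator settings with morning-surge ectopy."""
    return SimConfig(
        hr_mesor=87.0,
        hr_circ_amplitude=4.8,
        hr_acrophase=12.0,
        lf_depth=0.02,
        hf_depth=0.03,
        lf_circ_frac=0.1,
        fractal_alpha=0.46,
        fractal_sd=1.75,
        pvc_base_rate=6.0,
        pvc_morning_fold=4.46,
        pvc_acrophase=9.0,
        vt_rate=0.5,
        seed=seed,
    )
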