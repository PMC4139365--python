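"""End-to-end Holter analysis pipeline.

Orchestrates: beat input (files or the synthetic generator) → NN-series
construction → clock-aligned windowing → per-window linear and nonlinear
HRV plus arrhythmia counts → morning-vs-night deltas, cosinor rhythm
calls, χ² event-timing tests and group comparisons.  Outputs are tidy
pandas tables plus a JSON manifest (config hash, seed, versions) so a run
is fully reproducible from its config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .arrhythmia import chi2_uniformity, classify_ventricular, fold_change
from .beats import BeatStream, NNSeries, build_nn, read_beats, segment
from .errors import InsufficientDataError, ParameterError
from .linear import time_domain, window_spectral
from .nonlinear import nonlinear_summary
from .rhythm import CosinorFit, cosinor_fit, delta_metric, group_compare
from .synthetic import SimConfig, simulate

#: Metrics carried through delta / cosinor / group statistics.
RHYTHM_METRICS = ("mean_hr", "sdnn", "cv", "rmssd", "lf_hf",
                  "dfa_alpha1", "dfa_alpha2", "cd", "se")


@dataclass
class AnalysisParams:
    """Tunable analysis parameters (defaults follow standard HRV practice)."""

    bin_h: float = 3.0
    nn_bounds_ms: tuple[float, float] = (200.0, 3000.0)
    resample_fs: float = 4.0
    ar_order: int = 16
    spectral_segment_s: float = 300.0
    embedding_m: int = 10
    delay: int = 1
    lmin: int = 2
    max_nl_points: int = 5000


@dataclass
class RunConfig:
    """A fully parameterized pipeline run.

    ``groups`` maps a group name to either a list of beat-file paths or a
    dict ``{"sim": {...SimConfig fields...}, "n_subjects": k}``.
    """

    groups: dict
    params: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        params = AnalysisParams(**data.get("params", {}))
        if "nn_bounds_ms" in data.get("params", {}):
            params.nn_bounds_ms = tuple(params.nn_bounds_ms)
        return cls(groups=data["groups"], params=params,
                   seed=int(data.get("seed", 0)), out_dir=data.get("out_dir"))

    def canonical(self) -> str:
        d = {"groups": self.groups, "params": asdict(self.params),
             "seed": self.seed}
        return json.dumps(d, sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Tidy output tables of one pipeline run."""

    window_metrics: pd.DataFrame
    deltas: pd.DataFrame
    cosinor: pd.DataFrame
    timing: pd.DataFrame
    group_tests: pd.DataFrame
    manifest: dict

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("window_metrics", "deltas", "cosinor", "timing",
                     "group_tests"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        return out


def subject_seed(master_seed: int, group: str, index: int) -> int:
    """Stable per-subject seed derived from the master seed (< 2^31)."""
    h = hashlib.sha256(f"{master_seed}:{group}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def materialize_groups(config: RunConfig) -> dict[str, list[BeatStream]]:
    """Load or simulate every recording declared in the config."""
    out: dict[str, list[BeatStream]] = {}
    for group, spec in config.groups.items():
        streams: list[BeatStream] = []
        if isinstance(spec, dict) and "sim" in spec:
            n = int(spec.get("n_subjects", 1))
            for i in range(n):
                sim = SimConfig(**{**spec["sim"],
                                   "seed": subject_seed(config.seed, group, i)})
                s = simulate(sim)
                s.record_id = f"{group}_{i:02d}"
                streams.append(s)
        elif isinstance(spec, (list, tuple)):
            for p in spec:
                streams.append(read_beats(p))
        else:
            raise ParameterError(
                f"group {group!r}: expected a path list or a 'sim' block"
            )
        out[group] = streams
    return out


def analyze_recording(stream: BeatStream, params: AnalysisParams) -> pd.DataFrame:
    """Per-window metric table (one row per clock window) for one recording.

    Window metrics that cannot be computed (too few NN intervals, unusable
    spectra, degenerate series) are NaN rather than fatal.
    """
    nn = build_nn(stream, bounds_ms=params.nn_bounds_ms)
    windows = segment(stream, nn, bin_h=params.bin_h)
    counts = classify_ventricular(stream, bin_h=params.bin_h)
    n_raw = len(stream) - 1
    pct_excluded = 100.0 * nn.n_excluded / n_raw if n_raw else float("nan")
    rows = []
    for w in windows:
        row = {
            "recording": stream.record_id,
            "window_start_h": w.start_h,
            "window_end_h": w.end_h,
            "n_nn": w.n_nn,
            "pct_excluded_recording": pct_excluded,
        }
        wc = counts.per_window.get(w.start_h, (0, 0, 0))
        row.update({"pvc": wc[0], "vt_episodes": wc[1], "vt_beats": wc[2]})
        for k in ("mean_hr", "mean_rr", "sdnn", "cv", "rmssd", "lf", "hf",
                  "lf_hf", "dfa_alpha1", "dfa_alpha2", "cd", "se"):
            row[k] = float("nan")
        if w.n_nn >= 2:
            wnn = NNSeries(w.nn_onsets_s, w.nn_ms, stream.record_id,
                           stream.start_clock_h)
            td = time_domain(wnn)
            row.update(mean_hr=td.mean_hr, mean_rr=td.mean_rr, sdnn=td.sdnn,
                       cv=td.cv, rmssd=td.rmssd)
            spec = window_spectral(wnn, fs=params.resample_fs,
                                   order=params.ar_order,
                                   segment_s=params.spectral_segment_s)
            if spec is not None:
                row.update(lf=spec.lf_power, hf=spec.hf_power,
                           lf_hf=spec.lf_hf_ratio)
            nl = nonlinear_summary(w.nn_ms, m=params.embedding_m,
                                   tau=params.delay, lmin=params.lmin,
                                   max_points=params.max_nl_points)
            row.update(dfa_alpha1=nl.dfa_alpha1, dfa_alpha2=nl.dfa_alpha2,
                       cd=nl.cd, se=nl.se)
        rows.append(row)
    return pd.DataFrame(rows)


def _delta_table(win: pd.DataFrame) -> pd.DataFrame:
    """Per-recording morning−night deltas for every rhythm metric."""
    rows = []
    for (group, rec), sub in win.groupby(["group", "recording"], sort=True):
        bins = dict(zip(sub["window_start_h"], sub.index))
        for metric in RHYTHM_METRICS:
            means = {h: float(sub.loc[i, metric]) for h, i in bins.items()}
            try:
                dm = delta_metric(means, metric)
            except ParameterError:
                continue
            if np.isnan(dm.morning_mean) or np.isnan(dm.night_mean):
                continue
            rows.append({"group": group, "recording": rec, "metric": metric,
                         "morning_mean": dm.morning_mean,
                         "night_mean": dm.night_mean, "delta": dm.delta})
    return pd.DataFrame(rows)


def _cosinor_table(win: pd.DataFrame, period: float = 24.0) -> pd.DataFrame:
    """Per-recording cosinor fit of each metric's window-mean time course."""
    rows = []
    for (group, rec), sub in win.groupby(["group", "recording"], sort=True):
        mid = sub["window_start_h"] + (sub["window_end_h"] - sub["window_start_h"]) / 2
        for metric in RHYTHM_METRICS:
            y = sub[metric].to_numpy(dtype=float)
            t = mid.to_numpy(dtype=float)
            ok = ~np.isnan(y)
            if int(ok.sum()) < 6:
                continue
            fit: CosinorFit = cosinor_fit(t[ok], y[ok], period=period)
            rows.append({
                "group": group, "recording": rec, "metric": metric,
                "mesor": fit.mesor, "amplitude": fit.amplitude,
                "acrophase_h": fit.acrophase, "p_rhythm": fit.p_rhythm,
                "rhythmic": bool(fit.rhythmic),
            })
    return pd.DataFrame(rows)


def _timing_table(streams: dict[str, list[BeatStream]],
                  bin_h: float) -> pd.DataFrame:
    """Pooled per-group quartile counts, χ² uniformity test, quartile folds."""
    rows = []
    for group, ss in streams.items():
        pooled = {"pvc": np.zeros(4, int), "vt_episodes": np.zeros(4, int),
                  "vt_beats": np.zeros(4, int)}
        for s in ss:
            counts = classify_ventricular(s, bin_h=bin_h)
            for what in pooled:
                pooled[what] += counts.quartile_counts(what)
        for what, q in pooled.items():
            row = {"group": group, "event": what,
                   "q_00_06": int(q[0]), "q_06_12": int(q[1]),
                   "q_12_18": int(q[2]), "q_18_24": int(q[3]),
                   "chi2": float("nan"), "p_value": float("nan"),
                   "morning_fold": float("nan"), "low_count": True}
            if q.sum() >= 1:
                res = chi2_uniformity(q)
                folds = fold_change(q)
                row.update(chi2=res.chi2_statistic, p_value=res.p_value,
                           morning_fold=folds["morning_fold"],
                           low_count=res.low_count_warning)
            rows.append(row)
    return pd.DataFrame(rows)


def _group_tests(win: pd.DataFrame, deltas: pd.DataFrame) -> pd.DataFrame:
    """Across-group tests on 24-h means and on morning−night deltas."""
    groups = sorted(win["group"].unique())
    if len(groups) < 2:
        return pd.DataFrame()
    rows = []
    day_means = (win.groupby(["group", "recording"])[list(RHYTHM_METRICS)]
                 .mean().reset_index())
    for metric in RHYTHM_METRICS:
        for label, table, col in (("mean_24h", day_means, metric),
                                  ("delta", deltas, "delta")):
            if label == "delta":
                table = deltas[deltas["metric"] == metric]
                if table.empty:
                    continue
            vals = [table[table["group"] == g][col].dropna().to_numpy()
                    for g in groups]
            if any(v.size < 2 for v in vals):
                continue
            cmp = group_compare(*vals)
            row = {"metric": metric, "quantity": label, "test": cmp.test,
                   "statistic": cmp.statistic, "p_value": cmp.p_value}
            for g, mu, sem in zip(groups, cmp.group_means, cmp.group_sems):
                row[f"mean_{g}"] = mu
                row[f"sem_{g}"] = sem
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig,
                 streams: dict[str, list[BeatStream]] | None = None
                 ) -> PipelineResult:
    """Run the full analysis described by ``config``.

    ``streams`` may be passed to reuse already-materialized recordings
    (e.g. in-memory streams); otherwise they are loaded/simulated from the
    config.
    """
    if streams is None:
        streams = materialize_groups(config)
    win_parts = []
    for group, ss in streams.items():
        for s in ss:
            try:
                df = analyze_recording(s, config.params)
            except InsufficientDataError as e:
                raise InsufficientDataError(
                    f"stage window-metrics failed for {s.record_id}: {e}"
                ) from e
            df.insert(0, "group", group)
            win_parts.append(df)
    win = pd.concat(win_parts, ignore_index=True)
    deltas = _delta_table(win)
    cosinor = _cosinor_table(win)
    timing = _timing_table(streams, config.params.bin_h)
    gtests = _group_tests(win, deltas)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "holterchaos_version": __version__,
        "numpy_version": np.__version__,
        "n_recordings": int(sum(len(v) for v in streams.values())),
    }
    result = PipelineResult(win, deltas, cosinor, timing, gtests, manifest)
    if config.out_dir:
        result.save(config.out_dir)
    return result
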