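"""Beat-annotation containers and I/O.

A Holter analysis starts from an exported beat list: a time stamp (seconds
from recording start) and a beat label per detected QRS complex.  Labels
follow the usual annotation alphabet: ``N`` normal (sinus), ``V``
ventricular ectopic, ``A`` atrial ectopic, ``X`` artifact/unknown.

This module reads and writes those beat lists, derives the normal-to-normal
(NN) interval series that every HRV statistic is computed on, and cuts a
recording into clock-aligned analysis windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InsufficientDataError, ParameterError

#: Recognised beat labels.
VALID_LABELS = ("N", "V", "A", "X")

#: Holter timing grid (s): exported annotations are quantized to 1/125 s.
TICK_S = 1.0 / 125.0

#: Default physiological NN bounds (ms): intervals outside are artifacts.
DEFAULT_NN_BOUNDS_MS = (200.0, 3000.0)


def quantize_times(times_s: np.ndarray) -> np.ndarray:
    """Snap times (s) onto the 1/125-s digitization grid."""
    return np.round(np.asarray(times_s, dtype=float) * 125.0) / 125.0


@dataclass
class BeatStream:
    """A timestamped, labeled 24-h (or shorter) beat sequence.

    Parameters
    ----------
    times_s : ndarray
        Beat times in seconds from recording start, strictly increasing,
        representable on the 1/125-s grid.
    labels : ndarray of str
        One of ``N``, ``V``, ``A``, ``X`` per beat.
    record_id : str
        Identifier of the recording.
    start_clock_h : float
        Wall-clock hour of recording start in ``[0, 24)`` (0 = midnight).
    duration_s : float
        Nominal recording duration in seconds.
    """

    times_s: np.ndarray
    labels: np.ndarray
    record_id: str = "rec"
    start_clock_h: float = 0.0
    duration_s: float | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.labels = np.asarray(self.labels, dtype="U1")
        if self.times_s.shape != self.labels.shape:
            raise ParameterError("times_s and labels must have equal length")
        if self.times_s.size and np.any(np.diff(self.times_s) <= 0):
            i = int(np.argmax(np.diff(self.times_s) <= 0))
            raise FormatError(f"beat times not strictly increasing at index {i + 1}")
        bad = ~np.isin(self.labels, VALID_LABELS)
        if np.any(bad):
            raise FormatError(f"invalid beat label {self.labels[bad][0]!r}")
        if self.duration_s is None:
            self.duration_s = float(self.times_s[-1]) if self.times_s.size else 0.0

    def __len__(self) -> int:
        return int(self.times_s.size)

    @property
    def clock_h(self) -> np.ndarray:
        """Wall-clock hour in [0, 24) of each beat."""
        return (self.start_clock_h + self.times_s / 3600.0) % 24.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times_s, "label": self.labels})

    def relabel(self, mapping: dict[str, str]) -> "BeatStream":
        """Return a copy with labels mapped through ``mapping``."""
        new = np.array([mapping.get(l, l) for l in self.labels], dtype="U1")
        return BeatStream(self.times_s.copy(), new, self.record_id,
                          self.start_clock_h, self.duration_s)


@dataclass
class NNSeries:
    """Normal-to-normal RR intervals after ectopic/artifact exclusion.

    ``onsets_s[i]`` is the time of the first (opening) N beat of interval
    ``i``; ``nn_ms[i]`` its duration.  ``exclusions`` logs how many raw
    intervals were removed and why.
    """

    onsets_s: np.ndarray
    nn_ms: np.ndarray
    source_id: str = "rec"
    start_clock_h: float = 0.0
    exclusions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        self.nn_ms = np.asarray(self.nn_ms, dtype=float)
        if np.any(self.nn_ms <= 0):
            raise ParameterError("all NN intervals must be positive")
        if self.onsets_s.size > 1 and np.any(np.diff(self.onsets_s) <= 0):
            raise ParameterError("NN onsets must be strictly increasing")

    def __len__(self) -> int:
        return int(self.nn_ms.size)

    @property
    def clock_h(self) -> np.ndarray:
        return (self.start_clock_h + self.onsets_s / 3600.0) % 24.0

    @property
    def n_excluded(self) -> int:
        return int(sum(self.exclusions.values()))

    def exclusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"reason": list(self.exclusions), "count": list(self.exclusions.values())}
        )


@dataclass
class Window:
    """A half-open clock-aligned analysis window ``[start_h, end_h)``.

    Holds index slices into the parent stream / NN series rather than
    copies, plus convenience views.
    """

    start_h: float
    end_h: float
    nn_onsets_s: np.ndarray
    nn_ms: np.ndarray
    beat_times_s: np.ndarray
    beat_labels: np.ndarray

    @property
    def label(self) -> str:
        return f"{int(self.start_h):02d}-{int(self.end_h):02d}"

    @property
    def n_nn(self) -> int:
        return int(self.nn_ms.size)


# ---------------------------------------------------------------------------
# I/O


def write_beats(stream: BeatStream, path: str | Path) -> Path:
    """Write a beat stream as CSV with header ``time_s,label``.

    Times are written with millisecond-plus precision (1/125 s = 8 ms grid,
    6 decimals are exact for it) so that a round trip through
    :func:`read_beats` reproduces the stream.
    """
    path = Path(path)
    df = stream.to_frame()
    df["time_s"] = df["time_s"].map(lambda t: f"{t:.6f}")
    df.to_csv(path, index=False)
    return path


def read_beats(
    path: str | Path,
    dialect: str = "csv",
    record_id: str | None = None,
    start_clock_h: float = 0.0,
) -> BeatStream:
    """Read a beat-annotation file into a :class:`BeatStream`.

    Parameters
    ----------
    dialect : {"csv", "ann"}
        ``csv``: header ``time_s,label``.  ``ann``: whitespace-separated
        two-column text (time in seconds, annotation symbol), the layout of
        text dumps of WFDB-style annotation files.
    """
    path = Path(path)
    if dialect == "csv":
        df = pd.read_csv(path, dtype={"time_s": float, "label": str})
        if not {"time_s", "label"}.issubset(df.columns):
            raise FormatError(f"{path}: expected columns time_s,label")
        times = df["time_s"].to_numpy(dtype=float)
        labels = df["label"].astype(str).to_numpy()
    elif dialect == "ann":
        rows = []
        for ln in path.read_text().splitlines():
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split()
            if len(parts) < 2:
                raise FormatError(f"{path}: malformed annotation line {ln!r}")
            rows.append((float(parts[0]), parts[1]))
        times = np.array([r[0] for r in rows], dtype=float)
        labels = np.array([r[1] for r in rows], dtype=str)
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")

    labels = np.array([l[:1].upper() for l in labels], dtype="U1")
    unknown = ~np.isin(labels, VALID_LABELS)
    if np.any(unknown):
        warnings.warn(
            f"{path}: {int(unknown.sum())} unknown beat labels mapped to X",
            stacklevel=2,
        )
        labels = np.where(unknown, "X", labels)
    if times.size and np.any(np.diff(times) <= 0):
        i = int(np.argmax(np.diff(times) <= 0)) + 1
        raise FormatError(f"{path}: non-monotone timestamp at data row {i}")
    return BeatStream(times, labels, record_id or path.stem, start_clock_h)


# ---------------------------------------------------------------------------
# NN construction and windowing


def build_nn(
    stream: BeatStream,
    bounds_ms: tuple[float, float] = DEFAULT_NN_BOUNDS_MS,
) -> NNSeries:
    """Derive the NN-interval series, excluding ectopy-adjacent intervals.

    An RR interval is retained iff both bounding beats are labeled ``N``
    and its duration lies within ``bounds_ms``.  Both intervals touching a
    ``V``/``A``/``X`` beat are therefore removed: an ectopic beat corrupts
    the interval it ends as well as the one it starts.  Removed intervals
    are dropped, never interpolated.
    """
    if len(stream) < 3:
        raise InsufficientDataError("need at least 3 beats to build an NN series")
    t = stream.times_s
    lab = stream.labels
    rr_ms = np.diff(t) * 1000.0
    both_n = (lab[:-1] == "N") & (lab[1:] == "N")
    in_bounds = (rr_ms >= bounds_ms[0]) & (rr_ms <= bounds_ms[1])
    keep = both_n & in_bounds
    exclusions = {
        "ectopic_adjacent": int(np.sum(~both_n)),
        "out_of_bounds": int(np.sum(both_n & ~in_bounds)),
    }
    if int(keep.sum()) < 2:
        raise InsufficientDataError(
            f"fewer than 2 NN intervals retained ({int(keep.sum())})"
        )
    return NNSeries(
        onsets_s=t[:-1][keep],
        nn_ms=rr_ms[keep],
        source_id=stream.record_id,
        start_clock_h=stream.start_clock_h,
        exclusions=exclusions,
    )


def segment(stream: BeatStream, nn: NNSeries, bin_h: float = 3.0) -> list[Window]:
    """Cut a recording into clock-aligned half-open windows tiling 24 h.

    Each NN interval is assigned to the window containing its onset; beats
    likewise.  An onset exactly on a boundary belongs to the later window
    (half-open convention).
    """
    if bin_h <= 0 or abs(24.0 / bin_h - round(24.0 / bin_h)) > 1e-9:
        raise ParameterError(f"bin width {bin_h} h does not divide 24 h")
    n_win = int(round(24.0 / bin_h))
    beat_clock = stream.clock_h
    nn_clock = nn.clock_h
    windows = []
    for k in range(n_win):
        lo, hi = k * bin_h, (k + 1) * bin_h
        bsel = (beat_clock >= lo) & (beat_clock < hi)
        nsel = (nn_clock >= lo) & (nn_clock < hi)
        windows.append(
            Window(
                start_h=lo,
                end_h=hi,
                nn_onsets_s=nn.onsets_s[nsel],
                nn_ms=nn.nn_ms[nsel],
                beat_times_s=stream.times_s[bsel],
                beat_labels=stream.labels[bsel],
            )
        )
    return windows
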