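"""Polysome-gradient trace segmentation and the polysome/monosome ratio.

A sucrose-gradient A254 trace shows, in order of depth, the ribosomal
subunit peaks, the 80S monosome, then 2-some, 3-some, ... polysome peaks.
The P/M ratio — area under the polysome region (4-somes and up) over the
area under the 80S monosome peak, both baseline-subtracted — summarizes
global translation: stress that blocks initiation collapses polysomes
into monosomes and drives P/M down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import trapezoid
from scipy.signal import find_peaks


@dataclass
class PolysomeTrace:
    positions: np.ndarray  # gradient depth, arbitrary units, strictly increasing
    absorbance: np.ndarray  # A254, arbitrary units

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.absorbance.shape:
            raise ValueError("positions and absorbance must be 1-D and equal length")
        if not (np.diff(self.positions) > 0).all():
            raise ValueError("positions must be strictly increasing")
        if not np.isfinite(self.absorbance).all():
            raise ValueError("non-finite absorbance")

    @classmethod
    def from_csv(cls, path, sep: str | None = None) -> "PolysomeTrace":
        arr = np.loadtxt(path, delimiter=sep, ndmin=2)
        if arr.shape[1] < 2:
            raise ValueError("trace file must have two columns: position, absorbance")
        return cls(arr[:, 0], arr[:, 1])


@dataclass
class TraceSegmentation:
    """Monosome interval [mono_start, mono_end] and polysome start, in
    position units; the polysome region runs to the end of the trace."""

    mono_start: float
    mono_end: float
    poly_start: float
    baseline: float

    def __post_init__(self) -> None:
        if not (self.mono_start < self.mono_end <= self.poly_start):
            raise ValueError("require mono_start < mono_end <= poly_start")


def segment_trace(
    trace: PolysomeTrace,
    prominence_frac: float = 0.05,
    boundaries: tuple[float, float, float] | None = None,
) -> TraceSegmentation:
    """Locate the 80S monosome interval and the >=4-some polysome start.

    Manual mode: ``boundaries`` = (mono_start, mono_end, poly_start) is
    passed through verbatim. Automatic mode: peaks are local maxima with
    prominence above ``prominence_frac`` of the absorbance range; the
    monosome is the highest peak in the first half of the trace, and the
    polysome (>=4-some) region starts at the valley after the 3-some,
    the second peak following the monosome. Requires at least 4 peaks
    (80S, 2-some, 3-some, polysomes).
    """
    baseline = float(trace.absorbance.min())
    if boundaries is not None:
        a, b, c = boundaries
        return TraceSegmentation(a, b, c, baseline)
    span = float(trace.absorbance.max() - trace.absorbance.min())
    if span == 0:
        raise ValueError("flat trace: no peaks; supply manual boundaries")
    peaks, _ = find_peaks(trace.absorbance, prominence=prominence_frac * span)
    half = len(trace.positions) // 2
    first_half_peaks = peaks[peaks < half]
    if len(first_half_peaks) == 0 or len(peaks) < 4:
        raise ValueError(
            f"found {len(peaks)} peak(s); need >= 4 (80S, 2-, 3-somes, polysomes) — "
            "supply manual boundaries"
        )
    mono_idx = first_half_peaks[np.argmax(trace.absorbance[first_half_peaks])]
    after = peaks[peaks > mono_idx]
    if len(after) < 3:
        raise ValueError("fewer than 3 peaks after the monosome; supply manual boundaries")

    def _valley(i: int, j: int) -> int:
        return i + int(np.argmin(trace.absorbance[i : j + 1]))

    before = peaks[peaks < mono_idx]
    mono_start_idx = _valley(before[-1], mono_idx) if len(before) else 0
    mono_end_idx = _valley(mono_idx, after[0])
    # 2-some, 3-some, then polysomes: the >=4-some region opens at the
    # valley between the 3-some (after[1]) and the first polysome peak
    poly_start_idx = _valley(after[1], after[2])
    return TraceSegmentation(
        mono_start=float(trace.positions[mono_start_idx]),
        mono_end=float(trace.positions[mono_end_idx]),
        poly_start=float(trace.positions[poly_start_idx]),
        baseline=baseline,
    )


def _area(trace: PolysomeTrace, lo: float, hi: float, baseline: float) -> float:
    mask = (trace.positions >= lo) & (trace.positions <= hi)
    if mask.sum() < 2:
        raise ValueError(f"region [{lo}, {hi}] covers fewer than 2 samples")
    return float(
        trapezoid(trace.absorbance[mask] - baseline, trace.positions[mask])
    )


def pm_ratio(trace: PolysomeTrace, seg: TraceSegmentation) -> float:
    """Polysome AUC (poly_start to end of trace) over monosome AUC, both
    baseline-subtracted, by trapezoidal integration."""
    mono = _area(trace, seg.mono_start, seg.mono_end, seg.baseline)
    poly = _area(trace, seg.poly_start, float(trace.positions[-1]), seg.baseline)
    if mono <= 0:
        raise ValueError("monosome area is non-positive; check segmentation/baseline")
    return poly / mono
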