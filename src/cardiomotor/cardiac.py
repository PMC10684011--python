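"""ECG processing and cardiac-phase classification.

Systole is operationalized as the interval from the R-peak to the end of
the T-wave; a diastolic window of exactly the same length is placed at the
end of the cardiac cycle, so that an event falling at a uniformly random
time is equally likely to land in either window.  T-wave end is delineated
with a trapezoid-area algorithm: given the T-peak ``(x_m, y_m)`` and a
reference point ``x_r`` placed on the flat segment after the wave, the
T-end is the sample ``x_i`` between them that maximizes the area

    A(i) = 0.5 * (y_m - y_i) * (2 * x_r - x_i - x_m).

The module also provides R-peak detection, TMS-artifact interpolation on
the ECG, and interbeat-interval (IBI) dynamics around stimulation events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .core_io import EventList
from .exceptions import DetectionError, ParameterError

REFRACTORY_S = 0.25


# ---------------------------------------------------------------------------
# stimulus-artifact interpolation
# ---------------------------------------------------------------------------

def interpolate_stim_artifact_ecg(
    ecg: np.ndarray,
    rate: float,
    event_times: np.ndarray,
    window_ms: tuple[float, float] = (-2.0, 10.0),
    n_anchor: int = 8,
) -> np.ndarray:
    """Replace samples around each event by cubic interpolation.

    The window (default -2 to 10 ms around the event) is removed and
    re-filled with a cubic spline fitted to ``n_anchor`` flanking samples on
    each side.  Overlapping windows are merged; windows at the record edge
    fall back to nearest-value extension.  All other samples are returned
    bit-identical.
    """
    out = np.array(ecg, dtype=float, copy=True)
    n = out.size
    event_times = np.atleast_1d(np.asarray(event_times, dtype=float))
    if event_times.size == 0:
        return out
    spans = []
    for t in np.sort(event_times):
        i0 = int(np.floor((t + window_ms[0] / 1000.0) * rate))
        i1 = int(np.ceil((t + window_ms[1] / 1000.0) * rate)) + 1
        i0, i1 = max(i0, 0), min(i1, n)
        if i1 <= i0:
            continue
        if spans and i0 <= spans[-1][1]:
            spans[-1] = (spans[-1][0], max(spans[-1][1], i1))
        else:
            spans.append((i0, i1))
    for i0, i1 in spans:
        left = np.arange(max(i0 - n_anchor, 0), i0)
        right = np.arange(i1, min(i1 + n_anchor, n))
        anchors = np.concatenate([left, right])
        if left.size == 0 or right.size == 0:
            # record edge: extend the nearest anchored value
            fill = out[right[0]] if left.size == 0 else out[left[-1]]
            out[i0:i1] = fill
            continue
        spline = CubicSpline(anchors, out[anchors])
        out[i0:i1] = spline(np.arange(i0, i1))
    return out


# ---------------------------------------------------------------------------
# R-peak detection
# ---------------------------------------------------------------------------

def detect_r_peaks(ecg: np.ndarray, rate: float) -> np.ndarray:
    """Detect R-peak times (seconds).

    Band-pass emphasis of the QRS (5-30 Hz), automatic polarity correction,
    amplitude-thresholded peak picking with a 250 ms refractory period, and
    refinement to the local extremum of the corrected raw trace.  Raises
    :class:`DetectionError` when no physiologically plausible beat sequence
    is found (degenerate input such as white noise or a flat trace).
    """
    ecg = np.asarray(ecg, dtype=float)
    if ecg.size < 5 * rate:
        raise ParameterError("need at least 5 s of ECG")
    sos = sps.butter(2, (5.0, min(30.0, 0.45 * rate)), btype="bandpass",
                     fs=rate, output="sos")
    f = sps.sosfiltfilt(sos, ecg - np.median(ecg))
    if np.abs(f.min()) > np.abs(f.max()):
        f = -f
        raw = -(ecg - np.median(ecg))
    else:
        raw = ecg - np.median(ecg)

    height = 0.5 * np.percentile(f, 99.5)
    noise = 1.4826 * np.median(np.abs(f - np.median(f)))
    if height <= 0 or (noise > 0 and height < 4 * noise):
        raise DetectionError("no QRS-like activity above the noise floor")
    peaks, _ = sps.find_peaks(f, height=height,
                              distance=int(REFRACTORY_S * rate))
    if peaks.size < 2:
        raise DetectionError("fewer than two R-peaks detected")
    # refine on the polarity-corrected raw trace
    half = int(0.025 * rate)
    refined = []
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half + 1, raw.size)
        refined.append(lo + int(np.argmax(raw[lo:hi])))
    times = np.unique(np.asarray(refined)) / rate
    rr = np.diff(times)
    if np.median(rr) < 0.3 or np.median(rr) > 2.0:
        raise DetectionError(
            f"implausible median RR interval {np.median(rr):.3f} s")
    return times


# ---------------------------------------------------------------------------
# T-wave end (trapezoid-area algorithm)
# ---------------------------------------------------------------------------

def detect_t_end(
    ecg: np.ndarray,
    r_peaks: np.ndarray,
    rate: float,
    search_ms: tuple[float, float] = (80.0, 450.0),
    ref_offset_ms: float = 120.0,
    min_prominence_uv: float = 40.0,
) -> np.ndarray:
    """Per-beat T-wave end times via trapezoid-area maximization.

    For each beat, the T-peak is the largest-magnitude deflection from the
    local baseline inside ``search_ms`` after the R-peak (clipped before the
    next R).  The reference point ``x_r`` sits ``ref_offset_ms`` beyond the
    search bound, clipped to 10 ms before the next R-peak.  Beats whose T
    deflection is below ``min_prominence_uv`` are returned as NaN
    (unusable).  Ties in the area are broken toward the earliest sample.
    """
    ecg = np.asarray(ecg, dtype=float)
    r_peaks = np.asarray(r_peaks, dtype=float)
    t_ends = np.full(r_peaks.size, np.nan)
    for k, r in enumerate(r_peaks):
        next_r = r_peaks[k + 1] if k + 1 < r_peaks.size else np.inf
        s0 = int(round((r + search_ms[0] / 1000.0) * rate))
        s1 = int(round((r + search_ms[1] / 1000.0) * rate))
        if np.isfinite(next_r):
            s1 = min(s1, int((next_r - 0.020) * rate))
        s1 = min(s1, ecg.size - 1)
        if s1 <= s0 + 2:
            continue
        seg = ecg[s0:s1]
        baseline = np.median(seg)
        dev = seg - baseline
        m_rel = int(np.argmax(np.abs(dev)))
        if np.abs(dev[m_rel]) < min_prominence_uv:
            continue  # flat T -> unusable
        sign = 1.0 if dev[m_rel] >= 0 else -1.0
        x_m = s0 + m_rel
        y = sign * ecg  # work on the positive-wave convention

        x_r = int(round((r + (search_ms[1] + ref_offset_ms) / 1000.0) * rate))
        if np.isfinite(next_r):
            x_r = min(x_r, int((next_r - 0.010) * rate))
        x_r = min(x_r, ecg.size - 1)
        if x_r <= x_m + 2:
            continue
        xi = np.arange(x_m + 1, x_r)
        area = 0.5 * (y[x_m] - y[xi]) * (2 * x_r - xi - x_m)
        best = xi[int(np.argmax(area))]  # argmax -> earliest on ties
        t_ends[k] = best / rate
    return t_ends


# ---------------------------------------------------------------------------
# cardiac map
# ---------------------------------------------------------------------------

@dataclass
class CardiacMap:
    """Per-beat systole/diastole windows of exactly equal length.

    ``systole`` spans ``[r_time, t_end]``; ``diastole`` spans
    ``[next_r - L, next_r]`` with ``L = t_end - r_time``.  A beat is usable
    only when the T-end was found, a next beat exists, and ``rr > 2 L`` so
    the two windows are disjoint.
    """

    r_time: np.ndarray
    t_end: np.ndarray
    rr: np.ndarray
    usable: np.ndarray

    @property
    def n_beats(self) -> int:
        return self.r_time.size

    @property
    def systole_len(self) -> np.ndarray:
        return self.t_end - self.r_time

    def diastole_start(self) -> np.ndarray:
        return self.r_time + self.rr - self.systole_len


def build_cardiac_map(r_peaks: np.ndarray, t_ends: np.ndarray) -> CardiacMap:
    r_peaks = np.asarray(r_peaks, dtype=float)
    t_ends = np.asarray(t_ends, dtype=float)
    if r_peaks.shape != t_ends.shape:
        raise ParameterError("r_peaks and t_ends must be aligned")
    n = r_peaks.size
    rr = np.full(n, np.nan)
    if n > 1:
        rr[:-1] = np.diff(r_peaks)
    L = t_ends - r_peaks
    with np.errstate(invalid="ignore"):
        usable = np.isfinite(t_ends) & np.isfinite(rr) & (L > 0) & (rr > 2 * L)
    return CardiacMap(r_peaks, t_ends, rr, usable)


def classify_events(events: EventList, cmap: CardiacMap) -> EventList:
    """Attach cardiac-phase labels and distance-from-R to every event.

    Each event becomes ``systole`` if it falls inside ``[R, t_end]`` of a
    usable beat, ``diastole`` if inside the equal-length window ending at
    the next R, and ``neither`` otherwise (including events outside beat
    coverage, which additionally carry ``outside_map=True``).
    ``distance_ms`` from the immediately preceding R-peak is recorded for
    every event inside coverage.
    """
    out_meta = []
    dia0 = cmap.diastole_start()
    for t in events.times:
        i = int(np.searchsorted(cmap.r_time, t, side="right")) - 1
        m: dict = {"phase": "neither", "distance_ms": None}
        last = cmap.n_beats - 1
        if i < 0 or i > last or (i == last):
            m["outside_map"] = True
        else:
            m["distance_ms"] = float((t - cmap.r_time[i]) * 1000.0)
            if t >= cmap.r_time[i] + cmap.rr[i]:
                m["outside_map"] = True
            elif cmap.usable[i]:
                if t <= cmap.t_end[i]:
                    m["phase"] = "systole"
                elif t >= dia0[i]:
                    m["phase"] = "diastole"
        out_meta.append(m)
    merged = [dict(old, **new) for old, new in zip(events.meta, out_meta)]
    return EventList(events.times.copy(), list(events.labels), merged)


# ---------------------------------------------------------------------------
# interbeat-interval dynamics around stimulation
# ---------------------------------------------------------------------------

@dataclass
class IbiTriplet:
    event_time: float
    phase: str
    ibi_pre: float   # ms
    ibi_tms: float   # ms, the cycle containing the event
    ibi_post: float  # ms


def ibi_triplets(
    event_times: np.ndarray,
    r_peaks: np.ndarray,
    phases: list[str],
) -> tuple[list[IbiTriplet], int]:
    """RR of the cycle before, containing, and after each event.

    Events whose pre or post cycle is unavailable (first/last cycles of the
    record) are dropped; the second return value counts them.
    """
    r = np.asarray(r_peaks, dtype=float)
    triplets, dropped = [], 0
    for t, ph in zip(np.atleast_1d(event_times), phases):
        i = int(np.searchsorted(r, t, side="right")) - 1
        if i < 1 or i + 2 >= r.size:
            dropped += 1
            continue
        triplets.append(IbiTriplet(
            float(t), ph,
            (r[i] - r[i - 1]) * 1000.0,
            (r[i + 1] - r[i]) * 1000.0,
            (r[i + 2] - r[i + 1]) * 1000.0,
        ))
    return triplets, dropped


def ibi_table(triplets: list[IbiTriplet]) -> dict:
    """Mean IBI per (interval x phase) cell, ms."""
    out = {}
    for phase in ("systole", "diastole"):
        sel = [tr for tr in triplets if tr.phase == phase]
        for interval in ("pre", "tms", "post"):
            vals = [getattr(tr, f"ibi_{interval}") for tr in sel]
            out[(interval, phase)] = float(np.mean(vals)) if vals else np.nan
    return out


def ibi_sham_correct(
    real: list[IbiTriplet], sham: list[IbiTriplet]
) -> list[IbiTriplet]:
    """Subtract the sham mean per (interval x phase) cell from real triplets."""
    sham_means = ibi_table(sham)
    out = []
    for tr in real:
        if tr.phase not in ("systole", "diastole"):
            continue
        out.append(IbiTriplet(
            tr.event_time, tr.phase,
            tr.ibi_pre - sham_means[("pre", tr.phase)],
            tr.ibi_tms - sham_means[("tms", tr.phase)],
            tr.ibi_post - sham_means[("post", tr.phase)],
        ))
    return out
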