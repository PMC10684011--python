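"""EMG analysis: MEP quantification, envelopes, and movement onsets.

Motor-evoked potential (MEP) amplitude is the peak-to-peak excursion of the
baseline-corrected EMG 20-40 ms after the TMS pulse.  A real pulse counts
as valid only when it evokes more than 50 uV; a sham pulse is valid only
when it does not.  Movement onsets in the pinch task are detected with the
Teager-Kaiser energy operator psi(n) = x(n)^2 - x(n-1) x(n+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core_io import EpochArray, Recording, bandpass_notch, lowpass
from .cardiac import CardiacMap
from .exceptions import CardioMotorError, ParameterError

MEP_VALID_THRESHOLD_UV = 50.0


@dataclass
class MepRecord:
    trial: int
    amplitude_uv: float
    phase: str
    distance_ms: float | None
    condition: str          # "tms" or "sham"
    valid: bool = True


def mep_amplitude(
    epochs: EpochArray,
    channel: str = "EMG",
    baseline: tuple[float, float] = (-0.110, -0.010),
    window: tuple[float, float] = (0.020, 0.040),
) -> np.ndarray:
    """Peak-to-peak amplitude (uV) in ``window`` after baseline correction.

    Baseline correction subtracts the per-trial mean of ``baseline``; the
    amplitude is max - min inside ``window``.  Invariant under adding a
    constant to the whole epoch and equivariant under gain scaling.
    """
    t = epochs.times
    if window[0] < t[0] or window[1] > t[-1] or baseline[0] < t[0]:
        raise ParameterError("analysis window outside the epoch")
    ch = epochs.index(channel)
    x = epochs.data[:, ch, :]
    bsl = epochs.time_slice(*baseline)
    win = epochs.time_slice(*window)
    xc = x - x[:, bsl].mean(axis=1, keepdims=True)
    seg = xc[:, win]
    return seg.max(axis=1) - seg.min(axis=1)


def mep_records(
    epochs: EpochArray, amplitudes: np.ndarray, condition: str
) -> list[MepRecord]:
    """Bundle amplitudes with the per-trial phase metadata."""
    recs = []
    for i, (amp, meta) in enumerate(zip(amplitudes, epochs.trial_meta)):
        recs.append(MepRecord(
            i, float(amp), meta.get("phase", "neither"),
            meta.get("distance_ms"), condition,
        ))
    return recs


def validate_trials(records: list[MepRecord]) -> list[MepRecord]:
    """Set validity flags: real TMS must evoke > 50 uV, sham must not."""
    for r in records:
        if r.condition == "tms":
            r.valid = r.amplitude_uv > MEP_VALID_THRESHOLD_UV
        else:
            r.valid = r.amplitude_uv <= MEP_VALID_THRESHOLD_UV
    return records


# ---------------------------------------------------------------------------
# envelope
# ---------------------------------------------------------------------------

def emg_envelope(
    obj,
    channel: str = "EMG",
    band: tuple[float, float] = (10.0, 500.0),
    notch: tuple[float, float] | None = (45.0, 55.0),
    lp_hz: float = 8.0,
):
    """Linear EMG envelope: band-pass, full-wave rectify, 8 Hz low-pass.

    Works on a Recording or an EpochArray; only ``channel`` is transformed
    and returned (1-D for a Recording, trials x time for epochs).  For a
    steady sinusoid of amplitude A the envelope settles at 2A/pi, the mean
    of the rectified wave.
    """
    if band[1] >= obj.rate / 2:
        raise ParameterError("EMG band exceeds Nyquist at this rate")
    filtered = bandpass_notch(obj, band=band, notch_stop=notch,
                              channels=[channel])
    ch = filtered.index(channel)
    if isinstance(filtered, Recording):
        rect = np.abs(filtered.data[ch])
    else:
        rect = np.abs(filtered.data[:, ch, :])
    sos = sps.butter(4, lp_hz, btype="lowpass", fs=obj.rate, output="sos")
    env = sps.sosfiltfilt(sos, rect, axis=-1)
    return np.clip(env, 0.0, None)


# ---------------------------------------------------------------------------
# Teager-Kaiser onset detection
# ---------------------------------------------------------------------------

def teager_kaiser(x: np.ndarray) -> np.ndarray:
    """psi(n) = x(n)^2 - x(n-1) x(n+1), zero-padded at the edges."""
    x = np.asarray(x, dtype=float)
    psi = np.zeros_like(x)
    psi[1:-1] = x[1:-1] ** 2 - x[:-2] * x[2:]
    return psi


def tke_onset(
    x: np.ndarray,
    rate: float,
    baseline_s: tuple[float, float] = (0.0, 0.5),
    k: float = 8.0,
    sustain_ms: float = 25.0,
    smooth_ms: float = 40.0,
) -> float | None:
    """First sustained TKE threshold crossing, in seconds from trace start.

    The TKE profile is smoothed with a ``smooth_ms`` moving average; the
    threshold is mean + k * sd of the profile over ``baseline_s``
    (pre-activity).  A crossing must be sustained for ``sustain_ms`` to
    count; the onset is then refined backwards to the last sample at
    baseline level (mean + 1 sd), correcting the latency bias of a pure
    threshold crossing on a ramping burst.  Returns ``None`` when no onset
    is found (flag for review).
    """
    psi = teager_kaiser(x)
    w = max(int(round(smooth_ms / 1000.0 * rate)), 1)
    psi = np.convolve(psi, np.ones(w) / w, mode="same")
    b0, b1 = int(baseline_s[0] * rate), int(baseline_s[1] * rate)
    if b1 <= b0 or b1 > psi.size:
        raise ParameterError("baseline window outside the trace")
    base = psi[b0:b1]
    thresh = base.mean() + k * base.std()
    floor = base.mean() + base.std()
    above = psi > thresh
    need = max(int(round(sustain_ms / 1000.0 * rate)), 1)
    run = 0
    for i in range(b1, psi.size):
        run = run + 1 if above[i] else 0
        if run >= need:
            j = i - need + 1
            while j > b1 and psi[j - 1] > floor:
                j -= 1
            return j / rate
    return None


# ---------------------------------------------------------------------------
# sham control subtraction and rest-state pseudo-trials
# ---------------------------------------------------------------------------

def sham_emg_correct(
    real_by_phase: dict[str, np.ndarray],
    sham_by_phase: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Subtract the per-phase sham mean trace/amplitude from the real means."""
    out = {}
    for phase, real in real_by_phase.items():
        if phase not in sham_by_phase or np.size(sham_by_phase[phase]) == 0:
            raise CardioMotorError(f"sham cell for phase {phase!r} is empty")
        out[phase] = np.asarray(real, dtype=float) - np.asarray(
            sham_by_phase[phase], dtype=float)
    return out


def rest_control_sampling(
    rest: Recording,
    cmap: CardiacMap,
    n: int,
    seed: int = 0,
) -> tuple[np.ndarray, list[str], int]:
    """Pseudo-events at random offsets inside systole/diastole of rest data.

    Draws at most one pseudo-event per usable beat, alternating phases so
    the two cells stay balanced.  Returns ``(times, phases, n_drawn)``;
    ``n_drawn`` may be below ``n`` when the rest recording has too few
    usable beats.
    """
    rng = np.random.default_rng(seed)
    usable = np.flatnonzero(cmap.usable)
    if usable.size == 0:
        raise CardioMotorError("rest recording has no usable beats")
    take = min(n, usable.size)
    picks = rng.choice(usable, size=take, replace=False)
    dia0 = cmap.diastole_start()
    times, phases = [], []
    for j, b in enumerate(picks):
        L = cmap.t_end[b] - cmap.r_time[b]
        u = rng.uniform(0.0, L)
        if j % 2 == 0:
            times.append(cmap.r_time[b] + u)
            phases.append("systole")
        else:
            times.append(dia0[b] + u)
            phases.append("diastole")
    order = np.argsort(times)
    times = np.asarray(times)[order]
    phases = [phases[i] for i in order]
    # keep pseudo-epochs inside the recording
    keep = (times > 1.0) & (times < rest.duration - 1.0)
    return times[keep], [p for p, k in zip(phases, keep) if k], int(keep.sum())
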