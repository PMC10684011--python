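"""Morlet wavelet time-frequency analysis and event-related desynchronization.

The wavelet family follows a linear cycle scheme: the number of cycles
grows from 4 at 5 Hz to 10 at 40 Hz, i.e. ``n(f) = 4 + 6 (f - 5) / 35``.
With the Gaussian-envelope convention ``sigma_t = n / (2 pi f)`` this gives
``sigma_f = f / n`` and a spectral full width at half maximum of
``2 sqrt(2 ln 2) sigma_f`` (about 4.85 Hz at 10 Hz, where the wavelet is
4.9 cycles long).  Event-related desynchronization (ERD) is the relative
power change against a pre-event baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .core_io import EpochArray
from .exceptions import ParameterError

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))

FREQ_LO, FREQ_HI = 5.0, 40.0
CYCLES_LO, CYCLES_HI = 4.0, 10.0


def morlet_cycles(f):
    """Cycle count at frequency ``f`` under the linear 4 -> 10 scheme."""
    f = np.asarray(f, dtype=float)
    if np.any(f < FREQ_LO) or np.any(f > FREQ_HI):
        raise ParameterError(f"frequency outside [{FREQ_LO}, {FREQ_HI}] Hz")
    n = CYCLES_LO + (CYCLES_HI - CYCLES_LO) * (f - FREQ_LO) / (FREQ_HI - FREQ_LO)
    return float(n) if n.ndim == 0 else n


def wavelet_resolution(f):
    """Temporal and spectral resolution of the wavelet at ``f``.

    Returns ``(sigma_t, sigma_f, fwhm_f)`` with ``sigma_t = n / (2 pi f)``
    seconds, ``sigma_f = f / n`` Hz and ``fwhm_f = 2 sqrt(2 ln 2) sigma_f``.
    The uncertainty identity ``sigma_t * sigma_f = 1 / (2 pi)`` holds for
    every frequency.
    """
    n = morlet_cycles(f)
    f = np.asarray(f, dtype=float)
    sigma_t = n / (2.0 * np.pi * f)
    sigma_f = f / n
    if sigma_t.ndim == 0:
        return float(sigma_t), float(sigma_f), float(_FWHM * sigma_f)
    return sigma_t, sigma_f, _FWHM * sigma_f


@dataclass
class TfrConfig:
    freqs: np.ndarray = field(
        default_factory=lambda: np.arange(5.0, 41.0, 1.0))
    baseline: tuple[float, float] = (-0.9, -0.1)
    test_band: tuple[float, float] = (8.0, 30.0)
    test_window: tuple[float, float] = (0.0, 1.0)
    electrodes: tuple[str, ...] = ("C4", "CP4", "C6", "CP6")


@dataclass
class TfrResult:
    power: np.ndarray          # trials x channels x freqs x times
    freqs: np.ndarray
    times: np.ndarray
    rate: float
    labels: list[str]
    trial_meta: list[dict]
    edge: np.ndarray           # freqs x times bool, within half wavelet support

    def band_indices(self, lo: float, hi: float) -> np.ndarray:
        return np.flatnonzero((self.freqs >= lo) & (self.freqs <= hi))


def _morlet(f: float, rate: float) -> np.ndarray:
    """Unit-energy complex Morlet wavelet at frequency ``f``."""
    sigma_t = morlet_cycles(f) / (2.0 * np.pi * f)
    half = int(np.ceil(5.0 * sigma_t * rate))
    t = np.arange(-half, half + 1) / rate
    w = np.exp(2j * np.pi * f * t) * np.exp(-0.5 * (t / sigma_t) ** 2)
    return w / np.sqrt(np.sum(np.abs(w) ** 2))


def compute_tfr(epochs: EpochArray, cfg: TfrConfig | None = None,
                channels: list[str] | None = None) -> TfrResult:
    """Single-trial wavelet power: |convolution with complex Morlet|^2.

    ``edge`` flags time-frequency samples within half the wavelet support
    of either epoch edge, where power estimates are contaminated by the
    boundary.  Raises when the epoch is shorter than the support of the
    lowest frequency.
    """
    cfg = cfg or TfrConfig()
    if channels is None:
        channels = [c for c in cfg.electrodes if c in epochs.labels]
        if not channels:
            channels = [l for l, r in zip(epochs.labels, epochs.roles)
                        if r == "eeg"]
    idx = [epochs.index(c) for c in channels]
    x = epochs.data[:, idx, :]
    nt = epochs.n_times
    freqs = np.asarray(cfg.freqs, dtype=float)

    powers = np.empty((x.shape[0], x.shape[1], freqs.size, nt))
    edge = np.zeros((freqs.size, nt), dtype=bool)
    for j, f in enumerate(freqs):
        w = _morlet(f, epochs.rate)
        half = (w.size - 1) // 2
        if w.size > nt:
            raise ParameterError(
                f"epoch too short for {f:g} Hz wavelet "
                f"(lowest valid frequency has support <= epoch length)")
        conv = fftconvolve(x, w[None, None, :], mode="same", axes=-1)
        powers[:, :, j, :] = np.abs(conv) ** 2
        guard = half // 2
        edge[j, :guard] = True
        if guard:
            edge[j, -guard:] = True
    return TfrResult(powers, freqs, epochs.times, epochs.rate,
                     channels, [dict(m) for m in epochs.trial_meta], edge)


def erd(tfr: TfrResult, baseline: tuple[float, float]) -> np.ndarray:
    """Per-trial relative power change against the baseline window.

    ERD(f, t) = (P(f, t) - mean_baseline P(f)) / mean_baseline P(f); a
    value of -0.3 means a 30 % power drop.  Invariant to channel-wise
    static gain by construction.
    """
    sel = (tfr.times >= baseline[0]) & (tfr.times <= baseline[1])
    if not np.any(sel):
        raise ParameterError("baseline window outside the TFR time range")
    base = tfr.power[:, :, :, sel].mean(axis=3, keepdims=True)
    return tfr.power / base - 1.0


def erd_contrast(tfr: TfrResult, cfg: TfrConfig | None = None) -> dict:
    """Phase-wise mean ERD maps over the configured electrodes.

    Trials are grouped by the ``phase`` entry of their metadata.  Returns a
    dict with per-phase maps (channels x freqs x times), the frequency/time
    axes restricted to the test band/window, and the per-trial maps needed
    as cluster-permutation input.
    """
    cfg = cfg or TfrConfig()
    maps = erd(tfr, cfg.baseline)
    fi = tfr.band_indices(*cfg.test_band)
    ti = np.flatnonzero((tfr.times >= cfg.test_window[0])
                        & (tfr.times <= cfg.test_window[1]))
    phases = [m.get("phase", "neither") for m in tfr.trial_meta]
    out = {"freqs": tfr.freqs[fi], "times": tfr.times[ti],
           "labels": tfr.labels, "per_trial": {}, "mean": {}}
    for phase in ("systole", "diastole"):
        sel = [i for i, p in enumerate(phases) if p == phase]
        if not sel:
            continue
        sub = maps[np.ix_(sel, range(len(tfr.labels)), fi, ti)]
        out["per_trial"][phase] = sub
        out["mean"][phase] = sub.mean(axis=0)
    return out
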