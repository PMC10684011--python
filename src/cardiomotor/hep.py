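"""Heartbeat-evoked potential (HEP) extraction around TMS.

HEPs are R-peak-locked EEG responses.  To study them in a TMS experiment
the stimulation artifact bleeding into the pre-stimulus window must be
estimated and removed: for trials where the pulse arrived at least 400 ms
after the previous R-peak, the R-to-pulse distances are shuffled and
subtracted from the pulse latencies to place "mock events" that sample the
TMS artifact at the same lags but without heartbeat locking; averaging
epochs around many such mock events (default 10 shuffles) yields an
artifact template that is subtracted from every HEP epoch.

Trials are then sorted by their MEP amplitude and split into tertiles;
the contrast of interest compares HEPs preceding strong (bin 3) versus
weak (bin 1) motor responses.  Variant analyses reuse the machinery with
a swapped trial-selection rule (early-TMS trials, previous cycle's HEP)
or event source (resting-state R-peaks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import EpochArray, EventList, Recording, baseline_correct, epoch
from .exceptions import CardioMotorError, ParameterError

BIN_NAMES = ("weak", "mid", "strong")


@dataclass
class HepConfig:
    min_r_to_tms_ms: float = 400.0
    epoch_s: tuple[float, float] = (-0.100, 0.400)
    baseline_s: tuple[float, float] = (-0.100, 0.0)
    n_shuffles: int = 10
    electrodes: tuple[str, ...] = (
        "FC2", "Cz", "C4", "CP1", "CP2", "Pz", "P4",
        "C1", "C2", "CPz", "CP4", "P1", "P2",
    )
    test_window_s: tuple[float, float] = (0.296, 0.400)
    early_test_window_s: tuple[float, float] = (0.362, 0.394)
    n_bins: int = 3

    def validate(self):
        if self.n_bins < 2:
            raise ParameterError("need at least two amplitude bins")
        if not (self.epoch_s[0] <= self.test_window_s[0]
                < self.test_window_s[1] <= self.epoch_s[1]):
            raise ParameterError("test window must lie inside the epoch")


# ---------------------------------------------------------------------------
# trial selection
# ---------------------------------------------------------------------------

def select_late_tms_trials(trial_meta: list[dict],
                           cfg: HepConfig | None = None):
    """Trials whose pulse came >= 400 ms after the previous R-peak.

    Returns ``(indices, distances_ms)``.  Raises with a distance histogram
    when the subset is empty.
    """
    cfg = cfg or HepConfig()
    idx, dist = [], []
    all_d = []
    for i, m in enumerate(trial_meta):
        d = m.get("distance_ms")
        if d is None:
            continue
        all_d.append(d)
        if d >= cfg.min_r_to_tms_ms:
            idx.append(i)
            dist.append(float(d))
    if not idx:
        hist, edges = np.histogram(all_d, bins=8) if all_d else ([], [])
        raise CardioMotorError(
            "no trials with R-to-pulse distance >= "
            f"{cfg.min_r_to_tms_ms} ms (distance histogram: {list(hist)} "
            f"over edges {[round(e) for e in np.asarray(edges)]})")
    return idx, np.asarray(dist)


def select_early_tms_trials(trial_meta: list[dict],
                            cfg: HepConfig | None = None):
    """Trials with the pulse inside the first 400 ms of the cycle.

    Used for the variant asking whether the previous cycle's heartbeat
    response predicts these trials' MEPs.
    """
    cfg = cfg or HepConfig()
    idx, dist = [], []
    for i, m in enumerate(trial_meta):
        d = m.get("distance_ms")
        if d is not None and d < cfg.min_r_to_tms_ms:
            idx.append(i)
            dist.append(float(d))
    if not idx:
        raise CardioMotorError("no early-TMS trials")
    return idx, np.asarray(dist)


# ---------------------------------------------------------------------------
# mock-event artifact template
# ---------------------------------------------------------------------------

def estimate_mock_artifact(
    raw: Recording,
    tms_times: np.ndarray,
    distances_ms: np.ndarray,
    cfg: HepConfig | None = None,
    seed: int = 0,
) -> np.ndarray:
    """TMS artifact template in the HEP window via shuffled mock events.

    For each of ``n_shuffles`` uniform random permutations of the distance
    list, mock event times are ``pulse latency - shuffled distance``; epochs
    around all mock events are averaged across events and shuffles.  Mock
    epochs falling outside the record are dropped (counted internally).
    A fixed seed reproduces the template exactly.
    """
    cfg = cfg or HepConfig()
    tms_times = np.asarray(tms_times, dtype=float)
    distances_ms = np.asarray(distances_ms, dtype=float)
    if tms_times.size != distances_ms.size:
        raise ParameterError("distances must align with TMS events")
    if tms_times.size < 2:
        raise ParameterError("need at least two trials for the template")
    rng = np.random.default_rng(seed)

    n_times = int(round((cfg.epoch_s[1] - cfg.epoch_s[0]) * raw.rate)) + 1
    acc = np.zeros((raw.n_channels, n_times))
    count = 0
    for _ in range(cfg.n_shuffles):
        perm = rng.permutation(distances_ms.size)
        mock_times = tms_times - distances_ms[perm] / 1000.0
        for t in mock_times:
            start = int(round((t + cfg.epoch_s[0]) * raw.rate))
            stop = start + n_times
            if start < 0 or stop > raw.n_samples:
                continue
            acc += raw.data[:, start:stop]
            count += 1
    if count == 0:
        raise CardioMotorError("all mock epochs fell outside the record")
    return acc / count


# ---------------------------------------------------------------------------
# HEP extraction
# ---------------------------------------------------------------------------

def extract_hep(
    raw: Recording,
    lock_times: np.ndarray,
    template: np.ndarray | None,
    cfg: HepConfig | None = None,
    trial_meta: list[dict] | None = None,
) -> EpochArray:
    """R-locked epochs with artifact template subtraction and baseline.

    ``lock_times`` are the R-peaks preceding the kept trials (seconds).
    ``template`` (channels x time, as from :func:`estimate_mock_artifact`)
    is subtracted from every epoch before the -100..0 ms baseline removal;
    pass ``None`` for a plain R-locked ERP (e.g. resting state).
    """
    cfg = cfg or HepConfig()
    cfg.validate()
    events = EventList(np.asarray(lock_times, dtype=float),
                       ["rpeak"] * len(lock_times),
                       [dict(m) for m in trial_meta] if trial_meta else None)
    ep = epoch(raw, events, "rpeak", *cfg.epoch_s)
    if template is not None:
        if template.shape != (ep.data.shape[1], ep.n_times):
            raise ParameterError(
                f"template shape {template.shape} does not match epochs")
        ep.data -= template[None, :, :]
        ep.provenance.append({"stage": "mock_template_subtraction"})
    baseline_correct(ep, cfg.baseline_s)
    return ep


# ---------------------------------------------------------------------------
# MEP-amplitude binning
# ---------------------------------------------------------------------------

def bin_by_mep(amplitudes: np.ndarray, n_bins: int = 3) -> np.ndarray:
    """Sort trials by MEP amplitude and split into near-equal bins.

    Trials are sorted ascending (ties keep their original order) and cut
    into ``n_bins`` contiguous groups; when the count is not divisible the
    remainder goes to the lower bins, so sizes are non-increasing (e.g.
    10 trials in 3 bins -> 4, 3, 3).  Returns integer bin labels per trial
    (0 = weakest).
    """
    amp = np.asarray(amplitudes, dtype=float)
    n = amp.size
    if n < n_bins:
        raise ParameterError(f"cannot split {n} trials into {n_bins} bins")
    order = np.argsort(amp, kind="stable")
    base, rem = divmod(n, n_bins)
    sizes = [base + (1 if b < rem else 0) for b in range(n_bins)]
    labels = np.empty(n, dtype=int)
    start = 0
    for b, s in enumerate(sizes):
        labels[order[start:start + s]] = b
        start += s
    return labels


def hep_window_mean(ep: EpochArray, cfg: HepConfig | None = None,
                    window: tuple[float, float] | None = None) -> np.ndarray:
    """Per-trial mean over the test window and electrode cluster (uV)."""
    cfg = cfg or HepConfig()
    window = window or cfg.test_window_s
    chans = [c for c in cfg.electrodes if c in ep.labels]
    if not chans:
        raise CardioMotorError("no HEP cluster electrodes present")
    idx = [ep.index(c) for c in chans]
    sl = ep.time_slice(*window)
    return ep.data[:, idx, sl.start:sl.stop].mean(axis=(1, 2))


def hep_tertile_contrast(
    ep: EpochArray,
    mep_amplitudes: np.ndarray,
    cfg: HepConfig | None = None,
    window: tuple[float, float] | None = None,
) -> dict:
    """Strong-vs-weak MEP tertile contrast of HEP activity.

    Returns per-bin mean traces over the electrode cluster plus the
    strong-minus-weak per-trial window data needed for cluster testing
    (bins 3 vs 1 only; the middle bin is retained in the outputs).
    """
    cfg = cfg or HepConfig()
    window = window or cfg.test_window_s
    bins = bin_by_mep(mep_amplitudes, cfg.n_bins)
    chans = [c for c in cfg.electrodes if c in ep.labels]
    idx = [ep.index(c) for c in chans]
    sl = ep.time_slice(*window)
    out = {"bins": bins, "channels": chans,
           "times": ep.times[sl.start:sl.stop], "per_bin": {}}
    for b in range(cfg.n_bins):
        rows = np.flatnonzero(bins == b)
        name = BIN_NAMES[b] if b < len(BIN_NAMES) else f"bin{b}"
        out["per_bin"][name] = ep.data[np.ix_(rows, idx)].mean(axis=0)
    weak = np.flatnonzero(bins == 0)
    strong = np.flatnonzero(bins == cfg.n_bins - 1)
    # channel x time arrays per trial, strong and weak cells
    out["strong"] = ep.data[np.ix_(strong, idx, range(sl.start, sl.stop))]
    out["weak"] = ep.data[np.ix_(weak, idx, range(sl.start, sl.stop))]
    return out


# ---------------------------------------------------------------------------
# variant analyses
# ---------------------------------------------------------------------------

def previous_cycle_locks(
    tms_times: np.ndarray,
    r_peaks: np.ndarray,
    cfg: HepConfig | None = None,
):
    """Lock times for the previous-cycle variant.

    For pulses inside the first 400 ms of their cycle, the heartbeat
    response of interest is the one from the *preceding* cycle.  Returns
    ``(kept_indices, lock_times, distances_ms)`` where distances measure
    lock-to-pulse lags (the input to mock-event artifact estimation).
    Trials whose preceding cycle has no R-peak on record are dropped.
    """
    cfg = cfg or HepConfig()
    r = np.asarray(r_peaks, dtype=float)
    kept, locks, dists = [], [], []
    for k, t in enumerate(np.atleast_1d(tms_times)):
        i = int(np.searchsorted(r, t, side="right")) - 1
        if i < 1:
            continue
        if (t - r[i]) * 1000.0 >= cfg.min_r_to_tms_ms:
            continue
        kept.append(k)
        locks.append(r[i - 1])
        dists.append((t - r[i - 1]) * 1000.0)
    if not kept:
        raise CardioMotorError("no early-TMS trials with a preceding cycle")
    return kept, np.asarray(locks), np.asarray(dists)


def rest_hep(
    rest: Recording,
    r_peaks: np.ndarray,
    cfg: HepConfig | None = None,
) -> EpochArray:
    """Resting-state HEP: plain R-locked epochs, no artifact template."""
    cfg = cfg or HepConfig()
    r = np.asarray(r_peaks, dtype=float)
    inside = r[(r + cfg.epoch_s[0] > 0)
               & (r + cfg.epoch_s[1] < rest.duration)]
    return extract_hep(rest, inside, None, cfg)
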