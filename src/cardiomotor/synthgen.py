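"""Synthetic study sessions with known injected effects.

This module emulates the multimodal recordings the analysis pipeline is
built for: a quasi-periodic ECG with R-peaks and T-waves, TMS (and sham)
pulses falling at random cardiac phases, motor-evoked potentials in the EMG
whose log-amplitude declines with time since the last R-peak and is boosted
during systole, TMS-evoked and heartbeat-evoked EEG deflections, pinch-task
EMG bursts with sensorimotor desynchronization, TMS pulse/decay artifacts,
and phase-dependent heart-rate dynamics.  Every effect is a configuration
knob with the true injected values echoed back in a :class:`GroundTruth`
object, so downstream stages can be tested by parameter recovery.

The generative model is deliberately simple (Gaussian QRS/T shapes, white
background noise, sinusoidal sensorimotor rhythm): it provides known
ground truth, not biophysical realism.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np

from .core_io import EventList, Recording
from .exceptions import ConfigError

#: channels the analyses address: TMS hotspot cluster, heartbeat-response
#: centroparietal cluster, mastoid references, one frontal site.
DEFAULT_EEG_CHANNELS = (
    "Fz", "FC2", "Cz", "C1", "C2", "C4", "C6",
    "CP1", "CP2", "CPz", "CP4", "CP6", "Pz", "P1", "P2", "P4",
    "M1", "M2",
)

HOTSPOT = ("C4", "CP4", "C6", "CP6")
HEP_CLUSTER = ("FC2", "Cz", "C4", "CP1", "CP2", "Pz", "P4",
               "C1", "C2", "CPz", "CP4", "P1", "P2")


@dataclass
class SynthConfig:
    """All knobs of the synthetic session generator.

    Defaults reproduce the study conditions the pipeline targets: 5 kHz
    sampling, RR intervals around 900 ms, ~350 ms systole, 416 real and 416
    sham pulses at 1.5-2.5 s inter-stimulus intervals, and 30 pinch trials.
    Effect knobs (``mep_systole_gain``, ``erd_depth``, ...) are free
    parameters; setting all of them to their null values produces data with
    no phase effects at all.
    """

    seed: int = 0
    rate: float = 5000.0
    duration_s: float | None = None  # derived from the event schedule if None

    # cardiac rhythm
    rr_mean_ms: float = 900.0
    rr_sd_ms: float = 50.0
    systole_len_ms: float = 350.0
    systole_jitter_ms: float = 10.0
    t_sigma_ms: float = 25.0        # T-wave Gaussian width
    qrs_amp_uv: float = 800.0
    qrs_sigma_ms: float = 8.0
    t_amp_uv: float = 200.0

    # stimulation schedule
    n_tms: int = 416
    n_sham: int = 416
    isi_range_s: tuple[float, float] = (1.5, 2.5)

    # motor-evoked potentials (EMG)
    mep_base_uv: float = 500.0
    mep_systole_gain: float = 1.0       # multiplicative systolic boost
    mep_distance_slope: float = 0.0     # log-amplitude decline per ms from R
    mep_log_sd: float = 0.5             # trial-to-trial lognormal noise
    mep_excit_sd: float = 0.25          # weight of the shared per-beat latent

    # TMS-evoked potentials (EEG hotspot)
    tep_amp_uv: float = 5.0
    tep_window_ms: tuple[float, float] = (22.0, 60.0)
    tep_systole_gain: float = 1.0

    # heartbeat-evoked potentials (EEG centroparietal)
    hep_amp_uv: float = 2.0
    hep_window_ms: tuple[float, float] = (296.0, 400.0)
    hep_mep_coupling: float = 0.0       # uV of HEP per SD of the shared latent

    # pinch task
    n_pinch: int = 30
    pinch_iti_s: float = 6.0            # 3 s contraction + 3 s rest
    pinch_burst_uv: float = 100.0       # EMG burst RMS
    pinch_rise_ms: float = 150.0
    pinch_hold_s: float = 3.0
    osc_amp_uv: float = 5.0             # ongoing 10/20 Hz sensorimotor rhythm
    erd_depth: float = 0.0              # fractional 8-25 Hz amplitude drop
    erd_systole_gain: float = 1.0       # extra depth factor for systolic onsets
    erd_duration_ms: float = 700.0

    # heart-rate dynamics around TMS
    ibi_decel_ms: float = 0.0           # lengthening of the systolic-TMS cycle
    ibi_accel_ms: float = 0.0           # shortening of the next cycle

    # stimulation artifacts (applied to real and sham alike)
    decay_amp_uv: float = 150.0
    decay_tau_ms: float = 50.0
    pulse_amp_uv: float = 3000.0
    pulse_width_ms: float = 2.0

    # noise standard deviations
    eeg_noise_uv: float = 10.0
    ecg_noise_uv: float = 5.0
    emg_noise_uv: float = 8.0

    eeg_channels: tuple[str, ...] = DEFAULT_EEG_CHANNELS

    def validate(self) -> None:
        if self.rate <= 0:
            raise ConfigError("rate must be positive")
        if self.rr_mean_ms <= 2 * self.systole_len_ms:
            raise ConfigError("rr_mean_ms must exceed twice the systole length")
        for name in ("mep_systole_gain", "tep_systole_gain", "erd_systole_gain"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 <= self.erd_depth < 1:
            raise ConfigError("erd_depth must be in [0, 1)")
        if self.isi_range_s[0] > self.isi_range_s[1] or self.isi_range_s[0] <= 0:
            raise ConfigError("invalid ISI range")
        if self.duration_s is not None and self.duration_s < 2 * self.rr_mean_ms / 1000:
            raise ConfigError("duration too short for a single cardiac cycle")


@dataclass
class Beat:
    r_time: float       # s
    t_end: float        # s (truth: T-wave centre + 2.5 sigma)
    rr: float           # s, to the next R-peak
    z: float            # shared excitability latent, N(0, 1)

    @property
    def systole_len(self) -> float:
        return self.t_end - self.r_time


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    r_times: np.ndarray
    t_ends: np.ndarray
    rr: np.ndarray
    z: np.ndarray
    events: list[dict] = field(default_factory=list)   # per TMS/sham/pinch event
    config: dict = field(default_factory=dict)

    def events_for(self, label: str) -> list[dict]:
        return [e for e in self.events if e["label"] == label]


# ---------------------------------------------------------------------------
# cardiac rhythm
# ---------------------------------------------------------------------------

def _true_phase(t: float, beats: list[Beat], i: int) -> str:
    b = beats[i]
    if t <= b.t_end:
        return "systole"
    if t >= b.r_time + b.rr - b.systole_len:
        return "diastole"
    return "neither"


def _gen_beats(cfg: SynthConfig, rng: np.random.Generator, duration: float,
               tms_times: np.ndarray | None = None) -> list[Beat]:
    """Draw the beat sequence, applying TMS-phase-dependent IBI dynamics.

    A real TMS pulse falling inside the systolic window of a beat lengthens
    that beat's RR interval by ``ibi_decel_ms`` and shortens the next one by
    ``ibi_accel_ms`` (deceleration-then-recovery pattern).
    """
    beats: list[Beat] = []
    t = 0.4 * cfg.rr_mean_ms / 1000.0
    pending_accel = 0.0
    min_rr = 2 * (cfg.systole_len_ms + 3 * cfg.systole_jitter_ms) / 1000.0 + 0.02
    while t < duration - 0.2:
        L = (cfg.systole_len_ms + cfg.systole_jitter_ms * rng.standard_normal()) / 1000.0
        L = max(L, 0.15)
        rr = (cfg.rr_mean_ms + cfg.rr_sd_ms * rng.standard_normal()) / 1000.0
        rr = max(rr, min_rr)
        rr -= pending_accel
        pending_accel = 0.0
        if tms_times is not None and tms_times.size:
            in_systole = np.any((tms_times >= t) & (tms_times <= t + L))
            if in_systole:
                rr += cfg.ibi_decel_ms / 1000.0
                pending_accel = cfg.ibi_accel_ms / 1000.0
        beats.append(Beat(t, t + L, rr, rng.standard_normal()))
        t += rr
    if not beats:
        raise ConfigError("duration too short for a single beat")
    return beats


def _add_gauss(trace: np.ndarray, rate: float, center_s: float,
               sigma_s: float, amp: float) -> None:
    """Add a Gaussian bump in place, restricted to +-5 sigma."""
    n = trace.size
    i0 = max(int((center_s - 5 * sigma_s) * rate), 0)
    i1 = min(int((center_s + 5 * sigma_s) * rate) + 1, n)
    if i1 <= i0:
        return
    tt = np.arange(i0, i1) / rate - center_s
    trace[i0:i1] += amp * np.exp(-0.5 * (tt / sigma_s) ** 2)


def _render_ecg(beats: list[Beat], n: int, cfg: SynthConfig,
                rng: np.random.Generator) -> np.ndarray:
    ecg = cfg.ecg_noise_uv * rng.standard_normal(n)
    sig_q = cfg.qrs_sigma_ms / 1000.0
    sig_t = cfg.t_sigma_ms / 1000.0
    for b in beats:
        _add_gauss(ecg, cfg.rate, b.r_time, sig_q, cfg.qrs_amp_uv)
        _add_gauss(ecg, cfg.rate, b.r_time + 0.030, sig_q, -0.25 * cfg.qrs_amp_uv)
        t_center = b.t_end - 2.5 * sig_t
        _add_gauss(ecg, cfg.rate, t_center, sig_t, cfg.t_amp_uv)
    return ecg


def gen_ecg(cfg: SynthConfig):
    """Generate the ECG channel alone.

    Returns ``(ecg, r_times, t_ends)`` where the analytic T-wave end (centre
    + 2.5 sigma of the T Gaussian) is reported as truth.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    duration = cfg.duration_s if cfg.duration_s is not None else 60.0
    beats = _gen_beats(cfg, rng, duration)
    n = int(round(duration * cfg.rate))
    ecg = _render_ecg(beats, n, cfg, rng)
    r = np.array([b.r_time for b in beats])
    te = np.array([b.t_end for b in beats])
    return ecg, r, te


# ---------------------------------------------------------------------------
# waveform primitives
# ---------------------------------------------------------------------------

def _half_sine(rate: float, t0_ms: float, t1_ms: float) -> tuple[int, np.ndarray]:
    """Positive half-sine deflection spanning [t0, t1] ms post-lock."""
    i0 = int(round(t0_ms / 1000.0 * rate))
    n = max(int(round((t1_ms - t0_ms) / 1000.0 * rate)), 2)
    return i0, np.sin(np.pi * np.arange(n) / (n - 1))


def _mep_shape(rate: float) -> tuple[int, np.ndarray]:
    """Biphasic deflection in the 20-40 ms post-pulse window, unit peak-to-peak."""
    i0 = int(round(0.020 * rate))
    n = max(int(round(0.020 * rate)), 4)
    x = np.arange(n) / (n - 1)
    w = np.sin(2 * np.pi * x) * np.hanning(n)
    return i0, w / (w.max() - w.min())


def _add_at(trace: np.ndarray, start: int, wave: np.ndarray) -> None:
    i0 = max(start, 0)
    i1 = min(start + wave.size, trace.size)
    if i1 > i0:
        trace[i0:i1] += wave[i0 - start: i1 - start]


def _stim_artifact(rate: float, cfg: SynthConfig) -> np.ndarray:
    """Pulse spike followed by an exponential decay, starting at t=0."""
    n_pulse = max(int(round(cfg.pulse_width_ms / 1000.0 * rate)), 2)
    n_decay = int(round(8 * cfg.decay_tau_ms / 1000.0 * rate))
    art = np.zeros(n_pulse + n_decay)
    art[:n_pulse] = cfg.pulse_amp_uv * np.sin(
        np.pi * np.arange(n_pulse) / max(n_pulse - 1, 1))
    tt = np.arange(n_decay) / rate
    art[n_pulse:] = cfg.decay_amp_uv * np.exp(-tt / (cfg.decay_tau_ms / 1000.0))
    return art


# ---------------------------------------------------------------------------
# full TMS session
# ---------------------------------------------------------------------------

def _schedule(cfg: SynthConfig, rng: np.random.Generator, n: int,
              start: float) -> np.ndarray:
    isis = rng.uniform(*cfg.isi_range_s, size=n)
    return start + np.cumsum(isis)


def _locate(t: float, beats: list[Beat], r_times: np.ndarray):
    """Index of the beat whose cycle contains t, or None outside coverage."""
    i = int(np.searchsorted(r_times, t, side="right")) - 1
    if i < 0 or i >= len(beats):
        return None
    if t >= beats[i].r_time + beats[i].rr:
        return None  # gap after the last rendered beat
    return i


def gen_session(cfg: SynthConfig):
    """Generate a complete TMS + sham session.

    Returns ``(Recording, EventList, GroundTruth)``.  The recording holds the
    configured EEG montage plus ``ECG`` and ``EMG`` channels.  Real pulses
    inject an MEP whose log amplitude is
    ``ln(mep_base) - slope * distance_from_R + ln(gain) * [systole]`` plus
    per-beat latent and trial noise; sham pulses share the artifact model but
    evoke no motor or cortical response.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    t0 = 5.0
    tms_times = _schedule(cfg, rng, cfg.n_tms, t0) if cfg.n_tms else np.empty(0)
    sham_start = (tms_times[-1] if cfg.n_tms else t0) + 5.0
    sham_times = (_schedule(cfg, rng, cfg.n_sham, sham_start)
                  if cfg.n_sham else np.empty(0))
    end = max(list(tms_times[-1:]) + list(sham_times[-1:]) + [t0]) + 5.0
    duration = cfg.duration_s if cfg.duration_s is not None else math.ceil(end)
    if (cfg.n_tms or cfg.n_sham) and end > duration:
        raise ConfigError(
            f"stimulation schedule ({end:.1f} s) exceeds duration {duration} s")

    beats = _gen_beats(cfg, rng, duration, tms_times)
    r_times = np.array([b.r_time for b in beats])
    n = int(round(duration * cfg.rate))

    ecg = _render_ecg(beats, n, cfg, rng)
    emg = cfg.emg_noise_uv * rng.standard_normal(n)
    eeg = {ch: cfg.eeg_noise_uv * rng.standard_normal(n)
           for ch in cfg.eeg_channels}
    # decay polarity varies across electrodes (electrode polarization)
    art_topo = {ch: rng.uniform(0.5, 1.5) * rng.choice((-1.0, 1.0))
                for ch in cfg.eeg_channels}

    truth = GroundTruth(
        r_times=r_times,
        t_ends=np.array([b.t_end for b in beats]),
        rr=np.array([b.rr for b in beats]),
        z=np.array([b.z for b in beats]),
        config=asdict(cfg),
    )

    # heartbeat-evoked potentials on every beat, coupled to the latent
    hep_i0, hep_w = _half_sine(cfg.rate, *cfg.hep_window_ms)
    for b in beats:
        amp = cfg.hep_amp_uv + cfg.hep_mep_coupling * b.z
        start = int(round(b.r_time * cfg.rate)) + hep_i0
        for ch in HEP_CLUSTER:
            if ch in eeg:
                _add_at(eeg[ch], start, amp * hep_w)

    mep_i0, mep_w = _mep_shape(cfg.rate)
    tep_i0, tep_w = _half_sine(cfg.rate, *cfg.tep_window_ms)
    art = _stim_artifact(cfg.rate, cfg)
    ecg_pulse = art[:int(round(cfg.pulse_width_ms / 1000.0 * cfg.rate)) + 1]

    for label, times in (("tms", tms_times), ("sham", sham_times)):
        for t in times:
            i = _locate(t, beats, r_times)
            start = int(round(t * cfg.rate))
            for ch in cfg.eeg_channels:
                _add_at(eeg[ch], start, art_topo[ch] * art)
            _add_at(ecg, start, 0.5 * ecg_pulse)
            rec_ev = {"time": float(t), "label": label, "phase": "neither",
                      "distance_ms": None, "mep_uv": 0.0, "beat": i}
            if i is not None:
                b = beats[i]
                rec_ev["phase"] = _true_phase(t, beats, i)
                rec_ev["distance_ms"] = (t - b.r_time) * 1000.0
            if label == "tms" and i is not None:
                b = beats[i]
                dist_ms = (t - b.r_time) * 1000.0
                # the most recent completed heartbeat response drives coupling
                z = b.z if dist_ms >= cfg.hep_window_ms[1] else (
                    beats[i - 1].z if i > 0 else 0.0)
                log_amp = (
                    math.log(cfg.mep_base_uv)
                    - cfg.mep_distance_slope * dist_ms
                    + (math.log(cfg.mep_systole_gain)
                       if rec_ev["phase"] == "systole" else 0.0)
                    + cfg.mep_excit_sd * z
                    + cfg.mep_log_sd * rng.standard_normal()
                )
                amp = math.exp(log_amp)
                _add_at(emg, start + mep_i0, amp * mep_w)
                tep_gain = (cfg.tep_systole_gain
                            if rec_ev["phase"] == "systole" else 1.0)
                for ch in HOTSPOT:
                    if ch in eeg:
                        _add_at(eeg[ch], start + tep_i0,
                                cfg.tep_amp_uv * tep_gain * tep_w)
                rec_ev["mep_uv"] = float(amp)
            truth.events.append(rec_ev)

    labels = list(cfg.eeg_channels) + ["ECG", "EMG"]
    data = np.vstack([eeg[ch] for ch in cfg.eeg_channels] + [ecg, emg])
    roles = ["eeg"] * len(cfg.eeg_channels) + ["ecg", "emg"]
    rec = Recording(data, cfg.rate, labels, roles)

    ev_times = np.concatenate([tms_times, sham_times])
    ev_labels = ["tms"] * len(tms_times) + ["sham"] * len(sham_times)
    events = EventList(ev_times, ev_labels)
    return rec, events, truth


# ---------------------------------------------------------------------------
# pinch task and rest
# ---------------------------------------------------------------------------

def _burst_envelope(rate: float, rise_ms: float, hold_s: float) -> np.ndarray:
    n_rise = max(int(round(rise_ms / 1000.0 * rate)), 2)
    n_hold = int(round(hold_s * rate))
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_rise) / (n_rise - 1)))
    return np.concatenate([ramp, np.ones(n_hold), ramp[::-1]])


def gen_pinch_task(cfg: SynthConfig):
    """Generate a pinch-task session: EMG bursts + sensorimotor rhythm.

    EMG bursts are band-limited noise under a shaped rise/hold envelope; the
    burst gain is multiplied by ``erd_systole_gain`` for systolic onsets.
    The EEG sensorimotor rhythm (10 and 20 Hz sinusoids on the hotspot
    cluster) is suppressed by a fraction ``erd_depth`` (amplitude) from each
    onset for ``erd_duration_ms``, more deeply for systolic onsets.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)

    onsets = 5.0 + cfg.pinch_iti_s * np.arange(cfg.n_pinch) \
        + rng.uniform(0.0, 1.0, size=cfg.n_pinch)
    duration = cfg.duration_s if cfg.duration_s is not None else \
        math.ceil(onsets[-1] + cfg.pinch_hold_s + 3.0)
    if onsets[-1] + cfg.pinch_hold_s > duration:
        raise ConfigError("pinch schedule exceeds duration")

    beats = _gen_beats(cfg, rng, duration)
    r_times = np.array([b.r_time for b in beats])
    n = int(round(duration * cfg.rate))

    ecg = _render_ecg(beats, n, cfg, rng)
    emg = cfg.emg_noise_uv * rng.standard_normal(n)

    truth = GroundTruth(
        r_times=r_times,
        t_ends=np.array([b.t_end for b in beats]),
        rr=np.array([b.rr for b in beats]),
        z=np.array([b.z for b in beats]),
        config=asdict(cfg),
    )

    # amplitude modulation of the ongoing rhythm: 1 everywhere, dipping
    # to (1 - depth) after each onset with 100 ms raised-cosine ramps
    tt = np.arange(n) / cfg.rate
    mod = np.ones(n)
    env = _burst_envelope(cfg.rate, cfg.pinch_rise_ms, cfg.pinch_hold_s)
    for t in onsets:
        i = _locate(t, beats, r_times)
        phase = _true_phase(t, beats, i) if i is not None else "neither"
        systolic = phase == "systole"
        # erd_depth is a fractional POWER drop; amplitude scales by sqrt
        p_drop = min(cfg.erd_depth * (cfg.erd_systole_gain if systolic else 1.0),
                     0.95)
        depth = 1.0 - np.sqrt(1.0 - p_drop)
        gain = cfg.pinch_burst_uv * (cfg.erd_systole_gain if systolic else 1.0)

        start = int(round(t * cfg.rate))
        burst = gain * rng.standard_normal(env.size) * env
        _add_at(emg, start, burst)

        n_erd = int(round(cfg.erd_duration_ms / 1000.0 * cfg.rate))
        n_ramp = max(int(round(0.1 * cfg.rate)), 2)
        dip = np.full(n_erd + 2 * n_ramp, depth)
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / (n_ramp - 1)))
        dip[:n_ramp] = depth * ramp
        dip[-n_ramp:] = depth * ramp[::-1]
        i1 = min(start + dip.size, n)
        if i1 > start >= 0:
            mod[start:i1] = np.minimum(mod[start:i1], 1 - dip[: i1 - start])

        truth.events.append({
            "time": float(t), "label": "pinch_on", "phase": phase,
            "distance_ms": (t - beats[i].r_time) * 1000.0 if i is not None else None,
            "erd_depth": float(p_drop), "burst_gain": float(gain), "beat": i,
        })

    eeg = {}
    for ch in cfg.eeg_channels:
        trace = cfg.eeg_noise_uv * rng.standard_normal(n)
        if ch in HOTSPOT:
            for f in (10.0, 20.0):
                trace += cfg.osc_amp_uv * mod * np.sin(
                    2 * np.pi * f * tt + rng.uniform(0, 2 * np.pi))
        eeg[ch] = trace

    labels = list(cfg.eeg_channels) + ["ECG", "EMG"]
    data = np.vstack([eeg[ch] for ch in cfg.eeg_channels] + [ecg, emg])
    roles = ["eeg"] * len(cfg.eeg_channels) + ["ecg", "emg"]
    rec = Recording(data, cfg.rate, labels, roles)
    events = EventList(onsets, ["pinch_on"] * len(onsets))
    return rec, events, truth


def gen_rest(cfg: SynthConfig, duration_s: float = 300.0):
    """Resting-state recording (no events): ECG + rhythm + quiescent EMG."""
    rest_cfg = SynthConfig(**{**asdict(cfg), "n_pinch": 0, "erd_depth": 0.0,
                              "duration_s": duration_s})
    rest_cfg.validate()
    rng = np.random.default_rng(rest_cfg.seed + 2)
    beats = _gen_beats(rest_cfg, rng, duration_s)
    n = int(round(duration_s * rest_cfg.rate))
    ecg = _render_ecg(beats, n, rest_cfg, rng)
    emg = rest_cfg.emg_noise_uv * rng.standard_normal(n)
    tt = np.arange(n) / rest_cfg.rate
    eeg = {}
    for ch in rest_cfg.eeg_channels:
        trace = rest_cfg.eeg_noise_uv * rng.standard_normal(n)
        if ch in HOTSPOT:
            for f in (10.0, 20.0):
                trace += rest_cfg.osc_amp_uv * np.sin(
                    2 * np.pi * f * tt + rng.uniform(0, 2 * np.pi))
        eeg[ch] = trace
    truth = GroundTruth(
        r_times=np.array([b.r_time for b in beats]),
        t_ends=np.array([b.t_end for b in beats]),
        rr=np.array([b.rr for b in beats]),
        z=np.array([b.z for b in beats]),
        config=asdict(rest_cfg),
    )
    labels = list(rest_cfg.eeg_channels) + ["ECG", "EMG"]
    data = np.vstack([eeg[ch] for ch in rest_cfg.eeg_channels] + [ecg, emg])
    roles = ["eeg"] * len(rest_cfg.eeg_channels) + ["ecg", "emg"]
    rec = Recording(data, rest_cfg.rate, labels, roles)
    return rec, EventList(np.empty(0), []), truth
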