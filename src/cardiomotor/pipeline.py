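"""End-to-end study orchestration on synthetic sessions.

``run_study`` simulates a cohort of participants, runs every analysis stage
on each session (cardiac phase classification from the ECG, MEP extraction
and validity filtering, the TMS-EEG cleaning pipeline and TEP contrast, the
mock-event HEP analysis with MEP tertiles, the pinch-task envelope and ERD
analysis, and interbeat-interval dynamics), and aggregates the group-level
statistics into a structured report.  Every stochastic step derives its
seed from the global study seed, so a rerun with the same configuration is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import cardiac, emg, hep, stats, synthgen, tep, tfr
from .core_io import epoch
from .exceptions import StageError
from .synthgen import SynthConfig


@dataclass
class StudyConfig:
    """Scale and toggles for a full synthetic study."""

    seed: int = 0
    n_participants: int = 36
    synth: SynthConfig = field(default_factory=SynthConfig)
    n_perm: int = 1000
    do_mep: bool = True
    do_ibi: bool = True
    do_tep: bool = True
    do_hep: bool = True
    do_pinch: bool = True
    do_lme: bool = True
    do_rest: bool = True
    rest_duration_s: float = 120.0
    tep_cfg: tep.TepPipelineConfig = field(default_factory=tep.TepPipelineConfig)
    hep_cfg: hep.HepConfig = field(default_factory=hep.HepConfig)
    tfr_cfg: tfr.TfrConfig = field(default_factory=tfr.TfrConfig)


def _participant_cfg(cfg: StudyConfig, i: int) -> SynthConfig:
    d = dataclasses.asdict(cfg.synth)
    d["seed"] = int((cfg.seed * 10007 + i * 101 + 1) % (2 ** 31))
    return SynthConfig(**d)


# ---------------------------------------------------------------------------
# per-session analysis
# ---------------------------------------------------------------------------

def analyze_session(rec, events, scfg: SynthConfig, study: StudyConfig,
                    seed: int) -> dict:
    """Run the single-participant analyses; returns derived quantities."""
    out: dict = {}
    ecg = rec.channel("ECG")
    ecg_clean = cardiac.interpolate_stim_artifact_ecg(
        ecg, rec.rate, events.times)
    r_peaks = cardiac.detect_r_peaks(ecg_clean, rec.rate)
    t_ends = cardiac.detect_t_end(ecg_clean, r_peaks, rec.rate)
    cmap = cardiac.build_cardiac_map(r_peaks, t_ends)
    classified = cardiac.classify_events(events, cmap)
    out["cardiac"] = {"n_beats": int(cmap.n_beats),
                      "mean_systole_ms": float(
                          np.nanmean(cmap.systole_len[cmap.usable]) * 1000)}

    amp_by = {}
    for cond in ("tms", "sham"):
        if not any(l == cond for l in classified.labels):
            continue
        ep = epoch(rec, classified, cond, -0.2, 0.1,
                   baseline=(-0.110, -0.010))
        amps = emg.mep_amplitude(ep)
        recs = emg.validate_trials(emg.mep_records(ep, amps, cond))
        amp_by[cond] = recs
    out["mep_records"] = amp_by
    if study.do_mep and "tms" in amp_by:
        means = {}
        for cond, recs in amp_by.items():
            means[cond] = {
                ph: float(np.mean([r.amplitude_uv for r in recs
                                   if r.valid and r.phase == ph]) or np.nan)
                for ph in ("systole", "diastole")
            }
        out["mep_phase_means"] = means

    if study.do_ibi:
        ibi = {}
        for cond in ("tms", "sham"):
            sel = classified.select(cond)
            if len(sel) == 0:
                continue
            phases = [m.get("phase", "neither") for m in sel.meta]
            trips, dropped = cardiac.ibi_triplets(sel.times, r_peaks, phases)
            ibi[cond] = {"triplets": trips, "dropped": dropped,
                         "table": cardiac.ibi_table(trips)}
        out["ibi"] = ibi

    if study.do_tep:
        teps = {}
        for cond in ("tms", "sham"):
            sel = classified.select(cond)
            if len(sel) == 0:
                continue
            clean = tep.run_tep_pipeline(
                rec, classified, cfg=study.tep_cfg, label=cond, seed=seed)
            teps[cond] = tep.tep_contrast(clean, study.tep_cfg)
        out["tep"] = teps
        if "tms" in teps and "sham" in teps:
            out["tep_corrected"] = tep.sham_correct_tep(
                teps["tms"], teps["sham"])

    if study.do_hep and "tms" in amp_by:
        sel = classified.select("tms")
        meta = sel.meta
        try:
            idx, dist = hep.select_late_tms_trials(meta, study.hep_cfg)
            template = hep.estimate_mock_artifact(
                rec, sel.times[idx], dist, study.hep_cfg, seed=seed)
            lock = sel.times[idx] - dist / 1000.0
            heps = hep.extract_hep(rec, lock, template, study.hep_cfg)
            amps = np.array([amp_by["tms"][i].amplitude_uv for i in idx])
            out["hep"] = hep.hep_tertile_contrast(heps, amps, study.hep_cfg)
            chans = [c for c in study.hep_cfg.electrodes if c in heps.labels]
            ci = [heps.index(c) for c in chans]
            sl = heps.time_slice(*study.hep_cfg.test_window_s)
            out["hep_all_mean"] = heps.data[
                np.ix_(range(heps.n_trials), ci,
                       range(sl.start, sl.stop))].mean(axis=0)
        except Exception as exc:  # small sessions may lack late trials
            out["hep_error"] = str(exc)
        # previous-cycle variant: early pulses, preceding cycle's heartbeat
        try:
            kept, locks, pdist = hep.previous_cycle_locks(
                sel.times, r_peaks, study.hep_cfg)
            template = hep.estimate_mock_artifact(
                rec, sel.times[kept], pdist, study.hep_cfg, seed=seed + 1)
            heps_prev = hep.extract_hep(rec, locks, template, study.hep_cfg)
            amps_prev = np.array(
                [amp_by["tms"][i].amplitude_uv for i in kept])
            out["hep_prev"] = hep.hep_tertile_contrast(
                heps_prev, amps_prev, study.hep_cfg,
                window=study.hep_cfg.early_test_window_s)
        except Exception as exc:
            out["hep_prev_error"] = str(exc)
    return out


def analyze_rest(scfg, study: StudyConfig, seed: int) -> dict:
    """Resting-state controls: R-locked HEP and phase-sampled EMG envelope."""
    rest, _, truth = synthgen.gen_rest(scfg, duration_s=study.rest_duration_s)
    ecg = rest.channel("ECG")
    r = cardiac.detect_r_peaks(ecg, rest.rate)
    te = cardiac.detect_t_end(ecg, r, rest.rate)
    cmap = cardiac.build_cardiac_map(r, te)
    out: dict = {}

    heps = hep.rest_hep(rest, r, study.hep_cfg)
    chans = [c for c in study.hep_cfg.electrodes if c in heps.labels]
    if chans:
        ci = [heps.index(c) for c in chans]
        sl = heps.time_slice(*study.hep_cfg.test_window_s)
        out["hep_rest_mean"] = heps.data[
            np.ix_(range(heps.n_trials), ci,
                   range(sl.start, sl.stop))].mean(axis=0)

    times, phases, _ = emg.rest_control_sampling(rest, cmap, 30, seed=seed)
    if times.size >= 4:
        from .core_io import EventList
        ev = EventList(times, ["rest_probe"] * times.size,
                       [{"phase": p} for p in phases])
        ep = epoch(rest, ev, "rest_probe", -0.2, 0.3)
        band_hi = min(500.0, 0.4 * rest.rate)
        env = emg.emg_envelope(ep, band=(10.0, band_hi))
        win = ep.time_slice(0.0, 0.25)
        means = {}
        for ph in ("systole", "diastole"):
            rows = [i for i, m in enumerate(ep.trial_meta)
                    if m["phase"] == ph]
            if rows:
                means[ph] = float(env[rows][:, win].mean())
        if len(means) == 2:
            out["rest_emg_contrast"] = means["systole"] - means["diastole"]
    return out


def analyze_pinch(rec, events, truth, study: StudyConfig) -> dict:
    """Pinch-task single-participant analysis: onsets, envelope, ERD."""
    ecg = rec.channel("ECG")
    r_peaks = cardiac.detect_r_peaks(ecg, rec.rate)
    t_ends = cardiac.detect_t_end(ecg, r_peaks, rec.rate)
    cmap = cardiac.build_cardiac_map(r_peaks, t_ends)

    # movement onsets from the EMG, then phase per onset
    ep_raw = epoch(rec, events, "pinch_on", -1.0, 4.0)
    ch = ep_raw.index("EMG")
    onset_times = []
    for i in range(ep_raw.n_trials):
        on = emg.tke_onset(ep_raw.data[i, ch], rec.rate,
                           baseline_s=(0.0, 0.8))
        t_ev = events.select("pinch_on").times[i]
        onset_times.append(t_ev if on is None else t_ev - 1.0 + on)
    from .core_io import EventList
    onset_events = EventList(np.array(onset_times),
                             ["pinch_on"] * len(onset_times))
    classified = cardiac.classify_events(onset_events, cmap)

    ep = epoch(rec, classified, "pinch_on", -1.0, 4.0)
    band_hi = min(500.0, 0.4 * rec.rate)  # full band needs >= 1250 Hz rates
    env = emg.emg_envelope(ep, band=(10.0, band_hi))
    bsl = ep.time_slice(-0.110, -0.010)
    env = env - env[:, bsl].mean(axis=1, keepdims=True)
    win = ep.time_slice(0.0, 1.0)
    phases = [m.get("phase") for m in ep.trial_meta]
    env_means = {
        ph: env[[i for i, p in enumerate(phases) if p == ph], win].mean(axis=0)
        for ph in ("systole", "diastole")
        if any(p == ph for p in phases)
    }

    tfr_res = tfr.compute_tfr(ep, study.tfr_cfg)
    erd_maps = tfr.erd_contrast(tfr_res, study.tfr_cfg)
    return {"onsets": onset_times, "phases": phases,
            "envelope": env_means, "erd": erd_maps,
            "env_times": ep.times[win]}


# ---------------------------------------------------------------------------
# group-level aggregation
# ---------------------------------------------------------------------------

def _wilcoxon_block(sys_vals, dia_vals):
    diffs = np.asarray(sys_vals) - np.asarray(dia_vals)
    w = stats.wilcoxon_signed_rank(diffs)
    return {"V": w.V, "p": w.p, "n": w.n, "method": w.method,
            "cohens_d": stats.cohens_d_paired(diffs),
            "mean_systole": float(np.mean(sys_vals)),
            "mean_diastole": float(np.mean(dia_vals))}


def _cluster_block(a, b, n_perm, seed, adjacency=None):
    res = stats.cluster_perm_test(np.asarray(a), np.asarray(b),
                                  adjacency=adjacency, n_perm=n_perm,
                                  seed=seed)
    return {"n_clusters": len(res.clusters),
            "min_p": min((c.p for c in res.clusters), default=1.0),
            "significant": bool(res.significant),
            "largest_mass": (abs(res.clusters[0].mass)
                             if res.clusters else 0.0),
            "method": res.method, "n_perm": res.n_perm}


def run_study(cfg: StudyConfig) -> dict:
    """Simulate and analyze a full cohort; return the structured report."""
    per, pinch_per, rest_per = [], [], []
    lme_rows = {"amp": [], "dist": [], "pid": []}
    for i in range(cfg.n_participants):
        scfg = _participant_cfg(cfg, i)
        try:
            rec, events, truth = synthgen.gen_session(scfg)
            sess = analyze_session(rec, events, scfg, cfg,
                                   seed=scfg.seed + 7)
        except StageError:
            raise
        per.append(sess)
        if cfg.do_lme and "tms" in sess.get("mep_records", {}):
            for r in sess["mep_records"]["tms"]:
                if r.valid and r.distance_ms is not None:
                    lme_rows["amp"].append(r.amplitude_uv)
                    lme_rows["dist"].append(r.distance_ms)
                    lme_rows["pid"].append(i)
        if cfg.do_pinch:
            prec, pevents, ptruth = synthgen.gen_pinch_task(scfg)
            pinch_per.append(analyze_pinch(prec, pevents, ptruth, cfg))
        if cfg.do_rest:
            rest_per.append(analyze_rest(scfg, cfg, seed=scfg.seed + 13))

    report: dict = {"seed": cfg.seed, "n_participants": cfg.n_participants,
                    "config": dataclasses.asdict(cfg.synth)}

    if cfg.do_mep:
        sysm = [p["mep_phase_means"]["tms"]["systole"] for p in per]
        diam = [p["mep_phase_means"]["tms"]["diastole"] for p in per]
        report["mep"] = _wilcoxon_block(sysm, diam)
        if all("sham" in p["mep_phase_means"] for p in per):
            sys_c = [p["mep_phase_means"]["tms"]["systole"]
                     - p["mep_phase_means"]["sham"]["systole"] for p in per]
            dia_c = [p["mep_phase_means"]["tms"]["diastole"]
                     - p["mep_phase_means"]["sham"]["diastole"] for p in per]
            report["mep_sham_corrected"] = _wilcoxon_block(sys_c, dia_c)
        amps = np.array(lme_rows["amp"])
        dists = np.array(lme_rows["dist"])
        report["mep_profile"] = {
            k: v.tolist() for k, v in
            stats.binned_mep_profile(amps, dists).items()}

    if cfg.do_ibi:
        tables = [p["ibi"]["tms"]["table"] for p in per]
        cells = np.array([
            [[tab[(iv, ph)] for ph in ("systole", "diastole")]
             for iv in ("pre", "tms", "post")]
            for tab in tables])  # participants x 3 x 2
        report["ibi_anova"] = stats.rm_anova_2way(cells)
        d_sys = cells[:, 1, 0] - cells[:, 0, 0]
        d_sys_post = cells[:, 1, 0] - cells[:, 2, 0]
        report["ibi_posthoc"] = {
            "systole_tms_minus_pre_ms": float(np.mean(d_sys)),
            "systole_tms_minus_post_ms": float(np.mean(d_sys_post)),
            "diastole_tms_minus_pre_ms": float(
                np.mean(cells[:, 1, 1] - cells[:, 0, 1])),
        }
        if all("sham" in p["ibi"] for p in per):
            corr = []
            for p in per:
                trips = cardiac.ibi_sham_correct(
                    p["ibi"]["tms"]["triplets"], p["ibi"]["sham"]["triplets"])
                tab = cardiac.ibi_table(trips)
                corr.append([[tab[(iv, ph)]
                              for ph in ("systole", "diastole")]
                             for iv in ("pre", "tms", "post")])
            report["ibi_anova_sham_corrected"] = stats.rm_anova_2way(
                np.array(corr))

    if cfg.do_tep:
        waves = {c: {} for c in ("tms", "sham")}
        for cond in ("tms", "sham"):
            for ph in ("systole", "diastole"):
                waves[cond][ph] = np.array(
                    [p["tep"][cond]["per_phase"][ph] for p in per])
        report["tep_cluster"] = {
            cond: _cluster_block(waves[cond]["systole"][:, None, :],
                                 waves[cond]["diastole"][:, None, :],
                                 cfg.n_perm, cfg.seed + 11)
            for cond in ("tms", "sham")}
        corr_s = waves["tms"]["systole"] - waves["sham"]["systole"]
        corr_d = waves["tms"]["diastole"] - waves["sham"]["diastole"]
        report["tep_cluster"]["corrected"] = _cluster_block(
            corr_s[:, None, :], corr_d[:, None, :], cfg.n_perm, cfg.seed + 12)
        report["tep_window_mean"] = {
            cond: {ph: float(waves[cond][ph].mean())
                   for ph in ("systole", "diastole")}
            for cond in ("tms", "sham")}

    if cfg.do_hep:
        strong = [p["hep"]["strong"].mean(axis=0) for p in per
                  if "hep" in p]
        weak = [p["hep"]["weak"].mean(axis=0) for p in per if "hep" in p]
        if len(strong) >= 2:
            report["hep_cluster"] = _cluster_block(
                np.array(strong), np.array(weak), cfg.n_perm, cfg.seed + 13)
            report["hep_window_mean"] = {
                "strong": float(np.mean([s.mean() for s in strong])),
                "weak": float(np.mean([w.mean() for w in weak]))}
        prev_s = [p["hep_prev"]["strong"].mean(axis=0) for p in per
                  if "hep_prev" in p]
        prev_w = [p["hep_prev"]["weak"].mean(axis=0) for p in per
                  if "hep_prev" in p]
        if len(prev_s) >= 2:
            report["hep_prev_cluster"] = _cluster_block(
                np.array(prev_s), np.array(prev_w), cfg.n_perm, cfg.seed + 16)
            report["hep_prev_window_mean"] = {
                "strong": float(np.mean([s.mean() for s in prev_s])),
                "weak": float(np.mean([w.mean() for w in prev_w]))}

    if cfg.do_rest and rest_per:
        tms_hep = [p.get("hep_all_mean") for p in per]
        rest_hep_m = [r.get("hep_rest_mean") for r in rest_per]
        pairs = [(a, b) for a, b in zip(tms_hep, rest_hep_m)
                 if a is not None and b is not None and a.shape == b.shape]
        if len(pairs) >= 2:
            report["hep_rest_vs_tms_cluster"] = _cluster_block(
                np.array([a for a, _ in pairs]),
                np.array([b for _, b in pairs]), cfg.n_perm, cfg.seed + 17)
        contrasts = [r["rest_emg_contrast"] for r in rest_per
                     if "rest_emg_contrast" in r]
        if len(contrasts) >= 2:
            w = stats.wilcoxon_signed_rank(np.array(contrasts))
            report["rest_emg_phase_contrast"] = {
                "mean_uv": float(np.mean(contrasts)), "V": w.V, "p": w.p}

    if cfg.do_pinch and pinch_per:
        pairs = [p for p in pinch_per
                 if {"systole", "diastole"} <= set(p["envelope"])]
        env_s = [p["envelope"]["systole"] for p in pairs]
        env_d = [p["envelope"]["diastole"] for p in pairs]
        if len(pairs) >= 2:
            report["envelope_cluster"] = _cluster_block(
                np.array(env_s)[:, None, :], np.array(env_d)[:, None, :],
                cfg.n_perm, cfg.seed + 14)
            report["envelope_mean"] = {
                "systole": float(np.mean(env_s)),
                "diastole": float(np.mean(env_d))}
        erd_pairs = [p for p in pinch_per
                     if {"systole", "diastole"} <= set(p["erd"]["mean"])]
        erd_s = [p["erd"]["mean"]["systole"] for p in erd_pairs]
        erd_d = [p["erd"]["mean"]["diastole"] for p in erd_pairs]
        if len(erd_pairs) >= 2:
            report["erd_cluster"] = _cluster_block(
                np.array(erd_s), np.array(erd_d), cfg.n_perm, cfg.seed + 15)
            report["erd_mean"] = {
                "systole": float(np.mean(erd_s)),
                "diastole": float(np.mean(erd_d))}

    if cfg.do_lme and lme_rows["amp"]:
        cmp_ = stats.lme_distance_models(
            np.array(lme_rows["amp"]), np.array(lme_rows["dist"]),
            np.array(lme_rows["pid"]))
        report["lme"] = {
            "loglik": cmp_.loglik,
            "lrt": {k: {"chi2": v[0], "df": v[1], "p": v[2]}
                    for k, v in cmp_.lrt.items()},
            "singular": cmp_.singular,
            "linear_slope_per_s": cmp_.coefficients["linear"][1],
        }
    return report


def write_report(report: dict, path) -> None:
    """Serialize the report deterministically (sorted keys, fixed floats)."""

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, np.bool_):
            return bool(o)
        raise TypeError(f"unserializable {type(o)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=default)
        fh.write("\n")
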