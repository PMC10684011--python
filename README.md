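# cardiomotor

Cardiac-phase-resolved analysis of motor excitability from combined
EEG/ECG/EMG recordings.

The heart modulates the brain: whether a transcranial magnetic stimulation
(TMS) pulse arrives during **systole** (ventricular contraction, R-peak to
T-wave end) or **diastole** (the relaxation phase at the end of the cycle)
can change the size of the motor-evoked potential (MEP) in the hand, the
TMS-evoked potential (TEP) over motor cortex, and movement-related
desynchronization of sensorimotor rhythms.  Testing this requires a chain
of specialised steps — beat-by-beat ECG delineation, TMS artifact removal,
heartbeat-evoked potential (HEP) extraction, and permutation statistics —
that this package implements as a tested, reusable pipeline, together with
a synthetic-session generator that makes every step verifiable against
known ground truth.

## What's inside

| module      | role |
|-------------|------|
| `core_io`   | `Recording`/`EventList`/`EpochArray` containers, EDF + text-bundle I/O, epoching, zero-phase Butterworth filters, mastoid re-referencing, polyphase resampling |
| `synthgen`  | synthetic sessions: quasi-periodic ECG, TMS/sham schedules, MEPs with phase and distance effects, TEP/HEP deflections, pinch-task EMG + ERD, stimulation artifacts, phase-dependent heart-rate dynamics |
| `cardiac`   | R-peak detection, T-wave-end delineation by trapezoid-area maximization, equal-length systole/diastole windows, event phase classification, interbeat-interval triplets around TMS |
| `emg`       | peak-to-peak MEP amplitude (20–40 ms), 50 µV validity rules, rectified 8 Hz EMG envelope, Teager–Kaiser movement onsets, sham/rest controls |
| `tep`       | the multi-stage TMS-EEG cleaning pipeline (pulse excision, two ICA rounds, cubic interpolation, filtering, re-referencing, downsampling) and hotspot TEP contrasts |
| `hep`       | mock-event estimation of the TMS artifact in the pre-stimulus window, R-locked HEP extraction, MEP-tertile contrasts |
| `tfr`       | Morlet wavelets with a linear 4→10-cycle scheme over 5–40 Hz; event-related desynchronization maps |
| `stats`     | cluster-based permutation t tests (sign-flip null, exhaustive for small n), exact Wilcoxon signed-rank, two-way rm-ANOVA with generalized η² and Greenhouse–Geisser correction, mixed-model distance comparisons, paired-t power analysis |
| `pipeline`  | `run_study`: simulate a cohort, run every analysis, emit a reproducible JSON report |

Key definitions: systole is `[R, T-end]` per beat; diastole is the window
of *equal length* ending at the next R-peak, so a uniformly-timed stimulus
is equally likely to land in either phase.  T-wave end maximizes the
trapezoid area `A(i) = ½ (y_m − y_i)(2x_r − x_i − x_m)` between the T-peak
`(x_m, y_m)` and a reference point `x_r` on the post-wave flat segment.
The Morlet wavelet at frequency *f* has `n(f) = 4 + 6(f − 5)/35` cycles,
hence spectral width `σ_f = f/n` and FWHM `2√(2 ln 2)·σ_f`.

## Worked example

Simulate a small session with a 30 % systolic MEP boost, classify each
pulse by cardiac phase from the ECG alone, and test the contrast:

```python
import numpy as np
from cardiomotor import cardiac, emg, stats
from cardiomotor.core_io import epoch
from cardiomotor.synthgen import SynthConfig, gen_session

cfg = SynthConfig(seed=11, rate=1000.0, n_tms=60, n_sham=60,
                  mep_systole_gain=1.3, mep_distance_slope=4e-4)
rec, events, truth = gen_session(cfg)

ecg = cardiac.interpolate_stim_artifact_ecg(rec.channel("ECG"),
                                            rec.rate, events.times)
r = cardiac.detect_r_peaks(ecg, rec.rate)
t_end = cardiac.detect_t_end(ecg, r, rec.rate)
cmap = cardiac.build_cardiac_map(r, t_end)
classified = cardiac.classify_events(events, cmap)

ep = epoch(rec, classified, "tms", -0.2, 0.1, baseline=(-0.110, -0.010))
amps = emg.mep_amplitude(ep)
phases = [m["phase"] for m in ep.trial_meta]
sys_a = amps[[p == "systole" for p in phases]]
dia_a = amps[[p == "diastole" for p in phases]]
print(f"mean systole L = {np.mean(cmap.systole_len[cmap.usable])*1000:.0f} ms")
print(f"MEP systole {sys_a.mean():.0f} uV vs diastole {dia_a.mean():.0f} uV, "
      f"ratio {np.exp(np.log(sys_a).mean() - np.log(dia_a).mean()):.2f}")
```

Output:

```
mean systole L = 362 ms
MEP systole 567 uV vs diastole 442 uV, ratio 1.31
```

The detected systole length tracks the generated ~350 ms windows, and the
systole/diastole log-amplitude ratio recovers the injected multiplicative
gain of 1.3 (in this run the distance decline happens to balance out; in
general the log-linear decline with distance from the R-peak adds to the
raw phase contrast, and the two effects are disentangled by the
mixed-model comparison in `stats.lme_distance_models`).

A whole synthetic cohort, ending in a JSON report with Wilcoxon/cluster/
ANOVA/mixed-model results, runs from the shell:

```sh
cardiomotor run --seed 1 --participants 4 --out report.json
```

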