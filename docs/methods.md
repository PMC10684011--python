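# Methods

This note documents the models, procedures and numerical choices behind
`cardiomotor`, and what the synthetic-data tests do and do not establish
about real recordings.

## Cardiac phase model

A cardiac cycle runs from one R-peak to the next.  **Systole** is
operationalized as the interval from the R-peak to the end of the T-wave
(ventricular contraction and ejection); **diastole** as the window of
*exactly the same length* ending at the next R-peak.  Equal lengths make a
uniformly-timed external event equally likely to fall in either window, so
phase contrasts are not confounded by unequal sampling time — the package
asserts this equalization property directly (10,000 uniform events, binomial
test).  Events in the remainder of the cycle are labelled `neither`; they
are excluded from phase contrasts but retain their distance-from-R metadata
for the distance-model and binned-profile analyses.  A beat is unusable for
classification when the T-end is not detectable, no next beat exists, or
`RR <= 2 L` (windows would overlap).

### T-wave end: trapezoid-area delineation

Within a post-R search window (default 80–450 ms, clipped before the next
R), the T-peak `(x_m, y_m)` is the largest-magnitude deflection from the
local median; a reference point `x_r` is placed 120 ms beyond the search
bound (clipped 10 ms before the next R).  The T-end is the sample `x_i`
maximizing

    A(i) = 1/2 · (y_m − y_i) · (2 x_r − x_i − x_m),

with ties broken toward the earliest sample and sign-flipped handling for
negative T-waves.  Beats whose T deflection is below 40 µV (default) are
flagged unusable.  The constants (search window, reference offset,
prominence floor) are exposed as function arguments because no single
convention exists; with the defaults, the detector lands within a few
milliseconds of the analytic truth on the generator's Gaussian T-waves
(median error well under 15 ms for mean RR between 700 and 1100 ms).

### R-peaks and interbeat intervals

R-peaks are found by 5–30 Hz band-pass emphasis, automatic polarity
correction, percentile-thresholded peak picking with a 250 ms refractory
period, and refinement to the local raw extremum.  Degenerate inputs (white
noise, flat traces) raise a detection error rather than returning garbage.
Heart-rate dynamics around stimulation are summarized as IBI triplets — the
RR of the cycle before, containing, and after each event — with sham
correction by subtracting the sham mean per (interval × phase) cell.

## Synthetic sessions

The generator emits ECG + EEG + EMG at a configurable rate (default 5 kHz)
with: Gaussian QRS and T-wave shapes whose analytic T-end (centre + 2.5 σ)
is the delineation truth; per-beat RR from a truncated normal (defaults
900 ± 50 ms); TMS and sham pulses at uniform 1.5–2.5 s intervals (defaults
416 + 416, the scale of a full stimulation protocol; tests use scaled-down
counts); MEPs injected 20–40 ms post-pulse with

    ln A = ln(base) − slope · distance_ms + ln(gain) · [systole]
           + σ_z · z_beat + σ_trial · ε,

where `z_beat` is a shared per-beat excitability latent that also scales
the heartbeat-evoked deflection (296–400 ms post-R, centroparietal
channels) — this is the generative counterpart of an HEP–MEP coupling, and
the latent of the most recent *completed* heartbeat response is used for
early-cycle pulses; TEP half-sine deflections 22–60 ms post-pulse on the
hotspot channels with a multiplicative systolic gain; a pulse spike plus
exponential decay artifact on all EEG channels for real and sham pulses
alike, with electrode-dependent amplitude *and polarity* (electrode
polarization differs across the cap, and a mixed-sign topography is also
what makes the artifact spatially separable); and phase-dependent IBI
dynamics (systolic pulses lengthen the current cycle by `ibi_decel_ms` and
shorten the next by `ibi_accel_ms`).  The pinch-task generator adds EMG
bursts under a raised-cosine rise/hold envelope and a 10/20 Hz sensorimotor
rhythm whose power drops by the fraction `erd_depth` (amplitude × √(1−d))
for ~700 ms after each onset, deeper by `erd_systole_gain` for systolic
onsets.

Everything is driven by one `numpy` generator seeded from the config, so
identical configs give byte-identical output.  What the generator does
**not** emulate: realistic ECG morphology (P-waves, QT adaptation),
1/f EEG background, respiratory modulation, electrode drift, or movement
artifacts.  Passing tests therefore demonstrate that the *pipeline*
recovers what it claims under known conditions — not that those conditions
exhaust real data.

## TMS-EEG cleaning

The cleaning chain, in order: wide epochs (−1400 to 1000 ms); −110 to
−10 ms baseline; excision of the −2 to 8 ms pulse window (exclusion mask,
not deletion); ICA round 1 for the decay artifact; 0.5–45 Hz band-pass +
45–55 Hz band-stop (both 4th-order Butterworth, forward–backward so group
delay is zero and the effective order doubles); ICA round 2 for residual
artifacts, whose unmixing is estimated on the *filtered* data but applied
to the unfiltered copy kept after round 1; cubic interpolation across −2 to
15 ms (display only — the samples stay masked out of every statistic);
mastoid re-referencing; polyphase downsampling to 500 Hz.  Every stage logs
its parameters and removed-component counts in a provenance record, and
re-running the pipeline on its own output raises a provenance warning.

Round-1 component selection ranks components by the variance of their
back-projection within −150 to 150 ms, but a component is only removed if
that variance is also *concentrated* there (window-to-total variance ratio
above 2).  An unconditional "remove the top k" rule destroys genuine signal
whenever no decay is present — with 18 channels, deleting 3 arbitrary
components costs ~40 % of the RMS — whereas the concentration gate makes
the stage a near-identity on artifact-free data (<10 % RMS deviation,
asserted) while still removing >80 % of the decay-window variance when the
artifact exists.  The configured count (default 3) remains the cap.
FastICA non-convergence is tolerated after three reseeds and logged: the
rejection rules only need the artifact subspace, not a fully converged
rotation.  Round-2 classification is heuristic (ECG-correlated sources,
frontal-dominant topographies) and deliberately conservative; a
manual-override component list takes precedence, because expert visual
selection cannot be automated faithfully.  The removed-component count is
logged, never targeted.  A known property of this class of pipeline: the
spatial projection that removes the decay also absorbs part of the evoked
response *common* to all trials, biasing absolute TEP levels; the
phase *contrast* is preserved (asserted), and the sham condition — run
through the identical pipeline — absorbs the common bias.

## Heartbeat-evoked potentials

Trials with the pulse ≥400 ms after the previous R keep the −100 to 400 ms
HEP window free of stimulation; the TMS artifact that still leaks in is
estimated by shuffling the R-to-pulse distance list (10 uniform random
permutations, seeded), placing mock events at `pulse − shuffled distance`,
and averaging epochs over all mock events — heartbeat-locked content
averages out, pulse-locked content survives.  The template converges on a
white-noise background at the usual 1/√N rate and removes ≥70 % of
pulse-locked energy in the test window (asserted).  Trials are then sorted
by MEP amplitude into three bins per participant (remainder to the lower
bins; ties stable by trial index); the contrast uses bins 3 vs 1.  The
variants swap the selection rule (early-cycle pulses → previous cycle's
HEP, test window 362–394 ms) or the event source (resting R-peaks).  The
template is estimated per participant with blocks pooled.

## Time–frequency analysis

Complex Morlet wavelets on a 1 Hz grid from 5 to 40 Hz with the cycle
count rising linearly from 4 to 10, unit-energy normalization.  With
`σ_t = n/(2πf)` the spectral width is `σ_f = f/n` and the FWHM
`2√(2 ln 2)·σ_f` — 4.85 Hz at 10 Hz, where the wavelet is 4.9 cycles long
and `σ_t ≈ 77 ms` (the temporal FWHM is ~182 ms under the matching
convention; 2σ of the power envelope gives ~109 ms — both are reported
since the two conventions are often conflated).  ERD is the relative power
change against a −900 to −100 ms baseline (epoch −1000 to 4000 ms; the
baseline window is this package's choice of the standard relative-change
convention), computed per trial and averaged per phase; it is invariant to
static channel gain by construction.  Edge samples within half a wavelet
support are flagged.

## Statistics

* **Cluster-based permutation t test** — per-sample paired t thresholded at
  the two-tailed 5 % critical value; suprathreshold samples clustered by
  sign with channel adjacency on the first axis (distance-threshold graph
  on the standard 10-10 montage, or a user TSV edge list) and chain
  adjacency along time/frequency; cluster mass = Σt.  The null records the
  maximum |mass| over random within-participant sign flips of the
  differences; with `2^n ≤ 4096` all patterns are enumerated and p values
  are exact, otherwise `p = (1 + #{null ≥ obs})/(1 + n_perm)` (the +1
  correction guarantees validity; the difference from the raw proportion is
  ≤ 1/(n_perm+1)).  Because the max statistic pools both tails, the p
  values are already two-tailed and a cluster is significant at p < 0.05;
  declaring at α/2 on top of the pooled-max null would double-correct and
  push the family-wise error to ~2.5 %.  Calibration at the nominal level
  is asserted by simulation.
* **Wilcoxon signed-rank** — V = sum of positive-difference ranks, zeros
  dropped, midranks for ties; exact distribution by subset-sum counting for
  n ≤ 25, normal approximation with tie and continuity corrections beyond;
  verified against an independent implementation and full enumeration.
* **Two-way repeated-measures ANOVA** — textbook within-subject sums of
  squares; generalized eta squared uses all subject-related error terms in
  the denominator; Mauchly's test on orthonormalized contrasts for factors
  with >2 levels (difference scores for the interaction when the other
  factor has 2 levels), Greenhouse–Geisser ε applied when Mauchly p < 0.05.
  Verified against an independent implementation on fixed tables.
* **Distance models** — ln(MEP) with a participant random intercept,
  fit by maximum likelihood (distance rescaled to seconds for
  conditioning); null vs linear vs quadratic compared by likelihood-ratio
  χ² with 1 df per step.  The random-effect variance can sit on the
  boundary; optimizers are tried in sequence and the first finite
  likelihood is used, with boundary/singular fits flagged but still
  reported.  A single participant reduces exactly to OLS.
* **Power analysis** — two-sided paired/one-sample noncentral-t power,
  solved continuously in n.  The default reports the conventionally quoted
  (nearest-integer) sample size — d = 0.48 at 80 % power, α = 0.05 gives a
  continuous root of 36.03, quoted as N = 36 — while `rounding="ceil"`
  guarantees `power(n) ≥ 0.8 > power(n−1)` (which yields 37 for the same
  inputs, since power(36) = 0.7996).

## Problem sizes in the test suite

The suite exercises everything end-to-end at reduced scale, chosen so each
property remains statistically decisive: sessions of 30–60 pulses at
250–1000 Hz for detection/recovery tests, 200 null studies of 8
participants for the type-I calibration of Wilcoxon/ANOVA/LME, 200–500
null datasets for cluster-test family-wise error (exhaustive enumeration
over 2^10 sign patterns), 100 sessions for gain recovery, and one
4-participant all-effects cohort for the qualitative direction pattern.
Calibration assertions use exact binomial acceptance bands around the
attainable rejection probability (discrete for the exact tests).

## Known limitations

* The generator's white-noise EEG background makes cluster tests more
  sensitive than they would be on autocorrelated real EEG; calibration
  (type-I error) is unaffected, power figures do not transfer.
* Round-2 ICA heuristics are minimal; on real data the manual-override
  sidecar is the expected path.
* The EDF writer requires integer sampling rates and whole-second
  durations; 16-bit quantization bounds the round-trip error at
  `range/2^16` per channel.  The text bundle is lossless.
* Arrhythmia, P-wave delineation, and source reconstruction are out of
  scope.
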