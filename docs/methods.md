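# Methods

`cardiotel` analyses continuous radio-telemetry from a murine hindlimb-
unloading (HU) protocol: three control days (C-3..C-1), five unloading days
(HU1..HU5) and two recovery days (R+1, R+2), under a 12:12 light/dark
schedule (lights on 07:00, off 19:00) with a daily handling hour
(10:00-11:00) excluded from all aggregate statistics. This note records the
models, the defaults and the genuinely open design choices.

## Data model and time base

Beat-level data are R-peak times in seconds from recording start plus the
derived RR intervals in ms; an absolute anchor datetime in the CSV header
ties the recording to the clock schedule. The validity flag is stored per
RR interval (the flag of the beat terminating the interval), because the
cleaning rule, the time-domain exclusions and the generator truth masks all
operate on intervals. Channel-level data (activity counts, temperature in
degC, pressures in mmHg, heart rate in bpm) are timestamped samples; the
reader accepts the long CSV layout of the deposited 2 h-bin datasets (one
value per subject per channel per bin) with bins labelled by their start
time, which aligns with the 07:00 lights-on boundary. Day labels roll over
at midnight; the "24 h mean" is therefore a 23-hour mean over the retained
samples.

## Synthetic data

The generators define the study conditions for every test; they are pure
functions of their spec (seed included).

**Beat series (IPFM).** An instantaneous RR signal — mean RR plus LF
(0.10-1.00 Hz) and HF (1.00-5.00 Hz) cosines — defines a continuous beat
rate `1000/rr(t)` whose integral emits a beat at each unit crossing
(integrated by trapezoid on a 1 ms grid). Defining the oscillations in
continuous time, rather than adding sinusoids to discrete RR values, means
the resampling + Welch chain is tested on the kind of signal it assumes.
Note that linear interpolation of a beat-sampled tachogram attenuates
amplitude at frequencies approaching the beat rate, so recovered HF *power*
is below the continuous-time value even though localisation is exact; the
spectral checks therefore assert band fractions and closed-form sinusoid
power, not IPFM amplitude recovery. Ectopics replace a beat with an early
beat at 0.6 of its interval followed by the compensatory pause (total time
preserved) — the standard morphology the cleaning rule must catch.

**Baroreflex coupling.** Beat-aligned SBP is a mean-reverting AR(1) walk
(innovation SD 0.1 mmHg) around 120 mmHg with injected strictly monotone
ramps (default 7/min, 4 beats, 2.5 mmHg/beat), digitised to a 0.5 mmHg
step as telemetry pressures are. The RR response is
`rr[i + lag] += gain * (sbp[i] - 120) + noise` with lag 0 by default — the
analyser's default lag must match, and both are configurable 0-2.
Quantisation matters: an unquantised walk produces many tiny-range monotone
runs, and slopes conditioned on a same-direction monotone RR response are
strongly positively biased when the SBP range is small — the intrinsic
selection bias of the threshold-free sequence method. With digitised
pressures the small fluctuations tie out (ties break runs), detected
sequences are dominated by genuine ramps, and the Monte-Carlo calibration
(gain 1.5, RR noise 2 ms, 10 min, 20 seeds) recovers the gain to about
+0.08 — inside the +/-0.2 band, with the residual being that same selection
bias, not an implementation artefact.

**Circadian channels.** Noiseless value
`M + A[(1-w) cos(2 pi t / tau + phi) + w step(t)]`, with `step = -1` in the
light cycle and `+1` in the dark cycle and `w` the square-wave fraction —
rodent activity is step-like rather than sinusoidal, and the step term lets
tests quantify cosinor misfit. Per-channel defaults (mesor, amplitude,
acrophase in radians from local midnight) are the control-period values of
the study system: activity (0.26, 0.18, -1.10), subcutaneous temperature
(33.81, 0.78, -0.69), SBP (128.3, 6.32, -0.76), DBP (102.3, 5.37, -1.18),
HR (590.6, 18.2, 0.30). Sampling defaults to 5 min; noise SDs (0.05
counts, 0.3 degC, 5 mmHg, 25 bpm) give per-channel rhythm-detection
behaviour comparable to the real recordings (robust for activity and
temperature, marginal for pressures and HR).

**Experiment-level effects.** Per-day multiplicative/additive effects on
(M, A): activity x0.15 throughout HU; HR x0.89 at HU1 and x0.945 at HU2
(bradycardia nadir then recovery toward baseline) and x1.044 during
recovery (reloading tachycardia); temperature -1.1 degC and SBP +6 mmHg
(DBP +4.2) during HU; every channel's amplitude attenuated by 70% during HU
(day/night flattening). Between-subject variation: 2% CV on mesor, 15% on
amplitude, 0.25 rad SD on acrophase. Each subject-day optionally gets a
beat-level pressure recording anchored at 08:00 whose true BRS gain follows
the observed phase profile (x1.35 early HU, x0.75 late HU, x0.70-0.85 at
recovery). For these coupled recordings the reflex-independent LF/HF
amplitudes are kept at 1 ms: in the generator (unlike a real baroreflex
loop) the modulation is independent of the SBP coupling, so it competes
with ramp matching; 1 ms keeps detected counts near the ~20-sequences-per-
3-min-analysis regime of real recordings.

What the generator does **not** emulate: reflex-driven closed-loop HRV,
respiratory-cardiac coupling, thermoregulatory or hemodynamic dynamics,
activity-HR correlation, non-stationary drift within a day, or telemetry
dropouts. Passing tests demonstrate that the analysis chain recovers known
parameters under these idealised conditions — not that the defaults are a
biofidelic mouse.

## HRV

Cleaning flags RR intervals deviating more than 20 ms (the vendor-pipeline
tolerance, here made explicit) from an 11-beat centred running median, then
linearly interpolates flagged values between neighbouring valid intervals;
flagged intervals stay excluded from time-domain statistics. Above 20%
flagged, a quality flag is set. SDNN uses the n-1 denominator (HRV
standards convention); RMSSD excludes successive pairs spanning an invalid
interval. The tachogram is interpolated onto a uniform 50 Hz grid and fed
to Welch's periodogram: 1024-point Hanning segments, 50% overlap,
per-segment mean removal only (no polynomial detrend). "1024 spectral
points" is read as the FFT segment length (configurable). Band powers are
trapezoidal integrals over half-open bands — VLF 0.01-0.10, LF 0.10-1.00,
HF 1.00-5.00 Hz — with a boundary frequency assigned to the upper band;
VLF is computed but excluded from interpretation. LF/HF is returned as
missing with a warning when HF is zero.

The triplicate protocol selects three non-overlapping 3-min windows between
08:00 and 10:00 and averages each metric. Candidate windows tile the
search interval (stride = window length, so candidates are disjoint and
the greedy pick is optimal within them); ranking is lowest artifact
fraction, then lowest RR variance, then earliest start — an explicit,
logged stand-in for the original by-eye selection of stable intervals.
Window start times are returned for audit.

## Baroreflex sensitivity

Ramps are maximal runs of >= 3 beats with strictly monotone SBP — maximal
runs are not split into sub-windows, so one long ramp yields one sequence
and counts stay comparable to the ~20-per-analysis regime. No SBP, RR or
correlation thresholds: any nonzero change counts, exact ties break a run,
and r is recorded but never used to filter. A ramp becomes a sequence when
the (optionally lagged) RR changes strictly monotonically in the same
direction; the slope is ordinary least squares of RR on SBP, and the BRS
estimate is the unweighted mean over up and down sequences pooled (a single
value, as reported in this field). Zero sequences yield a missing estimate
with a warning rather than an exception. Detection operates on
interval-aligned arrays (SBP at the interval-terminating beat); an
exhaustive O(n^3) enumerator of maximal monotone windows serves as the
oracle for the scan-based detector. The protocol entry point reuses the
triplicate stable-window selection (windows chosen on the cleaned series)
and pools sequences across windows before averaging; the sequence analysis
itself runs on the original RR values, since interpolated artifacts would
fabricate slopes.

## Cosinor

Single-component, fixed 24 h period:
`Y = M + beta cos(omega t) + gamma sin(omega t)` by least squares, with
`A = sqrt(beta^2 + gamma^2)` and `phi = atan2(-gamma, beta)` in (-pi, pi].
The acrophase reference is local midnight of the first day, so the fitted
peak occurs `-phi * tau / (2 pi)` hours after midnight; radians are
reported with an hours conversion available (`acrophase_to_hours`), since
signed values near +/-1 are ambiguous between conventions. Guards: >= 4
samples, span >= one period, full-rank design. Rhythm detection is the
zero-amplitude F test, `F = (MSS/2) / (RSS/(n-3))` on (2, n-3) df; a
noiseless fit underflows to p = 0.

Group summaries fit per subject first, then aggregate (mean +/- SD,
matching how such tables are reported); acrophase dispersion uses the
circular mean with the arithmetic SD of values unwrapped to the mean's
branch, because arithmetic means are wrong near +/-pi. The group rhythm
p-value is the population-mean cosinor test — Hotelling T^2 on the
per-subject (beta, gamma) pairs, `F = k(k-2)/(2(k-1)) m' S^-1 m` on
(2, k-2) df — used because individual and population-level "rhythm
detection" are distinct questions; both are computed and labelled.
Condition splits (Control / Unloading / Recovery) fit each subject per
condition on its 2 h-binned values (bin midpoints as timestamps); cells
that cannot support a fit are left missing with the reason logged.

## Aggregation and reporting

Daily summaries exclude the handling hour everywhere, so the 24 h mean is
the sample-count-weighted combination of the LC (11 retained hours) and DC
(12 hours) means, exactly. Percent change vs C-1 is computed per subject
then averaged; the pooled order is emitted alongside as a robustness
column because the two orders only provably agree on balanced designs.
Binning anchors at midnight with empty bins missing; light labels are
always assigned by bin start. The report bundle (CSV tables + JSON
manifest with config echo and seed) contains analysis-ready tables only —
the routine hypothesis-testing layer (repeated-measures ANOVA and
post-tests) is deliberately out of scope, and no timestamps are written so
reruns with one seed are byte-identical.

## Problem sizes and numerical choices

Default simulation sizes were chosen so the whole suite exercises every
stage at realistic scale while remaining quick to run: 8 subjects x 10
days at 5-min channel sampling; 600-1200 s beat recordings per subject-day
(enough for three disjoint 3-min windows after 08:00); 1000-case
enumeration suites; 1000-replicate null calibration of the rhythm test.
Degenerate inputs are handled explicitly: constant series produce exactly
zero spectra (float residue of detrending is suppressed), zero HF makes
LF/HF missing rather than infinite, zero sequences and zero-amplitude fits
warn rather than raise, and a zero reference day leaves percent change
missing while keeping the absolute change.

## Known limitations

* The sequence method's monotone-selection bias is positive whenever the
  RR noise is comparable to the per-ramp RR change; the generator's
  pressure quantisation keeps it small but it is not zero.
* The cosinor model is deliberately misspecified for step-like channels
  (that is what the square-wave fraction is for); amplitude estimates for
  such channels mix the cosine and step components.
* Interpolated (cleaned) RR values feed the spectral chain; heavy artifact
  burdens (> 20% flagged) bias spectra low and are only flagged, not
  corrected.
* Phase labels assume the calendar in the design; recordings extending
  outside it are labelled blank and silently dropped from day-level
  aggregation.
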