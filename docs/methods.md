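# Methods

This note documents the models behind `telecg`: what the generator
emulates, how each analysis stage is defined, the tunable parameters
with their defaults and units, the numerical choices, and what the
passing test suite does and does not establish about real telemetry
data.

## Study protocol emulated

Each simulated animal runs the standard telemetric protocol: a 96-h
baseline recording duty-cycled to 1 min of signal per 5-min block
(first minute of each block; which minute the acquisition system stores
is not observable, so the first is a convention), two continuous acute
sessions one simulated week apart (vehicle and isoproterenol in
randomised order; two same-agent i.p. injections 30 min apart; 30-min
lead-in plus 300-min observation), and a 96-h recording under chronic
oral metoprolol. Lights are on 07:00–19:00; activity is logged as one
value (A.U.) per 5-min epoch. The default cohort is Balb/c n=6,
C57Bl/6 n=6, Black Swiss n=6, FVB n=5 (23 animals).

The acute cross-over wording in such protocols is ambiguous about
whether the two injections within a session use the same agent; the
generator emulates same-agent pairs, which keeps the vehicle session a
clean negative control. This is an assumption, flagged here.

## Latent heart-rate model

Instantaneous HR (bpm) is an exact sum of four components, then
clipped:

* **Circadian**: raised-cosine transitions (1-h ramps starting at the
  07:00 and 19:00 light switches) between the day plateau
  `hr_day_mean` and the night plateau `hr_night_mean`, plus a mid-day
  quiescence trough (12:00–15:00, 1-h cosine edges) during which the
  component relaxes to `hr_min − trough_margin` (margin 15 bpm).
* **Activity**: Hill-type gain `g_max · a/(a + a50)` on the concurrent
  5-min activity value; defaults `g_max = 60` bpm, `a50 = 15` A.U.
  Monotone non-decreasing in activity by construction.
* **Drug**: metoprolol subtracts `metoprolol_delta_day` (50 bpm) in
  the clock-day window and `metoprolol_delta_night` (70 bpm) at night.
  The deltas are *defined* as reductions of the day-/night-window mean
  HR, so the term follows the hard light switch rather than the
  circadian ramp; the night value is a package choice (the day value is
  the canonical ~50 bpm effect; night effects are reported as more
  pronounced but not numerically). Isoproterenol adds a
  double-exponential surge normalised to peak at `iso_peak_delta`
  (250 bpm, identical across backgrounds, reflecting the
  strain-independent chronotropic response) with rise/decay taus of
  3/45 min; the analytic peak time is τ_r τ_d/(τ_d−τ_r) · ln(τ_d/τ_r)
  ≈ 8.7 min, and the residual at +300 min is ≈ 0.4 bpm, below the
  1-bpm decline contract.
* **Noise**: stationary Ornstein–Uhlenbeck process, sd 8 bpm,
  correlation time 30 s (exact discretisation), giving realistic
  minute-scale dispersion.

The stored trace is `clip(sum, floor(t), 850)` with
`floor(t) = hr_min + min(drug, 0)` and a global range of
[150, 850] bpm; the unclipped sum is always recoverable from the
stored components. Because the trough dips ~2 sd below the floor while
activity is forced to zero, deep-rest minutes saturate at exactly
`hr_min`: the strain's minimal naturally occurring epoch HR is a
calibrated parameter (Balb/c 317, C57Bl/6 327, BS 392, FVB 372 bpm),
which is what makes minimum-HR recovery a sharp test. A consequence of
the additive drug term is that the metoprolol-phase minimum is
`hr_min − delta_day`, i.e. the model does not reproduce the smaller
printed reductions of the *minimal* HR under blockade; the deltas are
calibrated to the mean effect, a known limitation.

Day/night plateau values per strain are set once to plausible levels
consistent with the published ordering (FVB/BS higher than C57Bl/6 and
Balb/c, night above day); they are not recovery targets.

## Activity model

Zero-inflated gamma per 5-min epoch: zero with probability 0.55 (day) /
0.15 (night), otherwise gamma (shape 1.2) scaled so the *overall* epoch
mean equals `activity_day_mean` / `activity_night_mean`; the mid-day
quiescence window forces additional zeros so rest and HR are
consistent. Values are capped at 300 A.U., matching the top activity
class.

## Beat placement and arrhythmia injection

Sinus beats come from time-rescaling of the latent rate: beat k+1
occurs when ∫ HR/60 dt advances by 1 since beat k. This is exact for
time-varying rates and yields quasi-periodic RR whose variability is
inherited from the OU noise (a thinned Poisson stream would have
exponential RR and would trip any prematurity criterion on almost half
of all sinus beats).

Events per class arrive as homogeneous Poisson processes over the
analysis window at per-5-h rates taken from the group-level class means
of the four backgrounds (e.g. Balb/c 158.2 PVB, 46.7 coupled, 14.0 VT,
4.7 VF; BS 40.2/11.2/0.5/0). Coupled events split 0.7/0.3 into
couplets/triplets (the pooled class does not constrain the split); VT
run lengths are 4 + geometric(p=0.35); VF durations are log-normal
(median 3 s, σ=0.5). Onsets are uniform; overlapping draws are
re-drawn until every event is separated by ≥ 1 s of sinus rhythm, so
each scheduled entry maps to exactly one maximal run downstream.
Vehicle sessions inject isolated PVBs at 0.3 events/5 h, emulating the
occasional ectopy seen under sham injection.

An ectopic run replaces sinus beats with premature beats at a coupling
interval of 0.65 of the local RR (0.55 within runs) while the sinus
clock keeps running, so the beat after a single ectopic falls on the
undisturbed grid: RR_pre + RR_post = 2 RR, the textbook fully
compensatory pause. Ectopic beats carry no P wave. VF intervals remove
all beats.

## Waveform synthesis

Beats are rendered as sums of Gaussians at murine scale (P: 0.10 mV at
−28 ms; QRS: Q/R/S of −0.15/1.0/−0.25 mV, R sd 2.5 ms; T: 0.18 mV at
+28 ms). Ectopic beats widen the QRS ×2.5, raise R ×1.4, invert the T
and omit the P — each printed criterion is objectively present in the
waveform. VF is three drifting 8–16 Hz sinusoids with frequency random
walk and no repeating template. Disturbances: slow baseline wander
(two sinusoids, 0.05 mV), white noise, and optional broadband artifact
bursts (1.2 mV) standing in for movement artefact. Record-level SNR is
defined as 20·log10(R amplitude / white-noise sd).

## Detection and morphology

The QRS detector band-passes at 20–120 Hz (murine QRS, ~10 ms wide,
concentrates its energy well above the bands used for human ECG),
squares, integrates over 12 ms and thresholds at 0.25 of each 10-s
window's 99th energy percentile, with a 50-ms refractory (well below
the 60000/850 ≈ 71 ms RR at ceiling HR) and an absolute energy floor so
flat or noise-only windows yield nothing. R peaks are refined to the
raw-signal apex, which keeps template windows phase-locked.

Template libraries use −20/+40 ms windows (T wave included, so T
alteration degrades the score), 3-ms box smoothing, and normalized
cross-correlation maximised over ±3 ms alignments; beats join the first
cluster matching at ≥ 0.95, clusters below 5 members are dropped
(provisional single template if none survive), the most populous
cluster is hinted "normal". Matching labels a beat atypical when its
best match is an abnormal-hinted template; scores below 0.80 are
unmatched. At 10 dB SNR individual-beat correlations fall below the
merge threshold and the library fragments; detection metrics are
unaffected, but morphology labels are only meaningful on cleaner
records — the 2-of-3 rule tolerates this by design.

P-wave search inspects −50…−25 ms before the QRS (truncated to start
≥ 50 ms after the previous beat, so a premature beat riding the
preceding T wave is judged on what remains and flagged low-confidence),
smooths over 3 ms and requires a deflection above
max(0.04 mV, 3·σ_noise/√m). Artifact flagging marks 0.5-s windows whose
RMS exceeds 3× the record median (with an absolute floor) or that
saturate, merging overlaps.

## Classification

RR criteria and thresholds: premature ⇔ RR_pre < 0.8·ref, pause ⇔
RR_post > 1.15·ref, ref = median of the last k=5 intervals flanked by
normal-labelled beats (sequential semantics; warm-up beats are
low-confidence and never PVB). The 0.8/1.15/k=5 values separate the
generator's fully compensatory ectopy from sinus arrhythmia with wide
margin (sinus RR cv is ~1–2%) and are exposed in the configuration.
Stream boundaries leave the affected criteria false. VF detection
slides 1-s windows (0.5-s hop): a window is VF-flagged when it contains
no template-matched beat (score ≥ 0.80) and its RMS exceeds 3× the
noise floor; flagged windows merge, episodes are padded by half a hop
(a flagged window only certifies its interior) and must last ≥ 1 s. VF
overrides beat-level labels inside its extent.

Counting uses half-open windows [start, end) on event onsets, skips
onsets inside artifact intervals, pools couplets and triplets as
"coupled beats", and counts each run once regardless of length. The
per-PVB column counts isolated PVBs only (runs are their own classes);
whether published tables count run members as PVBs is not stated — this
convention matches a table whose classes are mutually exclusive.

## HR analytics

Epoch HR is 60000 / mean RR (ms) over each recorded minute; epochs are
invalid with < 20 beats or > 20% artifact overlap. Day/night
assignment uses the epoch start clock time. Naturally occurring
min/max HR are extremes over valid 1-min epoch means — the duty cycle
makes epoch means the observable unit, so "minimal HR" is defined at
epoch, not instantaneous, resolution. Activity classes are 0 = exactly
0 A.U. and seven half-open bins (0,5], (5,10], …, (25,30], (30,300]
(the conventional printed bins overlap at their edges; a dedicated zero
class plus half-open upper bounds is the only partition consistent with
"0 = 0"). ΔHR is baseline minus metoprolol phase mean, per day and
night. Acute responses use 10-s sliding epochs (5-s hop) over the 5 h
after injection — 1-min epochs blur the surge peak — with artifact
exclusion and a flag when coverage falls below 90%. Note that epochs
containing ectopic runs have shortened mean RR, so the acute maximum
can exceed the sinus ceiling when arrhythmias are frequent; peak
recovery against generator truth is therefore validated on
arrhythmia-free sessions.

## Statistics

Normality screening is Shapiro–Wilk at α=0.05 (n < 3 or constant
samples force the nonparametric branch; the screening test itself is a
package choice since the convention only says samples "were tested").
SNK orders group means and tests each pair with the studentized range
at the enclosing span (Tukey–Kramer standard error for unequal n),
stepping down with the blocking rule: pairs inside a non-significant
span are declared non-significant without testing, with their reported
p floored at the blocking span's p. Tail probabilities come from
`scipy.stats.studentized_range` (numerical integration, no table
lookup), and with two groups SNK reduces exactly to the pooled t-test
(q = √2·|t|), which the tests assert to 1e-12. Two-way ANOVA uses
closed-form cell-mean sums of squares for the complete crossed layout
(missing cells rejected; cross-checked against `statsmodels.anova_lm`
on balanced data), with Sidak-adjusted pairwise t-contrasts on the
residual MSE; the family m is the number of comparisons actually
reported (day vs night within strain by default). Kruskal–Wallis is
tie-corrected (mid-ranks); Dunn's z uses the tie-corrected rank
variance and Sidak family-wise adjustment — the Dunn correction variant
is unspecified in the convention, so the family-wise Sidak used on the
parametric side is applied for consistency, and is configurable in
principle through the module API.

## Problem sizes and fidelity levels

`simulate_study` offers three fidelities: `epoch` (latent HR + epoch
means; circadian/pharmacological analyses at cohort scale), `beat`
(ground-truth beat streams; RR-based classification at scale) and
`waveform` (full 1-kHz synthesis; bounded durations). The recovery
experiments run at the scales a desk check affords: 200 replicate
6+6-animal cohorts for the burden ratio, 500 animals for PVB-rate
recovery (both beat-level, 5-h windows at a representative 600-bpm
sinus rate — the criteria are RR-ratio based, so recovered counts are
invariant to the base rate), and 20-animal 96-h epoch cohorts for ΔHR
and minimum-HR recovery. Waveform-route checks (detector operating
point, dual-route equality) use 2-min records, long enough for ~1100
beats and dozens of events at inflated rates.

## What passing tests do and do not show

The generator realises every printed classification rule exactly and
its parameters are recovered by the pipeline, so the tests establish
internal consistency, correct implementation of the grammar and
statistics, and detector adequacy down to 10 dB SNR on this waveform
family. They do not establish performance on real telemetry: real
mouse ECG has morphology drift, electrode artefacts correlated with
behaviour, non-compensatory ectopy, supraventricular events (out of
scope) and VF that is not band-limited sinusoids. Criteria thresholds
(0.8/1.15) were chosen against this generator's fully compensatory
ectopy; on real data they would need re-tuning against expert
adjudication. Template fragmentation at low SNR means morphology-based
criteria degrade gracefully rather than failing loudly — sections where
matching fails are the ones a study would send to manual review.

## Known limitations

* Single lead, no body-temperature channel, no hemodynamics or echo.
* The metoprolol effect is additive in HR; reductions of extremes are
  therefore as large as reductions of means, unlike published minima.
* VF morphology is an operational surrogate (no distinguishable QRS),
  not a biophysical model of fibrillatory conduction.
* Event rates are homogeneous within the 5-h window; real
  isoproterenol arrhythmia burden is likely front-loaded with the
  surge.
* The day-time injection clock (09:00) and the session spacing are
  fixed conventions; they matter only through the circadian baseline
  under the acute sessions.
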