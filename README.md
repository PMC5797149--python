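# telecg

Murine telemetric ECG analysis: synthetic telemetry studies, QRS
detection, ventricular-arrhythmia classification and circadian
heart-rate analytics.

## The problem

Implanted telemetry transponders record single-lead ECG (Einthoven-II
configuration, 1 kHz) and a cage-activity parameter from freely moving
mice over days. Studies of arrhythmia susceptibility across genetic
backgrounds (Balb/c, C57Bl/6, Black Swiss, FVB) follow a standard
protocol: a 96-hour baseline recording stored as 1 min of waveform per
5-min block, acute cross-over sessions with isoproterenol (β-agonist)
vs. saline recorded continuously for 300 min after injection, and a
second 96-hour recording under chronic metoprolol (β1-blocker). Because
such datasets are rarely deposited, `telecg` pairs every analysis stage
with a ground-truth-annotated generator, so the whole pipeline is
testable end to end and calibration parameters programmed into the
generator must be recovered by the analysis.

## Models and rules at the core

**Beat classification (Lambeth-Conventions style).** A beat is a
premature ventricular beat (PVB) when it is premature
(RR<sub>pre</sub> < 0.8 · RR<sub>ref</sub>, with RR<sub>ref</sub> the
median of the last 5 normal-flanked intervals) and at least **2 of 3**
criteria hold: (i) atypical QRS/T morphology, (ii) atrioventricular
dissociation (no P wave), (iii) compensatory post-extrasystolic pause
(RR<sub>post</sub> > 1.15 · RR<sub>ref</sub>). Maximal runs of k
consecutive PVBs map to events: k=1 → PVB, k=2 → couplet, k=3 →
triplet, k≥4 → ventricular tachycardia (VT); ventricular fibrillation
(VF) is an interval with no distinguishable QRS complexes. Each run
counts as one event.

**Detection.** A Pan–Tompkins-style energy detector re-parameterised
for mouse ECG (20–120 Hz band, 12-ms integration, 50-ms refractory,
adaptive per-10-s threshold), followed by animal-specific template
libraries built by greedy normalized-cross-correlation clustering on an
asymmetric −20/+40 ms window so T-wave alteration degrades the match.

**Heart-rate model.** Instantaneous HR is a sum of a circadian term
(day/night plateaus with 1-h raised-cosine ramps and a mid-day
quiescence trough pinned at the strain floor), a saturating activity
gain, pharmacological terms (metoprolol day/night reductions; a
double-exponential isoproterenol surge A(e^{−t/τ_d} − e^{−t/τ_r}) that
decays below 1 bpm within 300 min) and Ornstein–Uhlenbeck noise.
Arrhythmia events arrive as per-class Poisson processes at
strain-specific rates per 5-h window.

**Statistics.** Shapiro–Wilk routing; one-way ANOVA with
Student–Newman–Keuls step-down (studentized-range tails by numerical
integration); two-way ANOVA with Sidak-adjusted pairwise comparisons;
Kruskal–Wallis with Dunn's rank post-hoc; descriptives as median with
5–95 percentile / IQR or mean ± SEM.

## Worked example

A small two-strain study (3 Balb/c, 3 Black Swiss, 24-h long-term
phases at beat fidelity):

```sh
cat > cfg.yaml <<'YAML'
seed: 1
strains: ["Balb/c", "BS"]
n_per_strain: {"Balb/c": 3, "BS": 3}
longterm_duration_h: 24.0
YAML
telecg run --config cfg.yaml --out out --fidelity beat
```

prints

```
Heart rate under baseline conditions and under beta-adrenergic blockade
(bpm, mean +/- SEM per group)

baseline minimal HR      BS: 392 +/- 0   Balb/c: 317 +/- 0
baseline maximal HR      BS: 687 +/- 1   Balb/c: 624 +/- 0
metoprolol minimal HR    BS: 342 +/- 0   Balb/c: 267 +/- 0
metoprolol maximal HR    BS: 623 +/- 2   Balb/c: 565 +/- 4
delta HR day             BS: 52 +/- 2   Balb/c: 51 +/- 0
delta HR night           BS: 71 +/- 1   Balb/c: 70 +/- 1

Occurrence of ventricular arrhythmias under beta-adrenergic stimulation
(events per animal over 5 h, mean +/- SEM; (affected/n))

strain                       PVB         Coupled beats                    VT                    VF                 Total
BS              39.7 +/- 0.9 (3/3)      11.7 +/- 3.3 (3/3)       0.0 +/- 0.0 (0/3)       0.0 +/- 0.0 (0/3)      51.3 +/- 3.3 (3/3)
Balb/c         146.3 +/- 8.2 (3/3)      47.3 +/- 1.3 (3/3)      14.3 +/- 2.8 (3/3)       4.7 +/- 1.7 (3/3)     212.7 +/- 10.9(3/3)

Total events: Kruskal-Wallis H=3.86 p=0.0495
```

Reading it: the per-group minimal HRs sit on the strain-calibrated
circadian troughs (Balb/c 317 bpm); chronic metoprolol lowers day-time
HR by ~50 bpm and night-time HR by ~70 bpm in both backgrounds; and
under β-adrenergic stimulation the Balb/c group carries a ~4-fold
higher total arrhythmic burden than Black Swiss, with VT and VF
confined to Balb/c — the susceptibility gradient the generator encodes
and the pipeline recovers.

CLI verbs `simulate`, `detect`, `classify`, `analyze`, `stats`,
`report` run the stages standalone on their file formats (CSV records
with JSON sidecars, JSON-lines events, YAML configs); `simulate` is
byte-reproducible for a fixed config and seed (see the run manifest).

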