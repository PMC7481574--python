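# Methods

This note records the models, conventions and design choices behind
`qeegnfb`, in the spirit of a statistical-software methods appendix: what
is computed, under which assumptions, which knobs exist, and what the
synthetic data can and cannot tell you about real recordings.

## Spectral analysis and the iAPF

Recordings are assumed to be 10–20 montage EEG in μV at 500 Hz. Spectra
are averages of Hann-windowed periodograms over **non-overlapping
2000 ms epochs**, giving a 0.5 Hz grid; bin powers are scaled so their
sum approximates the signal variance (Parseval within windowing loss,
tested at 5 %). Epochs with any sample exceeding **100 μV** absolute are
excluded before averaging — a deliberately minimal stand-in for clinical
artifact handling, adequate here because the generator produces no
ocular or movement artifacts by default.

The individual alpha peak frequency is found on the **EC − EO difference
spectrum**: posterior alpha is suppressed when the eyes open, so
subtracting the EO from the EC spectrum isolates the alpha hump and, in
expectation, cancels the common 1/f background. The iAPF is the
frequency of the maximum between **6 and 13 Hz inclusive**; ties resolve
to the lowest frequency, and a peak sitting on either search edge (or a
non-positive maximum) raises an `edge_flag` rather than being discarded
— downstream consumers decide. With 0.5 Hz bins the quantization error
is at most 0.25 Hz; recovery on synthetic cohorts shows a mean absolute
error near 0.12 Hz at the default signal-to-noise level.

Band edges are half-open conventions `[lo, hi)`: theta 4–8, alpha 8–13,
SMR 12–15, beta 13–21, spindle search 13–30, EMG 55–100 Hz. The
theta/beta ratio divides theta by beta power (undefined and flagged when
beta power is zero). The individualized theta sub-band (4–6 vs 5–8 Hz)
follows the location of a local theta peak; a peakless (pure 1/f)
spectrum keeps the full 4–8 Hz band with a no-peak flag.

**Deviation flags** compare band powers against a normative table
(`band, site, mean, sd`). The package ships a *synthetic* normative
reference generated at a fixed seed from neurotypical-profile subjects;
it stands in for proprietary clinical norms and users should substitute
their own table for real data. The default z threshold is **z ≥ 1.5**
(configurable; clinical "excess" thresholds are not published).
Low-voltage EEG is flagged when the EC broadband (1–30 Hz) RMS amplitude
falls below 4 μV. Beta spindles are detected in the time domain:
13–30 Hz band-passed signal, Hilbert envelope above 2× its median for at
least 0.25 s, at a rate of ≥ 2 bursts/min on a fronto-central channel;
the centre frequency is the peak of zero-padded per-burst periodograms
(accurate to ~0.5 Hz on injected bursts). Mu excess is an EO 11–13 Hz
peak at C3/C4 at least as large as the occipital alpha peak.

## ERP scoring

Target-locked epochs span **[−300, 700) ms** (500 samples at 500 Hz; the
half-open convention keeps sample counts integral). Filtering is a
101-tap zero-phase FIR low-pass at 25 Hz applied forward-backward —
zero phase because peak *latency* is a scored outcome and phase-shifting
filters would bias it. Baseline is the mean of the 300 ms pre-stimulus
window. Peaks are signed extrema within scoring windows of **250–500 ms
(P300, maximum)** and **150–300 ms (N200, minimum)**; the windows are
common oddball conventions (the originating clinical software does not
publish its intervals) and are configurable. Ties resolve to the
earliest latency. All target trials enter the average; no behavioural
gating is applied.

## Protocol engine

The rule cascade is evaluated in a fixed, logged order (the clinical
description lists criteria without stating precedence; the order below
is this package's declared convention, slowing first and the SMR/SCP
family as the default):

1. **excess slowing → TBR** at the midline site of maximal theta,
   inhibiting the individualized theta sub-band; the 20–25 Hz beta
   reward is withheld when beta is elevated or spindling;
2. **frontal alpha excess → frontal-alpha down-training** at midline;
3. **beta spindles → beta down-training** at the detected site,
   inhibiting centre ± 2 Hz (the clinics name a centre, not a width);
4. **low-voltage EEG → SMR/SCP** with eyes-closed alpha up-training at
   Pz as an adjunct;
5. otherwise **SMR** (at C3/Cz/C4, 12–15 Hz reward), replaced by **SCP**
   when mu excess overlaps the SMR band.

Deviations that lose the precedence race are appended as adjunct
protocols. Session parameters default to mid-range values: 25 min
sessions in 5-min blocks, 30 % reinforcement target, 0.35 s SMR
time-above-threshold, and a 55–100 Hz EMG inhibit at 7.5 μV on every
protocol. "Sleep problems" enter as PSQI global > 5 (the clinical
sources link SMR/SCP to sleep problems without a cutoff). Ad-hoc
clinician overrides ("protocol adjusted to the patient's needs") are not
formalizable and are out of scope.

## Outcome classification

The ADHD rating scale is represented dually: 18 items rated 0–3; a
scale **score** is the count of items rated ≥ 2 (so inclusion cutoffs of
≥ 6 symptoms and baseline totals near 12 are coherent), while
**remission** is judged on the endpoint mean of the raw item ratings,
**≤ 1.00 inclusive**. Percentage reductions are computed per scale on
the count scores and a subject responds if *either* scale passes (a
literal "ATT or HYP" reading). Endpoints are outtake scores or LOCF;
intake-only records are flagged `baseline-only`. Drop-out is ≤ 20
sessions without R25 (the boundary is configurable); drop-outs are
excluded from analysis frames. Whether the original clinics computed
reductions on raw sums or symptom counts is not documented; the count
convention is this package's choice and is isolated in
`outcomes.scale_score`.

## Predictor statistics

The repeated-measures ANOVA uses the classical univariate split-plot
formulation: responses are transformed by an orthonormal within-subject
contrast basis; each within-stratum effect is an averaged (trace) F over
the transformed variates; between-subject effects are tested on subject
means. **Greenhouse-Geisser ε** is estimated from the within-error SSCP
(the pooled within-cells covariance, as commercial packages do) and
multiplies both degrees of freedom whenever the within factor has more
than two levels — Greenhouse-Geisser rather than Huynh-Feldt because
fractional dfs of the former match the reported analysis style. One
within factor is supported; multiple between factors are combined into
their cartesian cells for the split-plot strata, and the fully factorial
between-subject screens live in `glm_screen`, which fits Type-III
least squares with effect coding (the default of the commercial software
this mirrors) and reports every term involving the remission factor.

The discriminant surface for a single predictor reports **Wilks' Λ =
SS_within/SS_total** with Bartlett's χ² approximation
−(n − 1 − (p + g)/2)·ln Λ on p(g−1) = 1 df, alongside the Mann-Whitney
(tie-aware) estimator of the ROC area. Mann-Whitney U counts pairs where
the first group exceeds the second (ties ½) with a tie-corrected normal
approximation, two-sided, without continuity correction. Partial
correlations are residual correlations with df = n − 2 − k; Spearman is
Pearson on average ranks (ranks are taken before residualizing).
Sleep-related breathing (SBD) scores are log-transformed (natural log,
+1 offset for zeros) before correlating with response. The mediation
screen applies the three classical criteria — predictor→mediator,
mediator→outcome, and disappearance of an initially significant
predictor→outcome path under control — at a configurable α (default
0.05, two-sided throughout). No multiple-testing adjustment is applied
by default, matching the unadjusted reporting style it reproduces;
Benjamini-Hochberg is available as an option for users.

## Synthetic data: what it emulates, and what it does not

Resting EEG is 1/f^γ noise (γ ∈ [0.8, 1.2]) at ~8 μV RMS plus a
**narrowband alpha oscillator** — Gaussian-filtered noise (σ = 0.6 Hz)
centred on the subject's true peak — with a posterior-dominant
topography and EC amplitudes (4–7 μV RMS) well above EO (0.8–2 μV).
Filtered noise rather than a sinusoid is deliberate: a pure tone would
make peak detection trivially easy and hide quantization behaviour.
Optional components: fronto-central narrowband theta (gain ≈ 3 for
"slowing" subjects, within 1.0–1.3 otherwise), frontal alpha that does
not suppress with eye opening, 0.5 s spindle bursts at a configurable
beta frequency and rate, and a global 0.35 low-voltage scaling.

Oddball recordings inject, at each target onset, a biphasic template —
negative Gaussian (σ = 25 ms) at the true N200 latency, positive
Gaussian (σ = 45 ms) at the true P300 latency — with site gains Fz 0.7 /
Cz 0.9 / Pz 1.0 for P300 (canonical parietal maximum) and the reverse
gradient for N200, on 1 μV RMS 1/f background by default. Stimulus
sequences are quasi-random with the constraint that two targets never
occur back to back (positions drawn uniformly from the non-adjacent
arrangements), onsets 1 s apart.

The clinical generator draws symptom-count trajectories linearly
between baseline and endpoint (only three timepoints are ever observed
in the emulated design, so a richer trajectory model would be
unidentifiable) with per-assessment noise, and couples EEG/ERP truth to
outcome: remitting boys centred at 8.7 Hz iAPF vs 9.7 for
non-remitters; non-remitting women's P300 latency shifted by d = 0.85;
baseline hyperactivity shifted by d = 0.56 (non-remitters higher); SBD
tied to the hyperactivity latent through a normal copula with the
Pearson parameter 2·sin(πρ/6) for a target Spearman ρ. Two small fixed
calibrations — a 0.89 shrinkage of the latent hyperactivity shift and
the Beta(1.2, 3) non-remitter improvement distribution — offset the
distortions of rounding/clipping onto the bounded 0–9 scale so that the
*configured* effects are what the generated data actually realize; both
were measured once at large n during generator design and are not
runtime knobs.

What passing tests on this generator demonstrate: correctness of the
analysis arithmetic, recoverability of injected parameters at realistic
signal-to-noise, and determinism of the full pipeline. What they do not
demonstrate: robustness to ocular/muscle artifacts (a contamination
hook exists but is off by default), electrode bridging or drift,
non-stationary alpha, medication effects, multi-site hardware
differences, or any claim about real patients.

## Numerical conventions and degenerate inputs

Seeds propagate through `numpy.random.default_rng`; identical seed and
configuration give bit-identical arrays and byte-identical CSVs. EDF
output is plain 16-bit EDF with 1-s records, a fixed ±500 μV physical
range (LSB ≈ 0.015 μV) and a fixed header date, so files are also
reproducible. Degenerate inputs fail loudly or are flagged rather than
silently patched: zero baseline scores make reductions undefined (never
responders), zero beta power makes TBR NaN with a warning, zero-variance
variables make correlations NaN, all-identical within-subject columns
give F = 0 / p = 1 via a roundoff guard, and between-subject cells with
fewer than two subjects are dropped from the design with a warning.

## Problem sizes used in validation

The validation suite uses 200 subjects for alpha-peak recovery, 100
subjects × 40 trials for P300-latency recovery, cohorts of n = 2000 for
effect-size realization, 1000 replications for the type-I error of the
group screen, and a 24-subject fixture for the end-to-end
reproducibility run — sizes chosen to make stochastic checks tight
(standard errors a few times smaller than the asserted tolerances)
while keeping the whole suite fast enough to run routinely.

## Known limitations

* One within-subject factor per RM-ANOVA call; no doubly-multivariate
  designs, and the covariate enters the within stratum only through its
  interaction with the contrasts.
* The normative reference is synthetic; deviation-flag prevalences on
  real data depend entirely on the user-supplied norms.
* LOCF is the only missing-data policy, mirroring the emulated design.
* Contingent negative variation is out of scope (a 1 s inter-stimulus
  interval cannot support it), as are source localization, connectivity,
  real-time feedback delivery and device I/O.
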