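# Methods

This note documents the models, conventions and numerical choices behind
`avattn`. The package analyzes single-unit spiking recorded (or simulated)
during an audiovisual go/no-go rule-switching task in auditory cortex: mice
lick to rewarded tone clouds or gratings, and the modality that predicts
reward — the *rule* — alternates between an auditory block (A-rule) and a
visual block (V-rule). All analyses contrast the same physical stimuli
across the two rules.

## Behavioral sensitivity and trial filters

Go/no-go performance is summarized by d′ = Z(H) − Z(F) with the log-linear
correction: 0.5 is added to each cell of the 2×2 outcome table, so
H = (hits+0.5)/(hits+misses+1) and F = (FA+0.5)/(FA+CR+1). The correction
bounds |d′| by 2·Z(1 − 0.5/(n+1)) and keeps the transform finite for
perfect sessions. Sessions enter physiological analysis only when d′ > 1.5
in both rules and the false-alarm rate to *conflict* stimuli — the
audiovisual compounds whose reward valence flips between rules (A_UV_R in
the A-rule, A_RV_U in the V-rule) — stays below 0.5. d′ for inclusion is
computed from each rule's bimodal-block trials by default (configurable);
unimodal-block d′ can be computed identically but is reported separately.

Physiology trial filters: trials with any lick earlier than 300 ms after
stimulus onset or within 500 ms before onset are dropped everywhere;
decision-stimulus analyses keep correct trials only (hits and correct
rejects), except the error-trial path, which keeps false alarms and correct
rejects (misses are too rare to analyze and are always excluded there).

## Unit classification

Units split into narrow-spiking (NS, trough-to-peak < 0.6 ms; putative
fast-spiking inhibitory) and broad-spiking (BS, ≥ 0.6 ms; the boundary value
is BS by convention). Laminar depth is the fractional position of a unit's
peak channel within the cortical span estimated from the probe profile: the
white-matter border is the deepest channel with a reliable tone-evoked
multi-unit response *that is not an isolated outlier* (it must have another
responsive channel within two channels above it — a single spurious
white-matter channel would otherwise stretch the span and corrupt every
depth fraction), and the pial border is the shallowest channel whose peak
LFP amplitude rises above the probe-wise minimum by 10% of the amplitude
range. Depth groups split at fractions 0.365 and 0.505, approximating the
supragranular/granular/infragranular division of mouse auditory cortex;
both boundaries are configuration values, since the atlas-derived numbers
are not uniquely determined. When two channels tie for the largest
waveform, the shallower one is used.

Recording stability is screened automatically: spike counts in 2-minute
bins, bins below 20% of the unit's median bin rate flagged, and units
flagged for more than 10% of the recording excluded from receptive-field
analyses. This replaces a manual raster inspection; the 80% drop threshold
approximates the magnitude of dropoffs that inspection flags.

## Firing-rate contrasts

Evoked rate is the spike count in the half-open window [0, 0.3) s from
onset divided by the window length; the pre-stimulus window is [−0.3, 0).
Bimodal trials are pooled by auditory identity across visual pairings
(A_R* = {A_RV_R, A_RV_U}, A_U* likewise). Because the correct-trial filter
yields different stimulus compositions under the two rules (A-rule hits are
A_R* trials, V-rule hits are V_R pairings), the per-rule mean used for fold
changes averages the two auditory-class means rather than pooling trials,
so composition does not masquerade as a rule effect. The per-unit fold
change FC = mean A-rule FR / mean V-rule FR is defined only when both means
are nonzero and both conditions have ≥ 10 trials; the per-unit significance
test is an unpaired t-test at p < 0.01 (a paired variant is available — the
source descriptions disagree between the two, and both are exposed).

Group-level inference uses the paired Wilcoxon signed-rank across units
within each of the six depth × waveform groups, Benjamini–Hochberg
corrected at q = 0.05 across the six tests. Baseline normalization divides
each rule's evoked rates by that rule's mean pre-stimulus rate: a rule
effect that is a shared multiplicative gain on baseline and evoked activity
cancels exactly in normalized units, whereas an additive evoked-only effect
survives — this is the discriminating logic for the "gain" interpretation
of attentional suppression.

The error-trial analysis compares pre-stimulus rates before false alarms vs
correct rejects within a rule, per unit, for sessions with at least 10 of
each; units are pre-split by the sign of their evoked fold change
(suppressed FC < 1 vs enhanced), and group inference is a one-sample
Wilcoxon on the per-unit differences.

## STRF estimation

Receptive fields are estimated from responses to the random double sweep
(RDS): two independent trajectories of log2 frequency, band-limited to
20 Hz and spanning exactly 4–64 kHz, presented during inter-trial
intervals. The time–frequency representation bins each sweep's
instantaneous frequency on a 5 ms × 0.2 octave grid (each sweep deposits
unit energy per time bin; optional energy-conserving Gaussian smoothing of
σ = 0.1 octave across frequency). The first 200 ms of every epoch's
response is dropped, and total RDS time is equated across rules by
truncating the longer rule's later epochs.

The spike-triggered average uses a window of 200 ms before to 50 ms after
each spike (the acausal lags estimate chance structure). It is converted to
firing-rate deviation units as

    STRF(l, f) = r̄ · (STA(l, f) − m(f)) / sqrt(m'(f) · m̄),

where m(f) is the mean stimulus energy per band, m'(f) = max(m(f), 0.1·m̄),
and r̄ the mean rate. The square-root occupancy weighting is deliberate:
full per-band division (STA−m)/m amplifies estimation noise in rarely
visited edge bands, while plain centering biases peak estimates toward the
occupancy maximum; the square root is the compromise that recovers ground
truth best in simulation. The transform is per-band affine and shared by
observed and shuffled estimates, so reliability, per-bin significance,
best-frequency and projection analyses are invariant to the convention.

Tuning classification: per-epoch STRFs are split-half correlated — the
observed statistic is the mean over random half-splits (odd counts drop one
epoch per split) of the Pearson r between the two half-averages — and
compared with a null distribution built by circularly shuffling each
epoch's spike train (one uniform rotation per epoch in [0.5 s, duration −
0.5 s], preserving spike count and the circular ISI multiset) and repeating
the *identical* mean-over-splits procedure. The p-value is the fraction of
null reliabilities exceeding the observed mean; exchangeability of the
observed and null statistics makes p uniform for untuned units, which the
calibration tests verify. Units are tuned at p < 0.05 in either rule; at
least 4 epochs with spikes and 50 total spikes are required.

Per-bin significance masks compare each STRF bin two-sided against ≥ 100
shuffle-null STRFs at α = 0.01 (empirical quantiles). Best frequency is the
band maximizing |STRF| summed over significant bins at lags −100 to 0 ms;
ties resolve to the lower frequency.

Projection information: stimulus windows are projected onto the STRF
(full −200/+50 ms window), standardized by the mean and SD of the
*all-windows* distribution (every time-bin offset), and histogrammed on 40
shared bins over ±5 SD with outliers clipped into the edge bins; P(x) gets
a Laplace pseudocount. MI = Σ P(x|spike) log2(P(x|spike)/P(x)) in
bits/spike. Each spike's projection uses the STRF re-estimated without that
spike's own window (an exact leave-one-out identity via the stored per-band
affine coefficients); without this, self-overlap inflates P(x|spike) even
for stimulus-independent spike trains.

## PSTH-template decoding

Single-trial responses are spike counts over [0, 0.3) s in 30 ms bins (10
bins). Each test trial is assigned to the nearest class-template PSTH in
Euclidean space; only the test trial's own class template excludes it,
other classes use full-class means, and distance ties (detected on squared
distances with a 10⁻⁹ relative tolerance, robust to float summation order)
break uniformly at random under an explicit seed. Inclusion requires ≥ 10
trials and a class-mean rate ≥ 1 Hz for every class. Confusion-matrix MI is
the plug-in estimate; encoding efficiency divides MI by the pooled mean
spikes per trial. Stimulus decoding within each rule averages two runs
(A_RV_R vs A_UV_R, and A_RV_U vs A_UV_U); rule decoding classifies A-rule
vs V-rule responses to one fixed compound.

## Statistics

Wilcoxon signed-rank: zero differences dropped, tie-corrected normal
approximation with continuity correction by default, exact enumeration for
n ≤ 25 without ties; one-sided variants support tests against a fixed value
(fold change vs 1, accuracy vs chance). BH-FDR is the standard step-up
procedure (q = 0.05 for the six group tests, q = 0.01 for per-unit
responsiveness). Kruskal–Wallis uses the tie-corrected H with a chi-square
reference. Degenerate inputs resolve by convention: all-zero difference
sets give p = 1; identical groups give H = 0.

## Synthetic sessions

The generator emulates the statistical structure the analyses assume, as a
pure function of (config, seed):

* **Task**: four blocks (unimodal cue block then AV block per rule, both
  rule orders), 30 unimodal and 100 AV trials by default; outcomes drawn
  from configured hit/FA rates (defaults 0.90/0.15); lick latencies
  lognormal with median 611 ms (σ = 0.35 — only the median is pinned);
  occasional impulsive early/pre-stimulus licks at 2% rates exercise the
  trial filters.
* **Stimuli**: RDS synthesized as Fourier-domain band-limited Gaussian
  noise (support strictly ≤ 20 Hz, DC excluded) affinely rescaled so the
  realized min/max map exactly onto log2 4–64 kHz — both printed
  constraints hold by construction, for every seed. RDS epochs fill
  inter-trial intervals, always ending ≥ 0.35 s before the next onset, so
  the pre-stimulus window is silent. Tone clouds are 39 pips (50 ms, 25 ms
  hop) log-uniform within ±0.5 octave of 8 or 17 kHz, frozen per seed.
* **Units**: linear–nonlinear Poisson. rate(t) = rectify(baseline[rule] +
  gain[rule]·(K ∗ S)(t)) with half-wave rectification (configurable
  exponential), per-bin Poisson thinning at 1 ms. Ground-truth kernels are
  monophasic spectrotemporal Gabors (normalized Frobenius norm), present in
  a configurable fraction of units. Decision-stimulus responses add a
  per-unit random 10-bin temporal profile per stimulus element; auditory
  amplitudes are widely dispersed (lognormal σ = 1.0 around a 16 Hz mean)
  because the two tone clouds sit an octave apart and frequency-tuned units
  respond very unequally — this puts single-unit decoding in the
  accuracy range where the efficiency analysis is informative. Baselines
  are lognormal around 6 Hz.
* **Attention**: a multiplicative A-rule factor per depth group (default
  0.85 for deep, 1.0 elsewhere) scales baseline and evoked rates — factor
  1.0 means no effect, and control sessions with all factors 1.0 produce no
  group effects beyond the nominal FDR level. An optional pre-stimulus rate
  elevation (e.g. +0.35 Hz) on A-rule false-alarm trials of suppressed deep
  units reproduces the error-anticipation pattern.
* **Probe**: 64 channels, cortex spanning channels 10–50 by default; LFP
  near the noise floor above the pia, large within cortex, attenuated in
  white matter; multi-unit responsiveness true within cortex with small
  mislabel probabilities.

What the generator does *not* emulate: spike-sorting artifacts, drift other
than block-wise rate changes, correlated noise across units, adaptation,
pupil/locomotion covariates, and any non-multiplicative form of attentional
modulation. Passing tests therefore demonstrate that the analysis code
recovers the effects it targets under the stated generative assumptions,
not that those assumptions exhaust real data.

One consequence worth making explicit: with a pure LNP and a shared
multiplicative factor f on baseline and evoked rates, the decoder's
efficiency fold change is (1/f)·(MI_A/MI_V), and MI itself degrades
slightly with rate, so the "preserved accuracy, higher bits/spike" pattern
emerges only where decoding is strong enough for MI to be near saturation.
The recorded data's larger efficiency gain suggests suppression falls
disproportionately on non-stimulus-driven spikes, which a uniform gain
model cannot produce.

## Problem sizes used by the test suite

Chosen to give stable statistics at desk scale: decoder calibration 200–400
units × 20 trials/class; STRF recovery 25 seeds × 600 s of RDS (120 × 5 s
epochs, matching the ITI presentation of short individually rescaled
segments) at ~5.5 Hz; reliability calibration 200 units × 24 epochs with
20-split means and 100 null shuffles; attention and error-trial recovery
pool 3–4 synthetic sessions (≈ 45–65 units per group of interest), as the
original analyses pool units across sessions. The full suite runs in a few
minutes on one CPU.

## Known limitations

* Reverse correlation is uncorrected for stimulus autocorrelation, so
  estimated kernels are temporally smeared and recovery correlations
  plateau around 0.6–0.9 even with abundant data.
* The occupancy of the min/max-rescaled sweep is Gaussian-concentrated in
  the middle octaves; kernels within ~1.2 octaves of the band center are
  recovered reliably, edge kernels are not (mirrored in the generator's
  best-frequency placement).
* Plug-in MI estimates are biased upward at small trial counts; all
  cross-rule comparisons are therefore made between conditions of equal
  trial counts and equated stimulus time.
* The HDF5 session container stores one session per file; no multi-session
  container or lazy loading.
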