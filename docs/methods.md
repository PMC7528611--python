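# Methods

`circuitclock` analyses extracellular multielectrode recordings from brain
slices containing the principal output targets of the suprachiasmatic nucleus
(SCN) — the subparaventricular zone (SPZ), paraventricular hypothalamus (PVN)
and ventral thalamus. Two experiment types are supported: **acute** sessions,
in which electrical pulses to the SCN region (and interleaved optogenetic
flashes) probe synaptic input while GABA and glutamate receptor antagonists
dissect its neurochemistry, and **long-term** (> 26 h) sessions, in which
spontaneous firing reveals circadian modulation. Because such recordings are
not publicly deposited as raw spike trains, the package ships a synthetic
session generator with exact ground truth; every analysis stage is validated
by parameter recovery on simulated data.

## Data model

A session is a set of spike-sorted units (spike times in seconds from
recording start, with the electrode's projected position in µm dorsal of the
reference point at the SCN ventral boundary / midline intersection), a
stimulus log, and pharmacological epoch annotations. Intervals are half-open
`[start, end)`; times are real-valued seconds, stored at microsecond
resolution so the TSV/JSON serialization round-trips bit-exactly. Projected
Zeitgeber time is `(prep_time_zt + t/3600) mod 24` with ZT0 = lights-on.
Region assignment maps the dorsal offset through configurable boundaries,
defaulting to SPZ `[0, 350)`, PVN `[350, 700)`, ventral thalamus `[700, ∞)`
µm; these defaults are a working convention matched to the 100-µm electrode
grid, not measured anatomy, and should be overridden per slice.

## Synthetic sessions

Each unit is an inhomogeneous Poisson process sampled by thinning against an
exact rate upper bound (no time discretisation; fixed seeds give
bit-identical sessions). The instantaneous rate is

```
rate(t) = max(0, (envelope(t) + Σ active excitations) · Π active inhibition multipliers)
```

**Circadian envelope.** `envelope(t) = m + (A/2)·w(t)` with the unimodal
waveform `w(t) = 2·((1 + cos(2π(t − t_peak)/T))/2)^k − 1`. The exponent `k`
is solved in closed form so that the envelope spends exactly the requested
`peak_width` per cycle above half its maximum: the half-maximum condition is
a threshold `c = 1/2 − m/A` on `w`, giving
`k = log2((1+c)/2) / log2((1+cos(π·width/T))/2)`; for a zero trough
(`A = 2m`) this reduces to `k = 1/(1 − log2(1 + cos(π·width/T)))`, with
`k = 1` the plain cosine (width `T/2`). Exponents below 0.2 are rejected to
keep the waveform unimodal. An amplitude at or below `2m/3` leaves the whole
cycle above half-maximum and is rejected for rhythmic specs. Non-rhythmic
cells are flat or, optionally, drift linearly (`trend_hz_per_h`).

**Evoked components.** Each synaptic input is a component with a transmitter
(GABA, glutamate, or a direct ChR2 photocurrent), an effect (inhibition as a
rate multiplier in `[0,1)`, excitation as additive Hz), latency, duration and
the stimulus modality that drives it. A component is active within
`[stim + latency, stim + latency + duration)` unless its receptors are
blocked in the epoch containing the stimulus: GABA components under BIC and
BIC+iGlu-X, glutamate components under iGlu-X and BIC+iGlu-X, ChR2
photocurrents never; TTX silences all spiking. Excitation adds to the
envelope and inhibition multiplies the **total** drive (shunting), so a cell
receiving both — a "mixed" cell — is net-inhibited while GABAergic
transmission is intact and net-excited once bicuculline removes it, matching
the observed phenomenology. Latency jitter (Gaussian, SD 1 ms, truncated at
zero) is drawn once per stimulus and shared across a cell's components,
modelling variability in presynaptic recruitment; independent per-component
jitter would spuriously unmask disinhibited cells at window edges.

**Default effect sizes** (calibration choices of the simulator, not measured
values): inhibition to 10% of drive for 150 ms at 5 ms latency; excitation
+20 Hz for 50 ms at 4 ms latency; GABA-mediated activations (polysynaptic
disinhibition) get a 16 ms extra latency; direct ChR2 activation +40 Hz for
15 ms at 2 ms. A disinhibited cell pairs glutamatergic excitation with a
coincident shunting component scaled so the net baseline response is zero;
the masking is exact at the cell's mean rate and approximate at other
circadian phases (a known limitation).

**Population defaults** emulate reported prevalences in these circuits:
response classes at 36 : 18 : 12 : 47 : 13 : 540 (GABA-inhibited : mixed :
GABA-activated : glutamate-activated : glutamate-disinhibited :
non-responsive) out of 666; rhythmic fractions 45/54 for inhibited, 25/35
for activated, 566/651 for non-responsive cells; peak widths ~N(7, 1.5²) h;
peak-trough amplitude defaults to 1× the mean rate, so cells keep firing at
their trough (a zero trough would render early-day acute recordings of
late-peaking cells silent, an artefact rather than emulated biology);
inhibited cells' peak phases are von Mises-clustered around ZT18 (night /
early projected day), all others uniform. The SCN-removed mode strips all
evoked components, lowers the rhythmic fraction to 184/282, broadens widths
(~N(9.5, 2²) h) and references phases to time-since-start of recording
(local oscillators re-set by slicing rather than entrained to the prior
light cycle). Protocols: acute — 1 h baseline, 30 min BIC, 30 min
BIC+iGlu-X, electrical pulses every 2 s with optogenetic flashes at +1 s;
long-term — 26.5 h, pulses every 60 s with flashes at +30 s, no drugs.

What the simulator does **not** model: spike sorting and its errors,
electrode drift, bursting/refractoriness (pure Poisson), use-dependent
synaptic depression, neuropeptide signalling, and damped or non-stationary
oscillations. Passing recovery tests therefore demonstrates correctness of
the estimators under Poisson statistics at realistic rates, not robustness
to every artefact of real recordings.

## Evoked-response analysis

Responses are called from the peri-stimulus time histogram (PSTH) of spike
counts pooled over ≥ 750 stimulus repeats (trials truncated by epoch edges
are dropped; 25-ms bins covering 100 ms post-stimulus; 0.5 s pre-stimulus
baseline). The per-bin expected count is `μ = baseline_rate · bin_width ·
n_trials` and the confidence limits are Poisson quantiles at `μ` (pooled
counts over independent trials are exactly Poisson, so no empirical
percentile estimation is needed; an empirical mode could be added for
sensitivity analysis). A bin above the upper limit marks excitation, below
the lower limit inhibition; the earliest crossing decides, since the
earliest synaptic event is physiologically primary.

With a two-sided level applied per bin, the *cell-level* false-call rate is
roughly the number of tested bins times larger (≈ 3–4% for 4 bins at
α = 0.01, slightly inflated further by baseline-estimation noise).
`detect_response` therefore defaults to a Sidak correction across the tested
bins so that α is the cell-level two-sided level; `correction=None` restores
literal per-bin limits, and `null_call_rate_expectation` computes the exact
Monte-Carlo family expectation for either mode so the calibration is always
auditable rather than hidden. In drug epochs the analysis uses the trailing
25 min (equilibrated drug concentration); long-term sessions use the whole
drug-free epoch, since every one of the > 1500 repeats adds power.

**Amplitude** is the signed change in trial-averaged rate, relative to the
pre-stimulus baseline, at the 25-ms window (sliding in 1-ms steps over the
100-ms response window) maximising the absolute change. **Latency** is the
start of the first 15-ms window (sliding in 1-ms steps) whose summed count
leaves the two-sided 95% Poisson limits of the baseline expectation. The
window method floors estimates: onsets earlier than ~15 ms can yield a first
significant window at 0 ms, so estimates carry a negative bias bounded by
one window; across a latency grid the estimator's central tendency is
monotone in the true latency and within one window of it. Single-cell scans
retain an irreducible ~5–10% chance of an early spurious crossing at the
95% level; population medians are the reliable summary.

## Pharmacological taxonomy

A pure decision tree over the per-epoch direction calls for electrical
stimulation: baseline inhibition abolished by BIC → GABA-inhibited; baseline
inhibition replaced by excitation under BIC that vanishes under BIC+iGlu-X →
mixed; baseline excitation abolished by BIC → GABA-activated (taken as
polysynaptic disinhibition); baseline excitation persisting under BIC but
abolished by BIC+iGlu-X → glutamate-activated; no baseline response but
BIC-revealed excitation abolished by BIC+iGlu-X → glutamate-disinhibited;
none anywhere → non-responsive. Any other pattern — or a pattern whose
deciding epochs were not recorded — is `unclassified` rather than forced to
the nearest class; in particular a cell with only a baseline "none" call is
unclassified, because it cannot be distinguished from a disinhibited cell
without the BIC epoch. The binary detector call stands in for any
quantitative "abolished vs reduced" threshold. Optogenetic phenotyping is
independent of the electrical tree: light-evoked inhibition removed by BIC
marks synaptic innervation by the photostimulated SCN population
(VIP- or GAD-innervated by genotype); light-evoked excitation persisting
under BIC+iGlu-X marks direct ChR2 expression; cre-negative tissue forces
"none" and warns on any apparent response. An iGlu-X-first control epoch, if
present, is reported in the response table but not consulted by the tree.

## Circadian rhythmicity

A unit over ≥ 26 h is rhythmic when the period-constrained sinusoid
`r(t) = m + A·cos(2π(t − φ)/T)`, `T ∈ [20, 28] h`, `A ≥ 0`, beats the linear
model `r(t) = a + b·t`. Both are least-squares fits on the 60-s rate series
re-binned to 15 min (configurable): at 60-s resolution the residuals are
Poisson-dominated and the comparison is noisy. The sinusoid is fit by
profiling the residual sum of squares over a period grid (0.25-h steps, the
model being linear in mean/cos/sin at fixed `T`) with bounded scalar
refinement, which is globally convergent despite the objective's
multimodality in `(T, φ)`.

"Better fit" is decided by an information criterion (4 vs 2 parameters).
The default is **BIC**: at `n ≈ 104` fit bins the AICc penalty (~4.3 points)
is close to the ~3 effective degrees of freedom the period-profiled sinusoid
family absorbs under the null, leaving a ~9% false-positive rate on flat
cells — an uncomfortable boundary; BIC's `2·ln n ≈ 9.3` penalty brings the
false-positive rate to ~1% while sensitivity at the validated effect sizes
(peak-trough = mean rate, ≈ 10 Hz mean) remains 1.0. AICc and an
extra-sum-of-squares F-test are available via `criterion=`. Both criteria
are reported in the output for auditing. The comparison is
scale-equivariant: rescaling all rates changes neither the verdict nor the
fitted period or phase.

For rhythmic units, peak metrics come from the 60-s series smoothed with a
2-h boxcar: the peak is the global maximum within one fitted period —
capped at 24 h, so a fitted period longer than the recording cannot pull in
boxcar edge bins — centred mid-recording (so a recording slightly longer
than one cycle contributes exactly one peak), the width is the total time
above 50% of the peak within
the surrounding 24-h window, the amplitude is peak minus minimum and the
24-h mean is taken over that window. Peak time is reported both as hours
since recording start and projected ZT. A constant or all-zero series
yields NaN metrics with a `degenerate` flag. Note that the *fitted* period
and phase serve detection; the reported peak metrics are measured on the
smoothed series, which remains accurate for the peaky (non-sinusoidal)
waveforms typical of these cells even when the cosine's fitted period is
biased by seeing barely more than one cycle.

Numerical details: the 2-h boxcar spans an even number (120) of 60-s bins,
so the kernel is made symmetric by half-weighting its two outermost bins —
an even flat kernel would shift the series half a bin and distort ramps;
edges use the available truncated window. Ties in the peak search resolve to
the earliest bin (numpy argmax).

## Phase statistics

Peak times live on the 24-h circle. The package provides 6-h binning
(origin at ZT0 by default, configurable), the χ² uniformity test
`Σ(obs − n/k)²/(n/k)` with `k − 1` degrees of freedom, the Rayleigh mean
resultant vector `R` and circular mean, a supplementary Rayleigh p-value
(Zar's corrected `e^(−Z)` expansion), circular histograms smoothed with a
wrapped Gaussian kernel (SD 15 min, 1-min grid; mass equals the sample
size to better than 1e-6 relative), and tidy per-slice proportion tables
(per slice and class, the fraction of cells peaking in each 6-h bin) for
downstream mixed-model analysis, which is deliberately out of scope.

## Validation experiments and problem sizes

`circuitclock.validation` re-runs the recovery experiments end to end;
`scripts/acceptance.py` writes their headline numbers. Sizes chosen for the
package's standard validation run: 500 flat cells × 750 trials for detector
calibration (against the Monte-Carlo family expectation for both limit
modes); 300 cells across all six classes for taxonomy recovery; 15 cells per
true latency over {2, 5, 10, 20, 40} ms; 200 sinusoidal (24-h period,
peak-trough = mean, 10 Hz) + 100 flat + 100 linearly drifting 26.5-h cells
for rhythm detection; noise-free envelopes at widths {4, 7, 12, 18} h for
the width oracle; and two full pipeline runs (acute and long-term) for
byte-level determinism.

## Known limitations

Poisson spiking only; the acute pipeline assumes the baseline is
approximately stationary within each 25-min analysis window (strongly
rhythmic cells violate this mildly, and a cell sitting near its circadian
trough has genuinely little signal to detect); the disinhibited-cell mask is
exact only at the cell's mean rate; period estimates from a single observed
cycle of a non-sinusoidal waveform are biased even when peak metrics are
accurate; no ultradian decomposition, Lomb–Scargle or damped-oscillator
alternatives; mixed-effects inference on the exported tables is left to
external statistical software.
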