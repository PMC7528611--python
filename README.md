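# circuitclock

Analysis of stimulus-evoked and circadian firing in multielectrode recordings
of the suprachiasmatic nucleus (SCN) output circuit — the subparaventricular
zone, paraventricular hypothalamus and ventral thalamus — together with a
ground-truth-bearing simulator that makes the whole pipeline testable end to
end. It is written for electrophysiologists and circadian biologists who have
spike-sorted extracellular recordings (per-unit spike times, a stimulus log,
drug-epoch annotations) and want the standard analyses of this preparation as
a reproducible, scriptable library rather than a chain of GUI tools.

## What it computes

**Evoked responses.** For each unit and pharmacological epoch, the
peri-stimulus time histogram over ≥ 750 stimulus repeats is tested against
Poisson confidence limits of the pre-stimulus count,
`μ = r_baseline · Δ · n_trials`, bins of Δ = 25 ms over 100 ms post-stimulus
(99% limits, family-corrected by default). Response amplitude is the peak
change in a 25-ms sliding window relative to baseline; onset latency is the
first 15-ms sliding window whose count leaves the 95% baseline limits.

**Pharmacological taxonomy.** How a response changes under GABA_A blockade
(bicuculline, BIC) and combined GABA/ionotropic-glutamate blockade
(BIC+iGlu-X) resolves five classes — GABA-inhibited, mixed, GABA-activated,
glutamate-activated, glutamate-disinhibited — plus non-responsive and an
explicit `unclassified`. Optogenetic calls (light-evoked inhibition abolished
by BIC; excitation persisting under full blockade = direct ChR2 expression)
phenotype each unit independently.

**Circadian rhythmicity.** A unit recorded ≥ 26 h is rhythmic when
`r(t) = m + A·cos(2π(t − φ)/T)` with `T ∈ [20, 28] h` beats `r(t) = a + b·t`
by information criterion (BIC by default; AICc and an F-test available). Peak
time (hours since start and projected Zeitgeber time), peak width (time above
50% of peak per 24 h) and peak-trough amplitude are measured on the 60-s rate
series smoothed with a 2-h boxcar.

**Phase statistics.** Peak-time distributions on the 24-h circle: 6-h bin
counts with a χ² uniformity test, the Rayleigh vector `R = |n⁻¹ Σ e^{iθ_j}|`
with circular mean, wrapped-Gaussian smoothed circular histograms (SD
15 min), and per-slice proportion tables for downstream mixed-model software.

**Simulation.** Inhomogeneous Poisson spike trains (exact thinning) whose
rate combines a circadian envelope `m + (A/2)·w(t)`,
`w = 2·((1+cos(2π(t−t_peak)/T))/2)^k − 1` with pharmacologically gated
evoked components, under the acute (1 h baseline → 30 min BIC → 30 min
BIC+iGlu-X, 2-s stimulus interval) or long-term (> 26 h, 60-s interval)
protocol. Every session carries a ground-truth table, and identical seeds
reproduce sessions byte for byte.

## Worked example

```python
from circuitclock import (CellSpec, AcuteProtocol, simulate_session,
                          response_table, classification_table)
from circuitclock.synthetic import electrical_components

classes = ["GABA_inhibited", "Mixed", "GABA_activated", "Glu_activated",
           "Glu_disinhibited", "non_responsive"]
specs = [CellSpec(f"u{i}", true_class=c, baseline_rate=5.0,
                  components=electrical_components(c))
         for i, c in enumerate(classes)]
session, truth = simulate_session(specs, AcuteProtocol(opto=False), seed=11)
responses = response_table(session)
print(responses.pivot(index="unit_id", columns="epoch", values="direction"))
print(classification_table(responses)[["unit_id", "cell_class"]])
```

prints (`examples/03_classify_pharmacology.py`):

```
epoch        BIC BIC_iGluX   baseline
unit_id
u0          none      none  inhibited
u1       excited      none  inhibited
u2          none      none    excited
u3       excited      none    excited
u4       excited      none       none
u5          none      none       none
unit_id       cell_class
     u0   GABA_inhibited
     u1            Mixed
     u2   GABA_activated
     u3    Glu_activated
     u4 Glu_disinhibited
     u5   non_responsive
```

Row `u1` is the mixed-input signature: stimulation inhibits the cell at
baseline, blocking GABA_A receptors unmasks a glutamatergic excitation, and
adding glutamate antagonists abolishes it. Each unit's call matches its
ground-truth class. The other scripts in `examples/` walk through
simulation, single-cell response detection, rhythm detection (a cell
generated with a 7-h peak is measured at 7.08 h width, 9.91 Hz amplitude),
phase statistics (45 night-clustered cells: χ² = 23.0, p < 0.0001, R = 0.60,
circular mean ZT 18.5) and the full pipeline with its recovery report.

There is also a thin CLI:

```sh
circuitclock run-all --protocol acute --n-cells 30 --seed 1 --out out/
circuitclock analyze-rhythms --session out/session --out rhythms.tsv
```

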