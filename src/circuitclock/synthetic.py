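"""Synthetic multielectrode sessions with known ground truth.

The simulator emulates the two experiment types the analysis pipeline targets:

* **acute** sessions — 1 h drug-free baseline, then 30 min GABA-A
  block (BIC), then 30 min combined GABA/ionotropic-glutamate block
  (BIC+iGlu-X); electrical pulses to the SCN region every 2 s with optional
  optogenetic flashes interleaved 1 s later.
* **long-term** sessions — > 26 h of continuous recording, electrical pulses
  every 60 s with optogenetic flashes at +30 s, and circadian modulation of
  each unit's firing rate.

Each unit is an inhomogeneous Poisson process whose instantaneous rate is a
circadian envelope combined with pharmacologically gated stimulus-evoked
components:

``rate(t) = max(0, (envelope(t) + Σ active excitations) · Π active inhibition
multipliers)``

Excitatory synaptic drive is added on top of the envelope and inhibition acts
as a shunting factor on the total drive, so a cell receiving both (a "mixed"
cell) is net-inhibited while GABAergic transmission is intact and net-excited
once it is blocked.  A component is *active* within
``[stim + latency, stim + latency + duration)`` of a matching stimulus, unless
its transmitter is blocked in the pharmacological epoch covering the stimulus:
GABA components are silenced by BIC and BIC+iGlu-X, glutamate components by
iGlu-X and BIC+iGlu-X, and direct ChR2 photocurrents by neither.  TTX silences
all spiking.

The circadian envelope is ``m + (A/2)·w(t)`` with the unimodal waveform
``w(t) = 2·((1 + cos(2π(t − t_peak)/T))/2)^k − 1``; the exponent ``k``
controls the fraction of the cycle spent above half-maximum (``k = 1`` is a
plain cosine with a 50% duty cycle, larger ``k`` gives the brief high-firing
epochs typical of SCN-driven cells).

Spikes are drawn by thinning a homogeneous Poisson process at an exact upper
bound of the rate, so no time discretisation enters; identical seeds give
bit-identical sessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import (
    DEFAULT_REGION_BOUNDARIES,
    PharmEpoch,
    RecordingSession,
    SpikeTrain,
    StimulusEvent,
    assign_region,
    projected_zt,
    quantize_times,
)

__all__ = [
    "ResponseComponent",
    "CellSpec",
    "AcuteProtocol",
    "LongtermProtocol",
    "EffectSizes",
    "PopulationConfig",
    "solve_waveform_exponent",
    "waveform",
    "circadian_envelope",
    "rate_function",
    "simulate_session",
    "sample_population",
]

TRANSMITTERS = ("GABA", "glutamate", "ChR2")
#: epochs in which a transmitter's ionotropic receptors are antagonised
_BLOCKED_IN = {
    "GABA": frozenset({"BIC", "BIC_iGluX"}),
    "glutamate": frozenset({"iGluX", "BIC_iGluX"}),
    "ChR2": frozenset(),  # direct photocurrent, immune to synaptic blockers
}

MIN_WAVEFORM_EXPONENT = 0.2


@dataclass(frozen=True)
class ResponseComponent:
    """One synaptic (or direct optogenetic) input evoked by a stimulus."""

    transmitter: str  # GABA | glutamate | ChR2
    effect: str  # inhibition | excitation
    latency: float  # s after the stimulus
    duration: float  # s
    magnitude: float  # inhibition: rate multiplier in [0,1); excitation: +Hz
    evoked_by: str = "electrical"  # electrical | opto_wide | opto_local

    def __post_init__(self) -> None:
        if self.transmitter not in TRANSMITTERS:
            raise ValueError(f"unknown transmitter {self.transmitter!r}")
        if self.effect not in ("inhibition", "excitation"):
            raise ValueError(f"unknown effect {self.effect!r}")
        if self.latency < 0 or self.duration <= 0:
            raise ValueError("latency must be >= 0 and duration > 0")
        if self.effect == "inhibition" and not 0 <= self.magnitude < 1:
            raise ValueError("inhibition multiplier must lie in [0, 1)")
        if self.effect == "excitation" and self.magnitude <= 0:
            raise ValueError("excitation magnitude must be > 0 Hz")

    def blocked_in(self, epoch_label: str | None) -> bool:
        return epoch_label in _BLOCKED_IN[self.transmitter]


@dataclass
class CellSpec:
    """Ground-truth description of one simulated unit."""

    unit_id: str
    true_class: str = "non_responsive"
    opto_identity: str = "none"  # VIP_innervated | GAD_innervated | ChR2_direct | none
    baseline_rate: float = 5.0  # Hz; the envelope's mean level for rhythmic cells
    rhythmic: bool = False
    period: float = 24.0  # h
    peak_time: float = 0.0  # h, see peak_ref
    peak_ref: str = "zt"  # zt | rec (hours since recording start)
    peak_width: float = 12.0  # h above half-maximum per cycle
    peak_trough_amplitude: float = 0.0  # Hz
    trend_hz_per_h: float = 0.0  # linear drift of a non-rhythmic cell's rate
    components: tuple[ResponseComponent, ...] = ()
    dv_offset: float = 200.0  # µm
    ml_offset: float = 0.0  # µm
    slice_id: str = "slice0"
    genotype: str = "VIP_ChR2"
    latency_jitter_sd: float = 0.001  # s, per-stimulus Gaussian jitter

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.rhythmic:
            if not 20 <= self.period <= 28:
                raise ValueError("period must lie in [20, 28] h")
            if not 0 < self.peak_width < self.period:
                raise ValueError("peak_width must lie in (0, period)")
            if self.baseline_rate - self.peak_trough_amplitude / 2 < -1e-12:
                # envelope would need clipping over a substantial fraction of
                # the cycle; keep the trough at or above zero instead
                raise ValueError("peak_trough_amplitude may not exceed 2x mean rate")
            self.waveform_exponent  # validates width vs amplitude geometry

    @property
    def waveform_exponent(self) -> float:
        return solve_waveform_exponent(
            self.peak_width, self.period, self.baseline_rate,
            self.peak_trough_amplitude,
        )

    def peak_time_rec_hours(self, prep_time_zt: float) -> float:
        if self.peak_ref == "rec":
            return self.peak_time
        return (self.peak_time - prep_time_zt) % 24.0

    def max_rate(self, duration_s: float = 0.0) -> float:
        env_max = self.baseline_rate + (
            self.peak_trough_amplitude / 2 if self.rhythmic else 0.0
        )
        env_max += max(0.0, self.trend_hz_per_h * duration_s / 3600.0)
        exc = sum(c.magnitude for c in self.components if c.effect == "excitation")
        return env_max + exc


def solve_waveform_exponent(
    peak_width: float,
    period: float,
    mean: float | None = None,
    amplitude: float | None = None,
) -> float:
    """Exponent ``k`` of the circadian waveform giving a target half-max width.

    With the trough at zero (``amplitude = 2·mean``, the default when mean and
    amplitude are omitted) the envelope exceeds half its maximum exactly where
    ``w(t) > 0``, i.e. where ``cos(2πt/T) > 2^(1-1/k) - 1``, giving the closed
    form ``k = 1 / (1 - log2(1 + cos(π·width/T)))``.  For a raised trough the
    half-maximum threshold on ``w`` moves to ``c = 1/2 - mean/amplitude`` and
    ``k = log2((1+c)/2) / log2((1+cos(π·width/T))/2)`` (same formula, same
    ``c = 0`` special case).  ``k = 1`` recovers the plain cosine
    (width = T/2 at zero trough); widths needing ``k < 0.2`` are rejected to
    keep the waveform unimodal.
    """
    if not 0 < peak_width < period:
        raise ValueError("peak_width must lie strictly inside (0, period)")
    c = 0.0
    if mean is not None and amplitude is not None:
        if amplitude <= 0:
            raise ValueError("amplitude must be positive for a rhythmic cell")
        c = 0.5 - mean / amplitude
        if c <= -1.0:
            raise ValueError(
                "peak-trough amplitude <= 2/3 of the mean rate: the envelope "
                "never falls below half its maximum, so the half-max width is "
                "undefined"
            )
    base = (1.0 + math.cos(math.pi * peak_width / period)) / 2.0
    k = math.log2((1.0 + c) / 2.0) / math.log2(base)
    if k < MIN_WAVEFORM_EXPONENT:
        raise ValueError(
            f"peak_width {peak_width} h of period {period} h needs exponent "
            f"{k:.3f} < {MIN_WAVEFORM_EXPONENT}; waveform would no longer be unimodal"
        )
    return k


def waveform(t_hours: np.ndarray, peak_hours: float, period: float, k: float):
    """Unimodal circadian waveform in [-1, 1], peak value 1 at ``peak_hours``."""
    base = (1.0 + np.cos(2 * np.pi * (np.asarray(t_hours) - peak_hours) / period)) / 2
    return 2.0 * base**k - 1.0


def circadian_envelope(spec: CellSpec, t_seconds, prep_time_zt: float = 0.0):
    """Noise-free instantaneous rate (Hz) ignoring evoked components."""
    t = np.asarray(t_seconds, dtype=float)
    if not spec.rhythmic:
        return np.maximum(
            0.0, spec.baseline_rate + spec.trend_hz_per_h * t / 3600.0
        )
    w = waveform(
        t / 3600.0,
        spec.peak_time_rec_hours(prep_time_zt),
        spec.period,
        spec.waveform_exponent,
    )
    return spec.baseline_rate + 0.5 * spec.peak_trough_amplitude * w


def _component_windows(
    component: ResponseComponent,
    stimuli: Sequence[StimulusEvent],
    epochs: Sequence[PharmEpoch],
    latencies: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Active [start, end) windows of one component, honouring receptor block."""
    times = np.array(
        [s.time for s in stimuli if s.modality == component.evoked_by], dtype=float
    )
    if times.size == 0:
        return np.empty(0), np.empty(0)
    labels = np.array([_epoch_label_at(epochs, t) for t in times], dtype=object)
    active = np.array(
        [not component.blocked_in(lab) and lab != "TTX" for lab in labels], dtype=bool
    )
    times = times[active]
    lat = (
        np.full(times.size, component.latency)
        if latencies is None
        else latencies[active]
    )
    starts = times + lat
    return starts, starts + component.duration


def _epoch_label_at(epochs: Sequence[PharmEpoch], t: float) -> str | None:
    for ep in epochs:
        if ep.contains(t):
            return ep.label
    return None


def _covered(t: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Boolean mask: is each (sorted) t inside any [start, end) window?"""
    if starts.size == 0:
        return np.zeros(t.size, dtype=bool)
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    delta = np.zeros(t.size + 1, dtype=np.int64)
    np.add.at(delta, np.searchsorted(t, starts, side="left"), 1)
    np.add.at(delta, np.searchsorted(t, ends, side="left"), -1)
    return np.cumsum(delta[:-1]) > 0


def rate_function(
    spec: CellSpec,
    t,
    stimuli: Sequence[StimulusEvent] = (),
    epochs: Sequence[PharmEpoch] = (),
    duration: float | None = None,
    prep_time_zt: float = 0.0,
    _component_latencies: Sequence[np.ndarray | None] | None = None,
):
    """Instantaneous firing rate (Hz) of a simulated unit at time(s) ``t``.

    Envelope plus gated evoked modulation; scalar in → scalar out.  Raises if
    any requested time lies outside ``[0, duration]``.
    """
    scalar = np.isscalar(t)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0) or (duration is not None and np.any(t > duration)):
        raise ValueError("t outside the session")
    order = np.argsort(t, kind="stable")
    ts = t[order]

    rate = circadian_envelope(spec, ts, prep_time_zt)
    mult = np.ones_like(rate)
    add = np.zeros_like(rate)
    for i, comp in enumerate(spec.components):
        lat = None if _component_latencies is None else _component_latencies[i]
        starts, ends = _component_windows(comp, stimuli, epochs, lat)
        mask = _covered(ts, starts, ends)
        if comp.effect == "inhibition":
            mult = np.where(mask, mult * comp.magnitude, mult)
        else:
            add = np.where(mask, add + comp.magnitude, add)
    rate = np.maximum(0.0, (rate + add) * mult)

    # TTX silences everything, gated or not
    ttx = [ep for ep in epochs if ep.label == "TTX"]
    if ttx:
        silenced = _covered(
            ts, np.array([ep.start for ep in ttx]), np.array([ep.end for ep in ttx])
        )
        rate = np.where(silenced, 0.0, rate)

    out = np.empty_like(rate)
    out[order] = rate
    return float(out[0]) if scalar else out


# -- protocols -----------------------------------------------------------------


@dataclass(frozen=True)
class AcuteProtocol:
    """Baseline → BIC → BIC+iGlu-X with 2-s electrical / interleaved opto."""

    baseline_min: float = 60.0
    bic_min: float = 30.0
    bic_iglux_min: float = 30.0
    isi_s: float = 2.0
    first_stim_s: float = 1.0
    opto: bool = True
    opto_offset_s: float = 1.0
    opto_modality: str = "opto_wide"
    prep_time_zt: float = 2.0

    mode = "acute"

    @property
    def duration(self) -> float:
        return 60.0 * (self.baseline_min + self.bic_min + self.bic_iglux_min)

    def epochs(self) -> list[PharmEpoch]:
        t0 = 60.0 * self.baseline_min
        t1 = t0 + 60.0 * self.bic_min
        eps = [PharmEpoch("baseline", 0.0, t0)]
        if self.bic_min > 0:
            eps.append(PharmEpoch("BIC", t0, t1))
        if self.bic_iglux_min > 0:
            eps.append(PharmEpoch("BIC_iGluX", t1, t1 + 60.0 * self.bic_iglux_min))
        return eps

    def stimuli(self) -> list[StimulusEvent]:
        return _interleaved_stimuli(self)


@dataclass(frozen=True)
class LongtermProtocol:
    """> 26 h continuous recording, 60-s electrical / opto at +30 s, no drugs."""

    duration_h: float = 26.5
    isi_s: float = 60.0
    first_stim_s: float = 30.0
    opto: bool = True
    opto_offset_s: float = 30.0
    opto_modality: str = "opto_wide"
    prep_time_zt: float = 2.0

    mode = "longterm"

    @property
    def duration(self) -> float:
        return self.duration_h * 3600.0

    def epochs(self) -> list[PharmEpoch]:
        return [PharmEpoch("baseline", 0.0, self.duration)]

    def stimuli(self) -> list[StimulusEvent]:
        return _interleaved_stimuli(self)


def _interleaved_stimuli(p) -> list[StimulusEvent]:
    elec = np.arange(p.first_stim_s, p.duration, p.isi_s)
    events = [StimulusEvent(float(t), "electrical") for t in elec]
    if p.opto:
        events += [
            StimulusEvent(float(t + p.opto_offset_s), p.opto_modality)
            for t in elec
            if t + p.opto_offset_s < p.duration
        ]
    return sorted(events, key=lambda s: (s.time, s.modality))


# -- simulation ----------------------------------------------------------------


def _thin_poisson(rate_fn, duration: float, rate_max: float, rng) -> np.ndarray:
    """Exact inhomogeneous Poisson sample on [0, duration) by thinning."""
    if rate_max <= 0:
        return np.empty(0)
    n = rng.poisson(rate_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, n))
    keep = rng.uniform(0.0, rate_max, n) < rate_fn(cand)
    return cand[keep]


def simulate_session(
    specs: Sequence[CellSpec],
    protocol: AcuteProtocol | LongtermProtocol | None = None,
    seed: int = 0,
    session_id: str | None = None,
    scn_intact: bool = True,
    region_boundaries=DEFAULT_REGION_BOUNDARIES,
) -> tuple[RecordingSession, pd.DataFrame]:
    """Draw a full session plus its ground-truth table.

    Returns ``(session, truth)`` where ``truth`` has one row per unit
    (``unit_id, true_class, opto_identity, rhythmic, period_h, peak_rec_h,
    peak_zt_h, peak_width_h, region``), bijective with ``session.trains``.
    """
    protocol = protocol or AcuteProtocol()
    stimuli = protocol.stimuli()
    epochs = protocol.epochs()
    duration = protocol.duration
    children = np.random.SeedSequence(seed).spawn(len(specs))

    trains, rows = [], []
    for spec, ss in zip(specs, children):
        rng = np.random.default_rng(ss)
        lats = _draw_component_latencies(spec, stimuli, rng)
        fn = lambda t: rate_function(  # noqa: E731
            spec, t, stimuli, epochs, duration, protocol.prep_time_zt, lats
        )
        times = quantize_times(
            _thin_poisson(fn, duration, spec.max_rate(duration), rng)
        )
        trains.append(
            SpikeTrain(
                unit_id=spec.unit_id,
                slice_id=spec.slice_id,
                spike_times=times,
                dv_offset=spec.dv_offset,
                ml_offset=spec.ml_offset,
                genotype=spec.genotype,
            )
        )
        peak_rec = spec.peak_time_rec_hours(protocol.prep_time_zt)
        rows.append(
            {
                "unit_id": spec.unit_id,
                "slice_id": spec.slice_id,
                "true_class": spec.true_class,
                "opto_identity": spec.opto_identity,
                "rhythmic": spec.rhythmic,
                "period_h": spec.period if spec.rhythmic else np.nan,
                "peak_rec_h": peak_rec % 24.0 if spec.rhythmic else np.nan,
                "peak_zt_h": (
                    projected_zt(peak_rec * 3600.0, protocol.prep_time_zt)
                    if spec.rhythmic
                    else np.nan
                ),
                "peak_width_h": spec.peak_width if spec.rhythmic else np.nan,
                "region": assign_region(spec.dv_offset, region_boundaries),
            }
        )

    session = RecordingSession(
        session_id=session_id or f"sim-{protocol.mode}-seed{seed}",
        mode=protocol.mode,
        prep_time_zt=protocol.prep_time_zt,
        scn_intact=scn_intact,
        duration=duration,
        trains=trains,
        stimuli=stimuli,
        epochs=epochs,
        region_boundaries=tuple(region_boundaries),
    )
    return session, pd.DataFrame(rows)


def _draw_component_latencies(spec, stimuli, rng):
    """Per-stimulus truncated-Gaussian latency jitter for each component.

    The jitter is drawn once per stimulus and shared by every component the
    stimulus drives (it models variability in presynaptic recruitment, which
    is common to all of a cell's inputs from that stimulus), so components
    engineered to coincide — e.g. the masking inhibition of a disinhibited
    cell — stay aligned trial by trial.
    """
    jitter = {}
    for mod in {c.evoked_by for c in spec.components}:
        n = sum(1 for s in stimuli if s.modality == mod)
        jitter[mod] = (
            rng.normal(0.0, spec.latency_jitter_sd, size=n)
            if spec.latency_jitter_sd > 0
            else np.zeros(n)
        )
    return [
        np.maximum(0.0, comp.latency + jitter[comp.evoked_by])
        for comp in spec.components
    ]


# -- population sampling -------------------------------------------------------


@dataclass(frozen=True)
class EffectSizes:
    """Evoked-response magnitudes shared by a simulated population.

    These are calibration choices of the simulator: inhibition suppresses to
    10% of ongoing drive for 150 ms, excitation adds 20 Hz for 50 ms, direct
    ChR2 activation adds 40 Hz for the 10-ms light pulse plus decay.
    """

    inhibition_multiplier: float = 0.1
    inhibition_duration: float = 0.150
    inhibition_latency: float = 0.005
    excitation_hz: float = 20.0
    excitation_duration: float = 0.050
    excitation_latency: float = 0.004
    polysynaptic_extra_latency: float = 0.016  # for GABA-mediated activations
    opto_inhibition_latency: float = 0.008
    chr2_hz: float = 40.0
    chr2_duration: float = 0.015
    chr2_latency: float = 0.002


def electrical_components(
    true_class: str, fx: EffectSizes = EffectSizes()
) -> tuple[ResponseComponent, ...]:
    """Evoked components reproducing one response class under the drug protocol."""
    gaba_inh = ResponseComponent(
        "GABA", "inhibition", fx.inhibition_latency, fx.inhibition_duration,
        fx.inhibition_multiplier,
    )
    glu_exc = ResponseComponent(
        "glutamate", "excitation", fx.excitation_latency, fx.excitation_duration,
        fx.excitation_hz,
    )
    if true_class == "GABA_inhibited":
        return (gaba_inh,)
    if true_class == "Mixed":
        return (gaba_inh, glu_exc)
    if true_class == "GABA_activated":
        # polysynaptic: released from inhibition via an intermediate GABAergic
        # cell, so it behaves as a slower GABA-dependent excitation
        return (
            ResponseComponent(
                "GABA", "excitation",
                fx.excitation_latency + fx.polysynaptic_extra_latency,
                fx.excitation_duration, fx.excitation_hz,
            ),
        )
    if true_class == "Glu_activated":
        return (glu_exc,)
    if true_class == "Glu_disinhibited":
        # glutamatergic drive masked at baseline by co-active GABAergic
        # shunting scaled so the net rate change is zero until BIC is applied
        return (
            replace(glu_exc),
            ResponseComponent(
                "GABA", "inhibition", fx.excitation_latency, fx.excitation_duration,
                0.2,
            ),
        )
    if true_class == "non_responsive":
        return ()
    raise ValueError(f"unknown class {true_class!r}")


def opto_components(
    opto_identity: str, fx: EffectSizes = EffectSizes(), modality: str = "opto_wide"
) -> tuple[ResponseComponent, ...]:
    if opto_identity in ("VIP_innervated", "GAD_innervated"):
        return (
            ResponseComponent(
                "GABA", "inhibition", fx.opto_inhibition_latency,
                fx.inhibition_duration, fx.inhibition_multiplier, evoked_by=modality,
            ),
        )
    if opto_identity == "ChR2_direct":
        return (
            ResponseComponent(
                "ChR2", "excitation", fx.chr2_latency, fx.chr2_duration, fx.chr2_hz,
                evoked_by=modality,
            ),
        )
    if opto_identity == "none":
        return ()
    raise ValueError(f"unknown opto identity {opto_identity!r}")


#: default class mix: prevalences representative of extracellular recordings
#: across the SPZ/PVN/ventral thalamus (54/666 inhibited split 2:1
#: GABA-only:mixed, 59/666 activated mostly glutamatergic, 13/666 disinhibited,
#: remainder unresponsive to SCN-region stimulation)
DEFAULT_CLASS_PROBS = {
    "GABA_inhibited": 36 / 666,
    "Mixed": 18 / 666,
    "GABA_activated": 12 / 666,
    "Glu_activated": 47 / 666,
    "Glu_disinhibited": 13 / 666,
    "non_responsive": 540 / 666,
}

#: fraction of each class exhibiting circadian firing in long-term recordings
DEFAULT_RHYTHMIC_FRACTIONS = {
    "GABA_inhibited": 45 / 54,
    "Mixed": 45 / 54,
    "GABA_activated": 25 / 35,
    "Glu_activated": 25 / 35,
    "Glu_disinhibited": 25 / 35,
    "non_responsive": 566 / 651,
}


@dataclass
class PopulationConfig:
    """Sampling distribution for a simulated population of units.

    Defaults emulate the intact-SCN condition; ``scn_intact=False`` removes all
    SCN-evoked input, lowers the rhythmic fraction, broadens peak widths and
    references phases to time-since-start of recording (local oscillators
    re-set by slicing rather than entrained to the prior light cycle).
    """

    n_cells: int = 100
    class_probs: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROBS))
    rhythmic_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_RHYTHMIC_FRACTIONS)
    )
    scn_intact: bool = True
    scn_removed_rhythmic_fraction: float = (51 + 58 + 75) / (78 + 84 + 120)
    genotype: str = "VIP_ChR2"
    vip_innervated_fraction: float = 0.2  # of GABA-inhibited/mixed cells
    chr2_direct_fraction: float = 0.8  # of all cells, GAD2 genotype only
    mean_rate_hz: float = 5.0
    rate_lognorm_sigma: float = 0.3
    amplitude_ratio: float = 1.0  # peak-trough amplitude / mean rate (2 → trough 0)
    period_h: float = 24.0
    peak_width_mean_h: float = 7.0
    peak_width_sd_h: float = 1.5
    peak_width_removed_mean_h: float = 9.5
    peak_width_removed_sd_h: float = 2.0
    inhibited_phase_mean_zt: float = 18.0  # night/early-day clustering
    inhibited_phase_kappa: float = 2.0
    dv_max_um: float = 1000.0
    effect_sizes: EffectSizes = field(default_factory=EffectSizes)
    opto_modality: str = "opto_wide"
    latency_jitter_sd: float = 0.001

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.class_probs.values()), 1.0, abs_tol=1e-9):
            if sum(self.class_probs.values()) > 1.0 + 1e-9:
                raise ValueError("class probabilities must sum to <= 1")


def sample_population(
    config: PopulationConfig, seed: int = 0, slice_id: str = "slice0"
) -> list[CellSpec]:
    """Draw a list of :class:`CellSpec` from a population configuration."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    classes = list(config.class_probs)
    probs = np.array([config.class_probs[c] for c in classes], dtype=float)
    leftover = 1.0 - probs.sum()
    if leftover > 1e-9:
        classes.append("non_responsive")
        probs = np.append(probs, leftover)
    fx = config.effect_sizes

    specs = []
    for i in range(config.n_cells):
        cls = classes[rng.choice(len(classes), p=probs / probs.sum())]
        if not config.scn_intact and cls != "non_responsive":
            cls = "non_responsive"  # no SCN left to evoke synaptic input

        rhythm_frac = (
            config.rhythmic_fractions[cls]
            if config.scn_intact
            else config.scn_removed_rhythmic_fraction
        )
        rhythmic = rng.random() < rhythm_frac
        mean_rate = config.mean_rate_hz * rng.lognormal(0.0, config.rate_lognorm_sigma)

        inhibited = cls in ("GABA_inhibited", "Mixed")
        if not config.scn_intact:
            peak_ref, peak = "rec", float(rng.uniform(0.0, 24.0))
            width_mu, width_sd = (
                config.peak_width_removed_mean_h,
                config.peak_width_removed_sd_h,
            )
        else:
            peak_ref = "zt"
            width_mu, width_sd = config.peak_width_mean_h, config.peak_width_sd_h
            if inhibited:
                peak = float(
                    np.mod(
                        config.inhibited_phase_mean_zt
                        + 12.0
                        / np.pi
                        * rng.vonmises(0.0, config.inhibited_phase_kappa),
                        24.0,
                    )
                )
            else:
                peak = float(rng.uniform(0.0, 24.0))
        width = float(np.clip(rng.normal(width_mu, width_sd), 2.0, 18.0))

        opto_identity = "none"
        if config.genotype == "GAD2_ChR2":
            if rng.random() < config.chr2_direct_fraction:
                opto_identity = "ChR2_direct"
        elif config.genotype == "VIP_ChR2" and inhibited:
            if rng.random() < config.vip_innervated_fraction:
                opto_identity = "VIP_innervated"

        comps = tuple(
            electrical_components(cls, fx) if config.scn_intact else ()
        ) + tuple(opto_components(opto_identity, fx, config.opto_modality))

        specs.append(
            CellSpec(
                unit_id=f"u{i:04d}",
                true_class=cls,
                opto_identity=opto_identity,
                baseline_rate=mean_rate,
                rhythmic=rhythmic,
                period=config.period_h,
                peak_time=peak,
                peak_ref=peak_ref,
                peak_width=width,
                peak_trough_amplitude=(
                    config.amplitude_ratio * mean_rate if rhythmic else 0.0
                ),
                components=comps,
                dv_offset=float(rng.uniform(0.0, config.dv_max_um)),
                ml_offset=float(rng.uniform(-100.0, 100.0)),
                slice_id=slice_id,
                genotype=config.genotype,
                latency_jitter_sd=config.latency_jitter_sd,
            )
        )
    return specs
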