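"""Session data model, TSV/JSON serialization and anatomical region assignment.

A :class:`RecordingSession` bundles everything one ex vivo multielectrode
recording produces after spike sorting: per-unit spike-time lists with
electrode positions, the stimulus log (electrical pulses to the SCN region and
interleaved optogenetic flashes), and the pharmacological epoch annotations
(baseline, GABA-A block, combined GABA/glutamate block, ...).

All times are seconds from recording start.  Intervals are half-open
``[start, end)``.  Projected Zeitgeber time of any event is
``(prep_time_zt + t/3600) mod 24`` with ZT0 = lights-on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GENOTYPES",
    "MODALITIES",
    "EPOCH_LABELS",
    "REGIONS",
    "DEFAULT_REGION_BOUNDARIES",
    "SpikeTrain",
    "StimulusEvent",
    "PharmEpoch",
    "RecordingSession",
    "ValidationError",
    "assign_region",
    "projected_zt",
    "read_session",
    "write_session",
]

GENOTYPES = ("VIP_ChR2", "GAD2_ChR2", "cre_negative")
MODALITIES = ("electrical", "opto_wide", "opto_local")
EPOCH_LABELS = ("baseline", "BIC", "BIC_iGluX", "iGluX", "NMDA", "TTX")
REGIONS = ("SPZ", "PVN", "ventral_thalamus")

#: Dorsal-vental boundaries (µm dorsal of the SCN ventral-boundary/midline
#: reference point).  SPZ = [0, 350), PVN = [350, 700), ventral thalamus
#: beyond.  These are configuration, not measured anatomy; override per slice.
DEFAULT_REGION_BOUNDARIES = (350.0, 700.0)


class ValidationError(ValueError):
    """A session table violates a structural invariant."""


@dataclass
class SpikeTrain:
    """One sorted unit: spike times plus projected electrode position."""

    unit_id: str
    slice_id: str
    spike_times: np.ndarray  # seconds, ascending
    dv_offset: float  # µm dorsal of the anatomical reference point
    ml_offset: float  # µm lateral of the midline
    genotype: str = "VIP_ChR2"

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=np.float64)

    def validate(self, duration: float) -> None:
        t = self.spike_times
        if t.size and np.any(np.diff(t) < 0):
            raise ValidationError(f"unit {self.unit_id}: spike_times not sorted")
        if t.size and (t[0] < 0 or t[-1] > duration):
            raise ValidationError(
                f"unit {self.unit_id}: spike times outside [0, {duration}] s"
            )
        if self.dv_offset < 0:
            raise ValidationError(f"unit {self.unit_id}: dv_offset < 0")
        if self.genotype not in GENOTYPES:
            raise ValidationError(f"unit {self.unit_id}: genotype {self.genotype!r}")

    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass(frozen=True)
class StimulusEvent:
    time: float  # seconds
    modality: str  # electrical | opto_wide | opto_local

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown stimulus modality {self.modality!r}")


@dataclass(frozen=True)
class PharmEpoch:
    """Half-open drug-condition interval ``[start, end)``."""

    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.label not in EPOCH_LABELS:
            raise ValidationError(f"unknown epoch label {self.label!r}")
        if not self.start < self.end:
            raise ValidationError(f"epoch {self.label}: start >= end")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end


@dataclass
class RecordingSession:
    session_id: str
    mode: str  # acute | longterm
    prep_time_zt: float  # hours, slice preparation time
    scn_intact: bool
    duration: float  # seconds
    trains: list[SpikeTrain] = field(default_factory=list)
    stimuli: list[StimulusEvent] = field(default_factory=list)
    epochs: list[PharmEpoch] = field(default_factory=list)
    region_boundaries: tuple[float, ...] = DEFAULT_REGION_BOUNDARIES

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.mode not in ("acute", "longterm"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if not 0 <= self.prep_time_zt < 24:
            raise ValidationError("prep_time_zt must lie in [0, 24)")
        if self.duration <= 0:
            raise ValidationError("duration must be positive")
        b = tuple(self.region_boundaries)
        if len(b) != 2 or not (0 < b[0] < b[1]):
            raise ValidationError("region_boundaries must be two increasing positives")
        for tr in self.trains:
            tr.validate(self.duration)
        seen_labels: set[str] = set()
        for ep in sorted(self.epochs, key=lambda e: e.start):
            if ep.label in seen_labels:
                raise ValidationError(f"epoch label {ep.label} appears twice")
            seen_labels.add(ep.label)
            if ep.end > self.duration + 1e-9 or ep.start < 0:
                raise ValidationError(f"epoch {ep.label} outside session")
        eps = sorted(self.epochs, key=lambda e: e.start)
        for a, b_ in zip(eps, eps[1:]):
            if a.end > b_.start + 1e-9:
                raise ValidationError(f"epochs {a.label} and {b_.label} overlap")
        for mod in MODALITIES:
            times = [s.time for s in self.stimuli if s.modality == mod]
            if any(np.diff(times) < 0):
                raise ValidationError(f"{mod} stimuli not sorted")
            if times and (min(times) < 0 or max(times) >= self.duration):
                raise ValidationError(f"{mod} stimulus outside session")

    # -- convenience accessors -------------------------------------------------

    def stimulus_times(self, modality: str) -> np.ndarray:
        return np.array(
            [s.time for s in self.stimuli if s.modality == modality], dtype=float
        )

    def epoch(self, label: str) -> PharmEpoch:
        for ep in self.epochs:
            if ep.label == label:
                return ep
        raise KeyError(label)

    def epoch_at(self, t: float) -> PharmEpoch | None:
        for ep in self.epochs:
            if ep.contains(t):
                return ep
        return None

    def train(self, unit_id: str) -> SpikeTrain:
        for tr in self.trains:
            if tr.unit_id == unit_id:
                return tr
        raise KeyError(unit_id)

    def unit_region(self, unit_id: str) -> str:
        return assign_region(self.train(unit_id).dv_offset, self.region_boundaries)


def projected_zt(t_seconds: float | np.ndarray, prep_time_zt: float):
    """Projected Zeitgeber time (hours) of a within-recording time."""
    return np.mod(prep_time_zt + np.asarray(t_seconds) / 3600.0, 24.0)


def assign_region(
    dv_offset: float, region_boundaries: Sequence[float] = DEFAULT_REGION_BOUNDARIES
) -> str:
    """Map a dorsal offset (µm from the SCN reference point) to a region name.

    Regions are half-open: ``SPZ = [0, b0)``, ``PVN = [b0, b1)``, ventral
    thalamus ``[b1, ∞)``.
    """
    if dv_offset < 0:
        raise ValueError("dv_offset must be >= 0")
    b = np.asarray(region_boundaries, dtype=float)
    if b.size != 2 or not np.all(np.diff(b) > 0):
        raise ValueError("region_boundaries must be two strictly increasing values")
    return REGIONS[int(np.searchsorted(b, dv_offset, side="right"))]


# -- serialization -------------------------------------------------------------

_SPIKE_COLS = ["unit_id", "slice_id", "time_s", "dv_offset_um", "ml_offset_um"]

def _fmt(t: float) -> str:
    return f"{t:.6f}"


def quantize_times(t: np.ndarray) -> np.ndarray:
    """Round times to the stored microsecond resolution.

    Integer-microsecond / 1e6 doubles survive a ``%.6f`` format → parse cycle
    bit-exactly, which is what makes the round-trip contract hold.
    """
    return np.round(np.asarray(t, dtype=np.float64) * 1e6) / 1e6


def write_session(session: RecordingSession, path: str | Path) -> None:
    """Write a session directory: spikes.tsv, stimuli.tsv, epochs.tsv, session.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    rows = []
    for tr in session.trains:
        for t in tr.spike_times:
            rows.append(
                (tr.unit_id, tr.slice_id, _fmt(t), f"{tr.dv_offset:.1f}", f"{tr.ml_offset:.1f}")
            )
    pd.DataFrame(rows, columns=_SPIKE_COLS).to_csv(
        path / "spikes.tsv", sep="\t", index=False
    )

    pd.DataFrame(
        [(_fmt(s.time), s.modality) for s in session.stimuli],
        columns=["time_s", "modality"],
    ).to_csv(path / "stimuli.tsv", sep="\t", index=False)

    pd.DataFrame(
        [(e.label, _fmt(e.start), _fmt(e.end)) for e in session.epochs],
        columns=["label", "start_s", "end_s"],
    ).to_csv(path / "epochs.tsv", sep="\t", index=False)

    meta = {
        "session_id": session.session_id,
        "mode": session.mode,
        "prep_time_zt": session.prep_time_zt,
        "scn_intact": session.scn_intact,
        "duration_s": session.duration,
        "region_boundaries_um": list(session.region_boundaries),
        "units": {
            tr.unit_id: {"genotype": tr.genotype} for tr in session.trains
        },
        # unit order and empty units must survive the round trip even though
        # spikes.tsv only names units that fired
        "unit_order": [
            [tr.unit_id, tr.slice_id, tr.dv_offset, tr.ml_offset]
            for tr in session.trains
        ],
    }
    (path / "session.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_session(path: str | Path) -> RecordingSession:
    """Read and validate a session directory written by :func:`write_session`."""
    path = Path(path)
    for fname in ("spikes.tsv", "stimuli.tsv", "epochs.tsv", "session.json"):
        if not (path / fname).exists():
            raise FileNotFoundError(f"session file missing: {path / fname}")
    meta = json.loads((path / "session.json").read_text())
    spikes = pd.read_csv(
        path / "spikes.tsv",
        sep="\t",
        dtype={"unit_id": str, "slice_id": str, "time_s": np.float64},
    )
    stim = pd.read_csv(path / "stimuli.tsv", sep="\t", dtype={"time_s": np.float64})
    epochs = pd.read_csv(path / "epochs.tsv", sep="\t")

    by_unit = {uid: g for uid, g in spikes.groupby("unit_id", sort=False)}
    trains = []
    for unit_id, slice_id, dv, ml in meta["unit_order"]:
        g = by_unit.get(unit_id)
        times = np.array([], dtype=np.float64) if g is None else g["time_s"].to_numpy()
        trains.append(
            SpikeTrain(
                unit_id=unit_id,
                slice_id=slice_id,
                spike_times=times,
                dv_offset=float(dv),
                ml_offset=float(ml),
                genotype=meta["units"][unit_id]["genotype"],
            )
        )
    session = RecordingSession(
        session_id=meta["session_id"],
        mode=meta["mode"],
        prep_time_zt=float(meta["prep_time_zt"]),
        scn_intact=bool(meta["scn_intact"]),
        duration=float(meta["duration_s"]),
        trains=trains,
        stimuli=[
            StimulusEvent(float(r.time_s), str(r.modality)) for r in stim.itertuples()
        ],
        epochs=[
            PharmEpoch(str(r.label), float(r.start_s), float(r.end_s))
            for r in epochs.itertuples()
        ],
        region_boundaries=tuple(meta["region_boundaries_um"]),
    )
    return session
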