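"""End-to-end pipeline: simulate → detect responses → classify → rhythms → phases.

Everything is driven by a :class:`PipelineConfig` whose defaults are the
experiment's standard constants (2-s / 60-s stimulus intervals, 99% / 95%
confidence limits, 100-ms response and 25-ms / 15-ms analysis windows, 20–28 h
period constraint, 60-s rate bins, 2-h boxcar, 50% width threshold, 6-h phase
bins).  A fixed config + seed reproduces every output table byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import classification_table
from .circadian import rhythm_table
from .data_io import RecordingSession, write_session
from .phase_stats import circular_error_hours, phase_distribution
from .stim_response import response_table
from .synthetic import (
    AcuteProtocol,
    LongtermProtocol,
    PopulationConfig,
    sample_population,
    simulate_session,
)

__all__ = ["PipelineConfig", "run_pipeline", "compare_to_truth"]

log = logging.getLogger("circuitclock")

_FLOAT_FMT = "%.6f"


@dataclass
class PipelineConfig:
    seed: int = 0
    protocol: str = "acute"  # acute | longterm
    n_cells: int = 30
    scn_intact: bool = True
    population: PopulationConfig | None = None
    acute: AcuteProtocol = field(default_factory=AcuteProtocol)
    longterm: LongtermProtocol = field(default_factory=LongtermProtocol)
    alpha: float = 0.01
    latency_alpha: float = 0.05
    epoch_minutes: float | None = 25.0  # acute drug epochs; longterm uses all
    fit_bin_s: float = 900.0
    rhythm_criterion: str = "bic"
    smooth_h: float = 2.0
    phase_bin_h: float = 6.0

    def population_config(self) -> PopulationConfig:
        if self.population is not None:
            return self.population
        return PopulationConfig(n_cells=self.n_cells, scn_intact=self.scn_intact)

    def protocol_obj(self):
        return self.acute if self.protocol == "acute" else self.longterm

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "population" in d and isinstance(d["population"], dict):
            d["population"] = PopulationConfig(**d["population"])
        if "acute" in d and isinstance(d["acute"], dict):
            d["acute"] = AcuteProtocol(**d["acute"])
        if "longterm" in d and isinstance(d["longterm"], dict):
            d["longterm"] = LongtermProtocol(**d["longterm"])
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage on a freshly simulated session; returns the report dict.

    Writes into ``out_dir``: the session directory, ``truth.tsv``,
    ``responses.tsv``, ``opto_responses.tsv``, ``classes.tsv``, for long-term
    sessions ``rhythms.tsv`` and ``phases.tsv``, plus ``config.json``,
    ``report.json`` and a log file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> dict:
    (out / "config.json").write_text(
        json.dumps(config.to_dict(), indent=1, sort_keys=True)
    )
    log.info("circuitclock %s seed=%d protocol=%s", __version__, config.seed,
             config.protocol)

    pop = config.population_config()
    specs = sample_population(pop, seed=config.seed)
    protocol = config.protocol_obj()
    session, truth = simulate_session(
        specs, protocol, seed=config.seed, scn_intact=pop.scn_intact
    )
    write_session(session, out / "session")
    _write(truth, out / "truth.tsv")
    log.info("simulated %d units, %d stimuli", len(session.trains),
             len(session.stimuli))

    minutes = config.epoch_minutes if config.protocol == "acute" else None
    responses = response_table(
        session, "electrical", alpha=config.alpha, epoch_minutes=minutes
    )
    _write(responses, out / "responses.tsv")
    opto = response_table(
        session, pop.opto_modality, alpha=config.alpha, epoch_minutes=minutes
    )
    _write(opto, out / "opto_responses.tsv")

    regions = {tr.unit_id: session.unit_region(tr.unit_id) for tr in session.trains}
    genotypes = {tr.unit_id: tr.genotype for tr in session.trains}
    classes = classification_table(responses, opto, regions, genotypes)
    _write(classes, out / "classes.tsv")
    log.info("classified %d units", len(classes))

    report = {
        "seed": config.seed,
        "protocol": config.protocol,
        "n_units": len(session.trains),
        "version": __version__,
    }

    rhythms = None
    if config.protocol == "longterm":
        rhythms = rhythm_table(
            session,
            fit_bin_s=config.fit_bin_s,
            criterion=config.rhythm_criterion,
            smooth_h=config.smooth_h,
            classes=classes,
        )
        _write(rhythms, out / "rhythms.tsv")
        phases = _phase_table(rhythms, responses, session)
        _write(phases, out / "phases.tsv")
        report["phase_summary"] = _phase_summary(phases, config.phase_bin_h)
        log.info("rhythmic: %d/%d", int(rhythms["rhythmic"].sum()), len(rhythms))

    report.update(compare_to_truth(classes, truth, rhythms))
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _phase_table(rhythms, responses, session: RecordingSession) -> pd.DataFrame:
    """Tidy peak-phase samples of rhythmic units, grouped by baseline response."""
    base = responses[responses["epoch"] == "baseline"].set_index("unit_id")[
        "direction"
    ]
    ref = "projected_ZT" if session.scn_intact else "time_since_start"
    rows = []
    for r in rhythms.itertuples():
        if not r.rhythmic or r.flag:
            continue
        phase = r.peak_zt_h if ref == "projected_ZT" else r.peak_rec_h % 24.0
        rows.append(
            {
                "unit_id": r.unit_id,
                "slice_id": r.slice_id,
                "phase": phase % 24.0,
                "reference": ref,
                "group": base.get(r.unit_id, "none"),
                "region": r.region,
            }
        )
    return pd.DataFrame(
        rows, columns=["unit_id", "slice_id", "phase", "reference", "group", "region"]
    )


def _phase_summary(phases: pd.DataFrame, bin_h: float) -> dict:
    out = {}
    for group, grp in phases.groupby("group"):
        if grp.empty:
            continue
        d = phase_distribution(grp["phase"].to_numpy(), bin_h)
        out[str(group)] = {
            "n": d.n,
            "bin_counts": d.bin_counts.tolist(),
            "chi2": round(d.chi2, 6),
            "p": round(d.p, 6),
            "rayleigh_R": round(d.rayleigh_R, 6),
            "circ_mean_h": round(d.circ_mean, 6),
        }
    return out


def compare_to_truth(
    classes: pd.DataFrame,
    truth: pd.DataFrame,
    rhythms: pd.DataFrame | None = None,
) -> dict:
    """Ground-truth recovery report: confusion matrices and parameter errors."""
    if not set(classes["unit_id"]) == set(truth["unit_id"]):
        raise ValueError("classification table and truth table disagree on unit ids")
    merged = truth.merge(classes, on="unit_id")
    confusion = pd.crosstab(merged["true_class"], merged["cell_class"])
    exact = float((merged["true_class"] == merged["cell_class"]).mean())
    nr = merged[merged["true_class"] == "non_responsive"]
    converted = float(
        (nr["cell_class"].isin(
            ["GABA_inhibited", "Mixed", "GABA_activated", "Glu_activated",
             "Glu_disinhibited"]
        )).mean()
    ) if len(nr) else 0.0
    report = {
        "class_confusion": {
            str(k): {str(c): int(v) for c, v in row.items()}
            for k, row in confusion.iterrows()
        },
        "class_exact_recovery": exact,
        "non_responsive_conversion_rate": converted,
    }
    if rhythms is not None:
        m = truth.merge(rhythms, on="unit_id", suffixes=("_true", ""))
        tp = m[m["rhythmic_true"] & m["rhythmic"]]
        report["rhythm"] = {
            "sensitivity": float(m.loc[m["rhythmic_true"], "rhythmic"].mean())
            if m["rhythmic_true"].any() else np.nan,
            "specificity": float((~m.loc[~m["rhythmic_true"], "rhythmic"]).mean())
            if (~m["rhythmic_true"]).any() else np.nan,
            "n_true_positive": int(len(tp)),
            "period_abs_err_h_median": float(
                np.median(np.abs(tp["period_h"] - m.loc[tp.index, "period_h_true"]))
            ) if len(tp) else np.nan,
            "phase_abs_err_h_median": float(
                np.median(
                    circular_error_hours(
                        tp["peak_rec_h"] % 24.0, m.loc[tp.index, "peak_rec_h_true"]
                    )
                )
            ) if len(tp) else np.nan,
            "width_abs_err_h_median": float(
                np.median(np.abs(tp["width_h"] - m.loc[tp.index, "peak_width_h"]))
            ) if len(tp) else np.nan,
        }
    return report
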