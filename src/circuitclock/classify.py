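"""Pharmacological response taxonomy and optogenetic phenotyping.

Five response classes are resolved from how a unit's evoked response to
electrical stimulation of the SCN region changes across the drug protocol
(baseline → GABA-A block with bicuculline → combined block with
ionotropic glutamate antagonists):

========================  ========  =======  ==========
class                     baseline  BIC      BIC+iGlu-X
========================  ========  =======  ==========
GABA_inhibited            inhibited none     --
Mixed                     inhibited excited  none
GABA_activated            excited   none     --
Glu_activated             excited   excited  none
Glu_disinhibited          none      excited  none
non_responsive            none      none     none
========================  ========  =======  ==========

Any other pattern — or a pattern whose deciding epochs were not recorded — is
reported as ``unclassified`` rather than forced into the nearest class.

Optogenetic phenotypes: cells inhibited by light with the inhibition removed
by bicuculline are synaptically innervated by the photostimulated SCN
population (``VIP_innervated`` / ``GAD_innervated`` depending on genotype);
cells whose light-evoked excitation persists under the combined blockade
express channelrhodopsin themselves (``ChR2_direct``).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .stim_response import ResponseCall

__all__ = [
    "CELL_CLASSES",
    "OPTO_PHENOTYPES",
    "classify_cell",
    "opto_phenotype",
    "classification_table",
    "crosstab_classes",
]

CELL_CLASSES = (
    "GABA_inhibited",
    "Mixed",
    "GABA_activated",
    "Glu_activated",
    "Glu_disinhibited",
    "non_responsive",
    "unclassified",
)

OPTO_PHENOTYPES = ("opto_inhibited", "ChR2_direct", "none")


def _direction(call) -> str:
    return call.direction if isinstance(call, ResponseCall) else str(call)


def classify_cell(calls: Mapping[str, "ResponseCall | str"]) -> str:
    """Resolve the response class from per-epoch electrical-stimulation calls.

    ``calls`` maps epoch label → :class:`ResponseCall` (or bare direction
    string).  A baseline call is mandatory; rules whose deciding drug epochs
    are absent yield ``unclassified`` instead of guessing.
    """
    if "baseline" not in calls:
        raise ValueError("baseline response call is required")
    base = _direction(calls["baseline"])
    bic = _direction(calls["BIC"]) if "BIC" in calls else None
    bix = _direction(calls["BIC_iGluX"]) if "BIC_iGluX" in calls else None

    if base == "inhibited":
        if bic == "none":
            return "GABA_inhibited"
        if bic == "excited":
            return "Mixed" if bix == "none" else "unclassified"
        return "unclassified"
    if base == "excited":
        if bic == "none":
            return "GABA_activated"
        if bic == "excited":
            return "Glu_activated" if bix == "none" else "unclassified"
        return "unclassified"
    if base == "none":
        if bic == "excited":
            return "Glu_disinhibited" if bix == "none" else "unclassified"
        if bic == "none" and bix in (None, "none"):
            return "non_responsive"
        return "unclassified"
    raise ValueError(f"unknown direction {base!r}")


def opto_phenotype(
    calls: Mapping[str, "ResponseCall | str"], genotype: str = "VIP_ChR2"
) -> str:
    """Phenotype from per-epoch optogenetic-stimulation calls.

    Cre-negative tissue expresses no opsin, so any apparent response there is
    treated as a false positive and the phenotype forced to ``none``.
    """
    if "baseline" not in calls:
        raise ValueError("baseline opto response call is required")
    if genotype == "cre_negative":
        if _direction(calls["baseline"]) != "none":
            import warnings

            warnings.warn(
                "opto response detected in cre-negative tissue; ignoring",
                stacklevel=2,
            )
        return "none"
    base = _direction(calls["baseline"])
    bic = _direction(calls["BIC"]) if "BIC" in calls else None
    bix = _direction(calls["BIC_iGluX"]) if "BIC_iGluX" in calls else None
    if base == "inhibited" and bic in (None, "none"):
        return "opto_inhibited"
    if base == "excited" and bix == "excited":
        return "ChR2_direct"
    return "none"


def innervation_label(phenotype: str, genotype: str) -> str:
    """Human-readable innervation label for an opto-inhibited cell."""
    if phenotype != "opto_inhibited":
        return phenotype
    return {"VIP_ChR2": "VIP_innervated", "GAD2_ChR2": "GAD_innervated"}.get(
        genotype, "opto_inhibited"
    )


def classification_table(
    responses: pd.DataFrame,
    opto_responses: pd.DataFrame | None = None,
    regions: Mapping[str, str] | None = None,
    genotypes: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Classify every unit in a tidy response table.

    ``responses``/``opto_responses`` are :func:`~circuitclock.stim_response.
    response_table` outputs.  Returns one row per unit with columns
    ``unit_id, cell_class, opto_phenotype, region``.
    """
    rows = []
    for unit_id, grp in responses.groupby("unit_id", sort=True):
        calls = dict(zip(grp["epoch"], grp["direction"]))
        genotype = (genotypes or {}).get(unit_id, "VIP_ChR2")
        pheno = "none"
        if opto_responses is not None and len(opto_responses):
            ogrp = opto_responses[opto_responses["unit_id"] == unit_id]
            if len(ogrp):
                ocalls = dict(zip(ogrp["epoch"], ogrp["direction"]))
                pheno = opto_phenotype(ocalls, genotype)
        rows.append(
            {
                "unit_id": unit_id,
                "cell_class": classify_cell(calls),
                "opto_phenotype": pheno,
                "opto_label": innervation_label(pheno, genotype),
                "region": (regions or {}).get(unit_id, ""),
            }
        )
    return pd.DataFrame(
        rows, columns=["unit_id", "cell_class", "opto_phenotype", "opto_label", "region"]
    )


def crosstab_classes(
    classified: pd.DataFrame, dv_offsets: Mapping[str, float] | None = None,
    dv_bin_um: float = 200.0,
) -> dict[str, pd.DataFrame]:
    """Contingency tables over the classified population.

    Returns ``class_by_region``, ``class_by_opto`` and (when electrode
    positions are supplied) ``class_by_dv_bin`` count tables whose rows sum to
    the per-class cell totals.
    """
    if classified.empty:
        raise ValueError("need at least one classified cell")
    out = {
        "class_by_region": pd.crosstab(
            classified["cell_class"], classified["region"]
        ),
        "class_by_opto": pd.crosstab(
            classified["cell_class"], classified["opto_phenotype"]
        ),
    }
    if "opto_phenotype" not in classified or classified["opto_phenotype"].eq(
        "none"
    ).all():
        # keep an explicit all-zero opto-positive column for empty opto data
        tab = out["class_by_opto"]
        for col in ("opto_inhibited", "ChR2_direct"):
            if col not in tab.columns:
                tab[col] = 0
    if dv_offsets:
        dv = classified["unit_id"].map(dv_offsets)
        bins = (dv // dv_bin_um * dv_bin_um).astype(float)
        out["class_by_dv_bin"] = pd.crosstab(classified["cell_class"], bins)
    return out
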