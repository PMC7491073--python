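"""Extracellular-flux trace analysis: segmentation and derived metrics.

The glycolysis-assay schedule has three phases separated by two
injections: basal measurements, one measurement after oligomycin (ATP
synthase inhibited), and two final measurements after rotenone/antimycin A
(electron transport fully inhibited).  From an OCR trace:

    mitochondrial basal respiration = basal - non-mitochondrial
    ATP-linked respiration          = basal - post-oligomycin
    proton leak                     = post-oligomycin - non-mitochondrial
    coupling efficiency (%)         = 100 * ATP-linked / mitochondrial basal

where basal is the last measurement before the first injection and the
non-mitochondrial rate is the minimum measurement after the second
injection.  ECAR traces are normalized to the final non-glycolytic
acidification value per well (that well's last post-rotenone/antimycin
point reads 100%).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .instruments import FluxTrace

__all__ = [
    "PhaseMetrics",
    "MissingPhaseError",
    "segment_trace",
    "respiration_metrics",
    "ecar_percent_nonglycolytic",
    "glycolytic_rate",
    "analyze_traces",
]


class MissingPhaseError(ValueError):
    """A trace lacks measurements in a required phase."""

    def __init__(self, phase: str, well: str = ""):
        self.phase = phase
        super().__init__(f"no measurement in phase {phase!r}" + (f" (well {well})" if well else ""))


@dataclass(frozen=True)
class PhaseMetrics:
    """Raw phase values and (after completion) derived respiration metrics."""

    basal: float
    post_oligo: float
    nonmito_or_nonglyc: float
    mito_basal: float | None = None
    atp_linked: float | None = None
    proton_leak: float | None = None
    coupling_efficiency_pct: float | None = None
    defined: bool = True


def _phase_values(trace: FluxTrace, measurement: str) -> pd.DataFrame:
    sub = trace.data[trace.data["measurement"] == measurement]
    if sub.empty:
        raise MissingPhaseError(measurement, trace.well)
    return sub.sort_values("time_min")


def segment_trace(trace: FluxTrace, measurement: str = "OCR") -> PhaseMetrics:
    """Pick the phase-defining values from a trace.

    basal: last measurement strictly before the first injection;
    post_oligo: first measurement after oligomycin;
    nonmito/nonglycolytic: minimum measurement after rotenone/antimycin.
    """
    trace.validate()
    sub = _phase_values(trace, measurement)
    t_oligo = trace.injections[0][1]
    t_rotaa = trace.injections[1][1]
    basal = sub[sub["time_min"] < t_oligo]
    if basal.empty:
        raise MissingPhaseError("basal", trace.well)
    post_oligo = sub[(sub["time_min"] > t_oligo) & (sub["time_min"] < t_rotaa)]
    if post_oligo.empty:
        raise MissingPhaseError("post_oligomycin", trace.well)
    final = sub[sub["time_min"] > t_rotaa]
    if final.empty:
        raise MissingPhaseError("post_rotenone_antimycin", trace.well)
    return PhaseMetrics(
        basal=float(basal["value"].iloc[-1]),
        post_oligo=float(post_oligo["value"].iloc[0]),
        nonmito_or_nonglyc=float(final["value"].min()),
    )


def respiration_metrics(pm: PhaseMetrics) -> PhaseMetrics:
    """Complete a segmented OCR trace with the derived respiration metrics."""
    mito = pm.basal - pm.nonmito_or_nonglyc
    atp = pm.basal - pm.post_oligo
    leak = pm.post_oligo - pm.nonmito_or_nonglyc
    if mito <= 0:
        return replace(pm, mito_basal=mito, atp_linked=atp, proton_leak=leak,
                       coupling_efficiency_pct=float("nan"), defined=False)
    return replace(
        pm,
        mito_basal=mito,
        atp_linked=atp,
        proton_leak=leak,
        coupling_efficiency_pct=100.0 * atp / mito,
    )


def ecar_percent_nonglycolytic(trace: FluxTrace) -> pd.DataFrame:
    """Normalize a well's ECAR series to its final non-glycolytic value.

    Each value is expressed as value * 100 / (last post-rotenone/antimycin
    ECAR measurement of the same well); the final point reads exactly 100%.
    """
    trace.validate()
    sub = _phase_values(trace, "ECAR")
    t_rotaa = trace.injections[1][1]
    final = sub[sub["time_min"] > t_rotaa]
    if final.empty:
        raise MissingPhaseError("post_rotenone_antimycin", trace.well)
    ref = float(final["value"].iloc[-1])
    if ref <= 0:
        raise ValueError(f"zero final non-glycolytic ECAR in well {trace.well}")
    out = sub.copy()
    out["value_pct_nonglycolytic"] = out["value"] * 100.0 / ref
    out.insert(0, "well", trace.well)
    return out


def glycolytic_rate(pm: PhaseMetrics) -> float:
    """Basal minus non-glycolytic acidification (for an ECAR segmentation)."""
    return pm.basal - pm.nonmito_or_nonglyc


def analyze_traces(traces: list[FluxTrace], normalize_protein: bool = False) -> pd.DataFrame:
    """Per-well metric table for a set of traces.

    Columns: well, basal/post-oligomycin/non-mitochondrial OCR, ATP-linked,
    proton leak, coupling efficiency (%), basal and normalized ECAR and the
    glycolytic rate.  With ``normalize_protein`` raw rates are divided by
    the well's protein mass before reporting (the coupling efficiency and
    normalized ECAR are scale-invariant either way).
    """
    rows = []
    for trace in traces:
        ocr = respiration_metrics(segment_trace(trace, "OCR"))
        ecar = segment_trace(trace, "ECAR")
        norm = ecar_percent_nonglycolytic(trace)
        t_oligo = trace.injections[0][1]
        basal_pct = float(
            norm[norm["time_min"] < t_oligo]["value_pct_nonglycolytic"].iloc[-1]
        )
        scale = 1.0 / trace.protein_mg if normalize_protein else 1.0
        rows.append(
            {
                "well": trace.well,
                "basal_ocr": ocr.basal * scale,
                "post_oligo_ocr": ocr.post_oligo * scale,
                "nonmito_ocr": ocr.nonmito_or_nonglyc * scale,
                "mito_basal_ocr": ocr.mito_basal * scale,
                "atp_linked_ocr": ocr.atp_linked * scale,
                "proton_leak_ocr": ocr.proton_leak * scale,
                "coupling_efficiency_pct": ocr.coupling_efficiency_pct,
                "coupling_defined": ocr.defined,
                "basal_ecar": ecar.basal * scale,
                "nonglycolytic_ecar": ecar.nonmito_or_nonglyc * scale,
                "glycolytic_rate_ecar": glycolytic_rate(ecar) * scale,
                "basal_ecar_pct_nonglycolytic": basal_pct,
            }
        )
    return pd.DataFrame(rows)
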