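"""Generators for extracellular-flux traces and amino-acid pool tables.

``simulate_flux_traces`` emulates a 96-well extracellular flux (Seahorse-
style) glycolysis assay: baseline measurement cycles, injection of the ATP
synthase inhibitor oligomycin, one measurement, then injection of rotenone
plus antimycin A with two final measurement cycles.  OCR steps from basal
to basal minus the ATP-linked component after oligomycin and to the
non-mitochondrial rate after rotenone/antimycin; ECAR steps from basal
(optionally rising after oligomycin) to the non-glycolytic acidification
rate.

``simulate_amino_pools`` emulates the HPLC amino-acid quantification: peak
areas linear in concentration for cell extracts and for a calibration
standard series at increasing known concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .measure import CohortDesign, NoiseModel

__all__ = [
    "BioenergeticParams",
    "FluxTrace",
    "simulate_flux_traces",
    "simulate_amino_pools",
    "AMINO_ANALYTES",
]

AMINO_ANALYTES = ("glutamate", "glutamine", "aspartate", "alanine")

#: Default calibration line: area = slope * concentration + intercept.
DEFAULT_SLOPE = 120.0
DEFAULT_INTERCEPT = 4.0
DEFAULT_STANDARD_CONCENTRATIONS = (0.0, 1.0, 2.5, 5.0, 10.0, 25.0)


@dataclass(frozen=True)
class BioenergeticParams:
    """Ground truth for one group's flux traces.

    Rates are in instrument units (e.g. pmol O2/min for OCR, mpH/min for
    ECAR); ``atp_linked_fraction`` is the share of mitochondrial (basal
    minus non-mitochondrial) respiration that is ATP-linked -- the coupling
    efficiency the analyzer should recover.
    """

    basal_ocr: float = 100.0
    nonmito_ocr: float = 10.0
    atp_linked_fraction: float = 0.779
    basal_ecar: float = 30.0
    nonglycolytic_ecar: float = 10.0
    ecar_post_oligo_rise: float = 0.0
    wells: int = 6
    cycle_minutes: float = 6.0
    n_basal_cycles: int = 3
    protein_mg: float = 0.2

    def __post_init__(self) -> None:
        if not self.nonmito_ocr < self.basal_ocr:
            raise ValueError("nonmito_ocr must be < basal_ocr")
        if not 0.0 < self.atp_linked_fraction <= 1.0:
            raise ValueError("atp_linked_fraction must be in (0, 1]")
        if not self.nonglycolytic_ecar < self.basal_ecar:
            raise ValueError("nonglycolytic_ecar must be < basal_ecar")
        if self.wells < 1 or self.n_basal_cycles < 1:
            raise ValueError("need at least one well and one basal cycle")
        if self.cycle_minutes <= 0 or self.protein_mg <= 0:
            raise ValueError("cycle_minutes and protein_mg must be > 0")


@dataclass
class FluxTrace:
    """One well's timestamped ECAR/OCR series with its injection schedule."""

    well: str
    data: pd.DataFrame  # columns: time_min, measurement, value, phase
    injections: list[tuple[str, float]]
    protein_mg: float = 1.0

    def validate(self) -> None:
        labels = [lab for lab, _ in self.injections]
        if labels != ["oligomycin", "rotenone_antimycin"]:
            raise ValueError("injections must be oligomycin then rotenone_antimycin")
        times = self.injections[0][1], self.injections[1][1]
        if not times[0] < times[1]:
            raise ValueError("injection times must be increasing")
        for meas, sub in self.data.groupby("measurement"):
            t = sub["time_min"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"{meas}: times not strictly increasing")


def simulate_flux_traces(
    bp: BioenergeticParams,
    noise: NoiseModel,
    rng: np.random.Generator | None = None,
    well_prefix: str = "W",
) -> list[FluxTrace]:
    """Simulate one plate group's wells.

    Schedule per well: ``n_basal_cycles`` baseline measurements, oligomycin,
    one post-oligomycin measurement, rotenone/antimycin, two final
    measurements.  Gaussian noise with SD = cv * true value is added per
    point (plus the additive floor).
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    dt = bp.cycle_minutes
    t_basal = [dt * (i + 1) for i in range(bp.n_basal_cycles)]
    t_oligo = t_basal[-1] + 0.5 * dt
    t_post_oligo = t_basal[-1] + dt
    t_rotaa = t_post_oligo + 0.5 * dt
    t_final = [t_post_oligo + dt, t_post_oligo + 2 * dt]
    injections = [("oligomycin", t_oligo), ("rotenone_antimycin", t_rotaa)]

    mito = bp.basal_ocr - bp.nonmito_ocr
    ocr_levels = (
        [(t, bp.basal_ocr, "basal") for t in t_basal]
        + [(t_post_oligo, bp.basal_ocr - bp.atp_linked_fraction * mito, "post_oligomycin")]
        + [(t, bp.nonmito_ocr, "post_rotenone_antimycin") for t in t_final]
    )
    ecar_levels = (
        [(t, bp.basal_ecar, "basal") for t in t_basal]
        + [(t_post_oligo, bp.basal_ecar * (1.0 + bp.ecar_post_oligo_rise), "post_oligomycin")]
        + [(t, bp.nonglycolytic_ecar, "post_rotenone_antimycin") for t in t_final]
    )

    traces = []
    for w in range(1, bp.wells + 1):
        rows = []
        for meas, levels in (("OCR", ocr_levels), ("ECAR", ecar_levels)):
            for t, value, phase in levels:
                v = value + rng.normal(0.0, noise.cv_multiplicative * value)
                if noise.additive_floor > 0:
                    v += rng.normal(0.0, noise.additive_floor)
                rows.append(
                    {"time_min": t, "measurement": meas, "value": max(v, 0.0), "phase": phase}
                )
        trace = FluxTrace(
            well=f"{well_prefix}{w:02d}",
            data=pd.DataFrame(rows),
            injections=list(injections),
            protein_mg=bp.protein_mg,
        )
        trace.validate()
        traces.append(trace)
    return traces


def simulate_amino_pools(
    design: CohortDesign,
    noise: NoiseModel,
    rng: np.random.Generator | None = None,
    analytes=AMINO_ANALYTES,
    slope: float = DEFAULT_SLOPE,
    intercept: float = DEFAULT_INTERCEPT,
    standard_concentrations=DEFAULT_STANDARD_CONCENTRATIONS,
    protein_mg: float = 0.2,
    n_standard_replicates: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit per-replicate HPLC peak areas and a calibration-standard series.

    The analyte concentration in an extract is pool size (nmol/mg protein)
    times the well's protein mass (a unit extract volume is assumed), and
    the detector responds linearly: ``area = slope * conc + intercept``
    with multiplicative lognormal noise on the concentration signal.
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    pool_rows = []
    for line_id, group, params in design.lines:
        for rep in range(1, design.n_replicates + 1):
            prot = protein_mg
            for analyte in analytes:
                conc = params.pool_size(analyte) * prot
                signal = slope * conc * noise.lognormal_factors(rng, ())
                area = float(signal) + intercept
                if noise.additive_floor > 0:
                    area += float(rng.normal(0.0, noise.additive_floor))
                pool_rows.append(
                    {
                        "group": group,
                        "line": line_id,
                        "replicate": rep,
                        "analyte": analyte,
                        "area": max(area, 0.0),
                        "protein_mg": prot,
                    }
                )
    std_rows = []
    for analyte in analytes:
        for conc in standard_concentrations:
            for rep in range(1, n_standard_replicates + 1):
                signal = slope * conc * noise.lognormal_factors(rng, ())
                area = float(signal) + intercept
                if noise.additive_floor > 0:
                    area += float(rng.normal(0.0, noise.additive_floor))
                std_rows.append(
                    {
                        "analyte": analyte,
                        "concentration": conc,
                        "replicate": rep,
                        "area": max(area, 0.0),
                    }
                )
    return pd.DataFrame(pool_rows), pd.DataFrame(std_rows)
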