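"""Documented parameter presets for control and disease-like conditions.

The presets encode the *directions* of the FTD3 (CHMP2B-mutant) metabolic
phenotype reported for patient-derived neurons versus isogenic controls --
they are not fitted flux values (no flux magnitudes are available to fit):

* glycolytic pyruvate supply down (reduced lactate/alanine M+3 labeling),
* TCA turnover up (larger citrate-derived alpha-KG share, faster cycle-pool
  turnover, hence larger cycling ratios and more M+2 intermediates),
* glutaminase (PAG) route up (more glutamine-derived labeling),
* GDH/AAT glutamate entry down (less labeling from exogenous glutamate),
* glutamine pool roughly halved,
* mitochondrial coupling efficiency down, basal ECAR down.

Astrocyte mode adds glutamine synthetase flux and elevated glutamate
uptake; pyruvate carboxylase is not modeled in either cell type.
"""

from __future__ import annotations

from dataclasses import replace

from .instruments import BioenergeticParams
from .measure import CohortDesign
from .propagate import (
    FluxParameterSet,
    TracerConfig,
    glucose_tracer,
    glutamate_tracer,
    glutamine_tracer,
)

__all__ = [
    "control_flux_params",
    "ftd3_flux_params",
    "control_bioenergetics",
    "ftd3_bioenergetics",
    "default_cohort_design",
    "neuron_tracer_panel",
]

#: Intracellular pool sizes, nmol/mg protein.  Glutamate and glutamine match
#: the measured neuronal contents (61 and 12 nmol/mg in controls; the
#: glutamine pool is roughly halved and succinate/malate are elevated in the
#: disease preset).
_CONTROL_POOLS = {
    "lactate": 25.0,
    "alanine": 8.0,
    "akg": 1.5,
    "succinate": 3.0,
    "fumarate": 1.5,
    "malate": 4.0,
    "oaa": 0.2,
    "aspartate": 20.0,
    "glutamate": 61.0,
    "glutamine": 12.0,
    "pyruvate": 1.0,
    "citrate": 3.0,
    "accoa": 0.05,
}

_FTD3_POOLS = {
    **_CONTROL_POOLS,
    "glutamine": 6.0,
    "glutamate": 55.0,
    "succinate": 4.0,
    "malate": 5.0,
}

_CONTROL_RHO = {
    "pyruvate": 0.3,
    "lactate": 0.5,
    "alanine": 0.5,
    "accoa": 0.3,
    "citrate": 0.3,
    "akg": 0.3,
    "succinate": 0.3,
    "fumarate": 0.3,
    "malate": 0.3,
    "oaa": 0.3,
    "aspartate": 0.5,
    "glutamate": 0.5,
    "glutamine": 0.5,
}

# faster cycle-pool turnover in the disease preset
_FTD3_RHO = {
    **_CONTROL_RHO,
    "citrate": 0.15,
    "akg": 0.15,
    "succinate": 0.15,
    "fumarate": 0.15,
    "malate": 0.15,
    "oaa": 0.15,
}


def control_flux_params(cell_type: str = "neuron") -> FluxParameterSet:
    """Isogenic-control preset."""
    params = FluxParameterSet(
        f_glycolysis=0.50,
        f_accoa_dilution=0.10,
        w_cit=0.50,
        w_glu_in=0.30,
        w_dil=0.20,
        f_pag=0.20,
        f_glu_from_akg=0.35,
        f_uptake_glu=0.10,
        f_uptake_gln=0.40,
        f_got=0.50,
        f_gs=0.0,
        rho=dict(_CONTROL_RHO),
        n_turns=4,
        pool_sizes=dict(_CONTROL_POOLS),
    )
    if cell_type == "astrocyte":
        params = replace(params, f_gs=0.25, f_uptake_glu=0.40, f_pag=0.10)
    return params


def ftd3_flux_params(cell_type: str = "neuron") -> FluxParameterSet:
    """Disease-like preset (directions only; not fitted values)."""
    params = FluxParameterSet(
        f_glycolysis=0.40,
        f_accoa_dilution=0.10,
        w_cit=0.62,
        w_glu_in=0.15,
        w_dil=0.23,
        f_pag=0.40,
        f_glu_from_akg=0.50,
        f_uptake_glu=0.10,
        f_uptake_gln=0.40,
        f_got=0.50,
        f_gs=0.0,
        rho=dict(_FTD3_RHO),
        n_turns=4,
        pool_sizes=dict(_FTD3_POOLS),
    )
    if cell_type == "astrocyte":
        # astrocytes: glutamate uptake and GS conversion both elevated,
        # direct glutamate oxidation largely maintained
        params = replace(
            params,
            f_gs=0.35,
            f_uptake_glu=0.50,
            f_pag=0.10,
            f_glu_from_akg=0.30,
            w_glu_in=0.30,
            w_dil=0.08,
        )
    return params


def control_bioenergetics(wells: int = 6) -> BioenergeticParams:
    """Control traces: coupling efficiency 77.9%, basal ECAR 3x non-glycolytic."""
    return BioenergeticParams(
        basal_ocr=100.0,
        nonmito_ocr=10.0,
        atp_linked_fraction=0.779,
        basal_ecar=30.0,
        nonglycolytic_ecar=10.0,
        wells=wells,
    )


def ftd3_bioenergetics(wells: int = 6) -> BioenergeticParams:
    """Disease traces: coupling efficiency 70.9%, reduced basal ECAR."""
    return BioenergeticParams(
        basal_ocr=70.0,
        nonmito_ocr=10.0,
        atp_linked_fraction=0.709,
        basal_ecar=20.0,
        nonglycolytic_ecar=10.0,
        wells=wells,
    )


def neuron_tracer_panel(purity: float = 0.99) -> list[TracerConfig]:
    """The three incubation conditions of the neuronal mapping experiment."""
    return [glucose_tracer(purity=purity), glutamine_tracer(purity=purity), glutamate_tracer(purity=purity)]


def default_cohort_design(
    n_replicates: int = 6,
    lines_per_group: int = 3,
    null: bool = False,
    cell_type: str = "neuron",
    tracers: list[TracerConfig] | None = None,
) -> CohortDesign:
    """Three patient lines vs three isogenic controls (or a null cohort).

    With ``null=True`` both groups receive the control preset, which is the
    layout used for false-positive calibration.
    """
    control = control_flux_params(cell_type)
    disease = control if null else ftd3_flux_params(cell_type)
    lines = []
    for i in range(1, lines_per_group + 1):
        lines.append((f"P{i}", "FTD3", disease))
        lines.append((f"C{i}", "isogenic_control", control))
    return CohortDesign(
        lines=lines,
        n_replicates=n_replicates,
        tracers=tracers if tracers is not None else neuron_tracer_panel(),
    )
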