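"""End-to-end orchestration: simulate -> correct -> enrich -> analyze -> test.

``run_pipeline`` executes the full study on synthetic data and
``signature_report`` condenses the statistics into the eight-point
metabolic signature of the disease phenotype:

1. lactate M+3 labeling decreased (glucose tracer),
2. TCA cycling ratios increased (glutamate, fumarate, malate),
3. glutamine-derived second-species enrichment increased (glutamine tracer),
4. glutamate M+5 unchanged (glutamate tracer -- transport intact),
5. glutamate-derived M+4 decreased (glutamate tracer -- metabolism down),
6. glutamine pool decreased,
7. mitochondrial coupling efficiency decreased,
8. normalized basal ECAR decreased.

Difference flags require an adjusted p below alpha *and* the expected
direction; the "unchanged" flag requires an adjusted p at or above alpha.
Every flag is backed by the comparison row(s) it was derived from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bioenergetics import analyze_traces
from .correction import correct_dataset
from .enrichment import (
    CYCLING_METABOLITES,
    cycling_ratio_table,
    labeling_table,
    quantify_pools,
)
from .instruments import simulate_amino_pools, simulate_flux_traces
from .measure import NoiseModel, simulate_cohort
from .presets import (
    control_bioenergetics,
    default_cohort_design,
    ftd3_bioenergetics,
)
from .stats import multiple_t_tests

__all__ = ["ResultsBundle", "SignatureReport", "signature_report", "run_pipeline", "PipelineResult"]

GROUP_DISEASE = "FTD3"
GROUP_CONTROL = "isogenic_control"

#: (metabolite, isotopologue) families tested per tracer condition.
GLUCOSE_FAMILY = [
    ("lactate", 3),
    ("alanine", 3),
    ("akg", 2),
    ("succinate", 2),
    ("glutamate", 2),
    ("aspartate", 2),
]
GLUTAMINE_FAMILY = [
    ("glutamate", 5),
    ("akg", 5),
    ("succinate", 4),
    ("fumarate", 4),
    ("malate", 4),
    ("aspartate", 4),
]
GLUTAMATE_FAMILY = [
    ("glutamate", 5),
    ("succinate", 4),
    ("fumarate", 4),
    ("malate", 4),
    ("aspartate", 4),
]
#: members of the glutamine family that define "second-species enrichment up"
GLUTAMINE_DERIVED = [("malate", 4), ("aspartate", 4)]
#: members of the glutamate family that define "direct metabolism down"
GLUTAMATE_DERIVED = [("fumarate", 4), ("malate", 4), ("aspartate", 4)]


@dataclass
class ResultsBundle:
    """Analysis-stage outputs feeding the signature report."""

    labeling: pd.DataFrame  # group, line, tracer, metabolite, isotopologue, replicate, value
    cycling: pd.DataFrame  # group, line, tracer, metabolite, replicate, value
    pools: pd.DataFrame | None = None  # group, line, replicate, analyte, amount_nmol_mg
    bioenergetics: pd.DataFrame | None = None  # group, well, coupling..., basal_ecar_pct...


@dataclass
class SignatureReport:
    """Boolean signature flags, each backed by its comparison rows."""

    flags: dict[str, bool | None]
    comparisons: dict[str, pd.DataFrame]
    alpha: float

    @property
    def n_true(self) -> int:
        return sum(1 for v in self.flags.values() if v is True)

    def difference_flags(self) -> dict[str, bool | None]:
        return {k: v for k, v in self.flags.items() if k != "glutamate_m5_unchanged"}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"flag": k, "value": v, "evaluable": v is not None} for k, v in self.flags.items()]
        )

    def text(self) -> str:
        lines = [f"Disease-signature report (alpha = {self.alpha})", "-" * 44]
        for k, v in self.flags.items():
            mark = "not evaluable" if v is None else ("YES" if v else "no")
            lines.append(f"  {k:32s} {mark}")
        lines.append(f"  {self.n_true}/{len(self.flags)} flags present")
        return "\n".join(lines)


def _family_tests(labeling, tracer, family, alpha):
    sub = labeling[labeling["tracer"] == tracer]
    if sub.empty:
        return None
    mask = pd.Series(False, index=sub.index)
    for met, iso in family:
        mask |= (sub["metabolite"] == met) & (sub["isotopologue"] == iso)
    sub = sub[mask]
    if sub.empty:
        return None
    return multiple_t_tests(
        sub,
        value="value",
        group="group",
        groups=(GROUP_DISEASE, GROUP_CONTROL),
        strata=["metabolite", "isotopologue"],
        alpha=alpha,
    )


def _row(tests, met, iso=None):
    if tests is None:
        return None
    sel = tests["metabolite"] == met
    if iso is not None:
        sel &= tests["isotopologue"] == iso
    rows = tests[sel]
    return None if rows.empty else rows.iloc[0]


def _down(row) -> bool | None:
    return None if row is None else bool(row["significant"] and row["direction"] == "a<b")


def _up(row) -> bool | None:
    return None if row is None else bool(row["significant"] and row["direction"] == "a>b")


def signature_report(bundle: ResultsBundle, alpha: float = 0.05) -> SignatureReport:
    """Evaluate the eight signature flags from a results bundle.

    Families are Bonferroni-Dunn corrected per tracer condition (and per
    assay for pools and bioenergetic metrics); a flag spanning several
    strata requires every member stratum to agree.  Missing assays or
    tracer conditions yield ``None`` (not evaluable) flags.
    """
    flags: dict[str, bool | None] = {}
    comps: dict[str, pd.DataFrame] = {}

    glc = _family_tests(bundle.labeling, "U13C_glucose", GLUCOSE_FAMILY, alpha)
    if glc is not None:
        comps["glucose_labeling"] = glc
    flags["lactate_m3_down"] = _down(_row(glc, "lactate", 3))

    cyc = bundle.cycling
    cyc_tests = None
    if cyc is not None and not cyc.empty:
        sub = cyc[(cyc["tracer"] == "U13C_glucose") & cyc["metabolite"].isin(CYCLING_METABOLITES)]
        if not sub.empty:
            cyc_tests = multiple_t_tests(
                sub,
                value="value",
                groups=(GROUP_DISEASE, GROUP_CONTROL),
                strata=["metabolite"],
                alpha=alpha,
            )
            comps["cycling_ratios"] = cyc_tests
    if cyc_tests is None:
        flags["cycling_ratios_up"] = None
    else:
        members = [_up(_row(cyc_tests, m)) for m in CYCLING_METABOLITES]
        flags["cycling_ratios_up"] = None if any(v is None for v in members) else all(members)

    gln = _family_tests(bundle.labeling, "U13C_glutamine", GLUTAMINE_FAMILY, alpha)
    if gln is not None:
        comps["glutamine_labeling"] = gln
    members = [_up(_row(gln, met, iso)) for met, iso in GLUTAMINE_DERIVED]
    flags["glutamine_derived_enrichment_up"] = (
        None if any(v is None for v in members) else all(members)
    )

    glu = _family_tests(bundle.labeling, "U13C_glutamate", GLUTAMATE_FAMILY, alpha)
    if glu is not None:
        comps["glutamate_labeling"] = glu
    row = _row(glu, "glutamate", 5)
    flags["glutamate_m5_unchanged"] = None if row is None else bool(not row["significant"])
    members = [_down(_row(glu, met, iso)) for met, iso in GLUTAMATE_DERIVED]
    flags["glutamate_derived_m4_down"] = (
        None if any(v is None for v in members) else all(members)
    )

    if bundle.pools is not None and not bundle.pools.empty:
        pool_tests = multiple_t_tests(
            bundle.pools[bundle.pools["analyte"].isin(["glutamine", "glutamate"])],
            value="amount_nmol_mg",
            groups=(GROUP_DISEASE, GROUP_CONTROL),
            strata=["analyte"],
            alpha=alpha,
        )
        comps["amino_pools"] = pool_tests
        flags["glutamine_pool_down"] = _down(_row(pool_tests.rename(columns={"analyte": "metabolite"}), "glutamine"))
    else:
        flags["glutamine_pool_down"] = None

    if bundle.bioenergetics is not None and not bundle.bioenergetics.empty:
        melted = bundle.bioenergetics.melt(
            id_vars=["group", "well"],
            value_vars=["coupling_efficiency_pct", "basal_ecar_pct_nonglycolytic"],
            var_name="metric",
            value_name="value",
        )
        bio_tests = multiple_t_tests(
            melted,
            value="value",
            groups=(GROUP_DISEASE, GROUP_CONTROL),
            strata=["metric"],
            alpha=alpha,
        )
        comps["bioenergetics"] = bio_tests
        bt = bio_tests.rename(columns={"metric": "metabolite"})
        flags["coupling_efficiency_down"] = _down(_row(bt, "coupling_efficiency_pct"))
        flags["ecar_down"] = _down(_row(bt, "basal_ecar_pct_nonglycolytic"))
    else:
        flags["coupling_efficiency_down"] = None
        flags["ecar_down"] = None

    return SignatureReport(flags=flags, comparisons=comps, alpha=alpha)


@dataclass
class PipelineResult:
    """Everything one pipeline run produced."""

    cohort: dict[str, pd.DataFrame]
    corrected: pd.DataFrame
    bundle: ResultsBundle
    report: SignatureReport
    seed: int


def run_pipeline(
    seed: int = 0,
    n_replicates: int = 6,
    lines_per_group: int = 3,
    cv: float = 0.05,
    null: bool = False,
    correction_mode: str = "empirical_standard",
    correction_method: str = "nnls",
    alpha: float = 0.05,
    wells_per_group: int = 12,
) -> PipelineResult:
    """Simulate the cohort and run every analysis stage.

    With ``null=True`` both groups use the control presets everywhere
    (labeling, pools and bioenergetics), the layout for false-positive
    checks.  All randomness derives from ``seed``.
    """
    design = default_cohort_design(
        n_replicates=n_replicates, lines_per_group=lines_per_group, null=null
    )
    noise = NoiseModel(cv_multiplicative=cv, seed=seed)
    cohort = simulate_cohort(design, noise)
    corrected = correct_dataset(
        cohort["samples"], cohort["standards"], mode=correction_mode, method=correction_method
    )
    labeling = labeling_table(corrected)
    cycling = cycling_ratio_table(corrected)

    rng = np.random.default_rng([seed, 17])
    pools_raw, pool_standards = simulate_amino_pools(design, noise, rng=rng)
    pools = quantify_pools(pools_raw, pool_standards)

    bio_frames = []
    for grp, params in (
        (GROUP_CONTROL, control_bioenergetics(wells_per_group)),
        (GROUP_DISEASE, control_bioenergetics(wells_per_group) if null else ftd3_bioenergetics(wells_per_group)),
    ):
        traces = simulate_flux_traces(params, NoiseModel(cv, seed=seed), rng=rng, well_prefix=grp[:1])
        metrics = analyze_traces(traces)
        metrics.insert(0, "group", grp)
        bio_frames.append(metrics)
    bioenergetics = pd.concat(bio_frames, ignore_index=True)

    bundle = ResultsBundle(
        labeling=labeling, cycling=cycling, pools=pools, bioenergetics=bioenergetics
    )
    report = signature_report(bundle, alpha=alpha)
    return PipelineResult(
        cohort=cohort, corrected=corrected, bundle=bundle, report=report, seed=seed
    )
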