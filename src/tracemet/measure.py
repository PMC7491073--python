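"""Forward measurement model and cohort-level dataset generation.

The simulator's true MIDs are turned into GC-MS-like observations by
convolving with the natural-abundance envelope, scaling by pool size, and
applying multiplicative lognormal noise with an optional additive baseline
-- the forward model that the correction module inverts.  Matching
unlabeled-standard tables are emitted through the same forward model so
that the empirical correction route can be exercised end to end.

``simulate_cohort`` assembles the full study layout: patient-derived lines
versus isogenic control lines, each with its own flux-parameter set,
measured under up to three tracer conditions with replicate cultures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correction import P13_NATURAL, CorrectionMatrix, correction_matrix_theoretical
from .network import METABOLITES
from .propagate import FluxParameterSet, TracerConfig, simulate_experiment

__all__ = [
    "NoiseModel",
    "CohortDesign",
    "ObservedDataset",
    "apply_measurement_model",
    "simulate_cohort",
    "MEASURED_METABOLITES",
]

#: Metabolites reported by the GC-MS assay (the measured subset of pools).
MEASURED_METABOLITES = (
    "lactate",
    "alanine",
    "akg",
    "succinate",
    "fumarate",
    "malate",
    "aspartate",
    "glutamate",
    "glutamine",
)

N_STANDARD_REPLICATES = 3


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal noise (unit mean) plus an additive floor.

    ``cv_multiplicative`` is the coefficient of variation of the lognormal
    factor; ``additive_floor`` is the SD of a zero-mean Gaussian baseline
    added per channel.  Observed intensities are truncated at zero.
    """

    cv_multiplicative: float = 0.05
    additive_floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_multiplicative < 0:
            raise ValueError("cv must be >= 0")
        if self.additive_floor < 0:
            raise ValueError("additive floor must be >= 0")

    def lognormal_factors(self, rng: np.random.Generator, shape) -> np.ndarray:
        if self.cv_multiplicative == 0:
            return np.ones(shape)
        sigma = np.sqrt(np.log1p(self.cv_multiplicative**2))
        return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=shape)


@dataclass
class ObservedDataset:
    """Tidy observed abundances plus the matching unlabeled standards."""

    samples: pd.DataFrame
    standards: pd.DataFrame


@dataclass
class CohortDesign:
    """Study layout: (line_id, group, parameters) plus replication."""

    lines: list[tuple[str, str, FluxParameterSet]]
    n_replicates: int = 6
    tracers: list[TracerConfig] = field(default_factory=list)

    def __post_init__(self) -> None:
        groups = {g for _, g, _ in self.lines}
        if len(groups) < 1 or any(
            sum(1 for _, g, _ in self.lines if g == grp) < 1 for grp in groups
        ):
            raise ValueError("need at least one line per group")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        ids = [line_id for line_id, _, _ in self.lines]
        if len(set(ids)) != len(ids):
            raise ValueError("line ids must be unique")


def _default_matrices(metabolites) -> dict[str, CorrectionMatrix]:
    return {m: correction_matrix_theoretical(m, p13=P13_NATURAL) for m in metabolites}


def _observe(
    true_mid: np.ndarray,
    matrix: np.ndarray,
    pool_size: float,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> np.ndarray:
    expected = (matrix @ true_mid) * pool_size
    obs = expected * noise.lognormal_factors(rng, expected.shape)
    if noise.additive_floor > 0:
        obs = obs + rng.normal(0.0, noise.additive_floor, size=obs.shape)
    return np.clip(obs, 0.0, None)


def apply_measurement_model(
    true_mids: dict[str, np.ndarray],
    pool_sizes: dict[str, float],
    noise: NoiseModel,
    nat_abund_matrices: dict[str, CorrectionMatrix] | None = None,
    n_replicates: int = 6,
    rng: np.random.Generator | None = None,
    metabolites=MEASURED_METABOLITES,
) -> ObservedDataset:
    """Generate replicate observed-abundance vectors for one condition.

    Per replicate and metabolite: ``obs = (C @ mid) * pool * lognormal(cv)
    + floor``, truncated at zero.  The standards table contains the same
    forward model applied to a pure M+0 species.  Reproducible given the
    noise seed (or an explicit generator).
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    matrices = nat_abund_matrices or _default_matrices(metabolites)
    sample_rows, standard_rows = [], []
    for met_name in metabolites:
        n = METABOLITES[met_name].n_carbons
        mid = np.asarray(true_mids[met_name], dtype=float)
        if mid.size != n + 1:
            raise ValueError(f"{met_name}: MID has {mid.size} entries, expected {n + 1}")
        pool = pool_sizes.get(met_name, 1.0)
        if pool < 0:
            raise ValueError(f"{met_name}: negative pool size")
        cm = matrices[met_name]
        matrix = cm.matrix if isinstance(cm, CorrectionMatrix) else np.asarray(cm)
        if matrix.shape != (n + 1, n + 1):
            raise ValueError(f"{met_name}: matrix shape {matrix.shape} does not match carbons")
        for rep in range(1, n_replicates + 1):
            obs = _observe(mid, matrix, pool, noise, rng)
            sample_rows += [
                {"metabolite": met_name, "isotopologue": iso, "replicate": rep, "abundance": v}
                for iso, v in enumerate(obs)
            ]
        unlabeled = np.zeros(n + 1)
        unlabeled[0] = 1.0
        for rep in range(1, N_STANDARD_REPLICATES + 1):
            obs = _observe(unlabeled, matrix, pool if pool > 0 else 1.0, noise, rng)
            standard_rows += [
                {"metabolite": met_name, "isotopologue": iso, "replicate": rep, "abundance": v}
                for iso, v in enumerate(obs)
            ]
    return ObservedDataset(pd.DataFrame(sample_rows), pd.DataFrame(standard_rows))


def simulate_cohort(
    design: CohortDesign,
    noise: NoiseModel,
    nat_abund_matrices: dict[str, CorrectionMatrix] | None = None,
    metabolites=MEASURED_METABOLITES,
) -> dict[str, pd.DataFrame]:
    """Simulate the full cohort; returns tidy ``samples``/``standards``/
    ``pool_sizes`` tables.

    ``samples`` columns: group, line, tracer, metabolite, isotopologue,
    replicate, abundance.  One shared standards table is emitted (the
    unlabeled standards characterize the instrument, not a cell line).
    """
    if not design.tracers:
        raise ValueError("cohort design lists no tracer conditions")
    rng = np.random.default_rng(noise.seed)
    matrices = nat_abund_matrices or _default_matrices(metabolites)
    sample_frames = []
    pool_rows = []
    for line_id, group, params in design.lines:
        for met_name in metabolites:
            pool_rows.append(
                {
                    "group": group,
                    "line": line_id,
                    "metabolite": met_name,
                    "pool_nmol_mg": params.pool_size(met_name),
                }
            )
        for tracer in design.tracers:
            true_mids = simulate_experiment(tracer, params)
            ds = apply_measurement_model(
                true_mids,
                {m: params.pool_size(m) for m in metabolites},
                noise,
                nat_abund_matrices=matrices,
                n_replicates=design.n_replicates,
                rng=rng,
                metabolites=metabolites,
            )
            df = ds.samples
            df.insert(0, "tracer", tracer.tracer)
            df.insert(0, "line", line_id)
            df.insert(0, "group", group)
            sample_frames.append(df)
    # standards generated once, after the cohort, from the same stream
    first_params = design.lines[0][2]
    standards = apply_measurement_model(
        {m: np.eye(METABOLITES[m].n_carbons + 1)[0] for m in metabolites},
        {m: first_params.pool_size(m) for m in metabolites},
        noise,
        nat_abund_matrices=matrices,
        n_replicates=1,
        rng=rng,
        metabolites=metabolites,
    ).standards
    return {
        "samples": pd.concat(sample_frames, ignore_index=True),
        "standards": standards,
        "pool_sizes": pd.DataFrame(pool_rows),
    }
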