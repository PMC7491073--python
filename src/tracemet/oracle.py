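"""Independent oracles for the turn-propagation model.

Two alternative routes to the same mass-isotopologue distributions:

* an exhaustive enumeration over all source-combination labeling paths,
  written with explicit per-carbon tuple masks and dictionary arithmetic
  (no shared code with the vectorized propagation engine), and
* a seeded Monte Carlo sampler that follows individual molecules through
  the network and reports binomial standard errors of the sampled
  fractions.

The enumeration is guarded to ``n_turns <= 4`` (the distributions are small
but the dictionary arithmetic is deliberately naive); beyond the guard the
Monte Carlo mode must be requested explicitly.
"""

from __future__ import annotations

import itertools
from collections import defaultdict

import numpy as np

from .network import METABOLITES
from .propagate import POOL_NAMES, FluxParameterSet, TracerConfig

__all__ = ["enumerate_oracle", "monte_carlo_oracle"]

Mask = tuple[int, ...]
Dist = dict[Mask, float]


def _unlabeled(n: int) -> Dist:
    return {(0,) * n: 1.0}


def _fully_labeled(n: int, purity: float) -> Dist:
    d: Dist = defaultdict(float)
    d[(0,) * n] += 1.0 - purity
    d[(1,) * n] += purity
    return dict(d)


def _sources(config: TracerConfig) -> dict[str, Dist]:
    p = config.tracer_purity
    return {
        "glucose": _fully_labeled(6, p) if config.tracer == "U13C_glucose" else _unlabeled(6),
        "medium_glutamine": _fully_labeled(5, p) if config.tracer == "U13C_glutamine" else _unlabeled(5),
        "medium_glutamate": _fully_labeled(5, p) if config.tracer == "U13C_glutamate" else _unlabeled(5),
    }


def _pick(mask: Mask, carbons: tuple[int, ...]) -> Mask:
    return tuple(mask[c] for c in carbons)


def _map_one(dist: Dist, carbons: tuple[int, ...]) -> Dist:
    out: Dist = defaultdict(float)
    for mask, p in dist.items():
        out[_pick(mask, carbons)] += p
    return dict(out)


def _condense(a: Dist, b: Dist) -> Dist:
    out: Dist = defaultdict(float)
    for (ma, pa), (mb, pb) in itertools.product(a.items(), b.items()):
        out[ma + mb] += pa * pb
    return dict(out)


def _scramble(dist: Dist) -> Dist:
    out: Dist = defaultdict(float)
    for mask, p in dist.items():
        out[mask] += 0.5 * p
        out[mask[::-1]] += 0.5 * p
    return dict(out)


def _blend(parts: list[tuple[float, Dist]], n: int) -> Dist:
    """Convex mixture; any missing weight is unlabeled dilution."""
    total = sum(w for w, _ in parts)
    if total < 1.0 - 1e-9:
        parts = parts + [(1.0 - total, _unlabeled(n))]
    out: Dist = defaultdict(float)
    for w, d in parts:
        for mask, p in d.items():
            out[mask] += w * p
    return dict(out)


def _retain(old: Dist, inflow: Dist, rho: float) -> Dist:
    out: Dist = defaultdict(float)
    for mask, p in old.items():
        out[mask] += rho * p
    for mask, p in inflow.items():
        out[mask] += (1.0 - rho) * p
    return dict(out)


def _enumerate_turn(
    state: dict[str, Dist], params: FluxParameterSet, config: TracerConfig
) -> dict[str, Dist]:
    src = _sources(config)
    rho = params.rho_for
    new = dict(state)

    glc_top = _map_one(src["glucose"], (2, 1, 0))
    glc_bot = _map_one(src["glucose"], (3, 4, 5))
    pyr_in = _blend(
        [(params.f_glycolysis * 0.5, glc_top), (params.f_glycolysis * 0.5, glc_bot)], 3
    )
    new["pyruvate"] = _retain(state["pyruvate"], pyr_in, rho("pyruvate"))
    new["lactate"] = _retain(state["lactate"], _map_one(new["pyruvate"], (0, 1, 2)), rho("lactate"))
    new["alanine"] = _retain(state["alanine"], _map_one(new["pyruvate"], (0, 1, 2)), rho("alanine"))

    ac_in = _blend([(1.0 - params.f_accoa_dilution, _map_one(new["pyruvate"], (1, 2)))], 2)
    new["accoa"] = _retain(state["accoa"], ac_in, rho("accoa"))

    cit_in = _condense(state["oaa"], new["accoa"])
    new["citrate"] = _retain(state["citrate"], cit_in, rho("citrate"))

    akg_in = _blend(
        [
            (params.w_cit, _map_one(new["citrate"], (0, 1, 2, 4, 5))),
            (params.w_glu_in, state["glutamate"]),
        ],
        5,
    )
    new["akg"] = _retain(state["akg"], akg_in, rho("akg"))

    gln_in = _blend(
        [(params.f_uptake_gln, src["medium_glutamine"]), (params.f_gs, state["glutamate"])], 5
    )
    new["glutamine"] = _retain(state["glutamine"], gln_in, rho("glutamine"))

    glu_in = _blend(
        [
            (params.f_glu_from_akg, new["akg"]),
            (params.f_pag, new["glutamine"]),
            (params.f_uptake_glu, src["medium_glutamate"]),
        ],
        5,
    )
    new["glutamate"] = _retain(state["glutamate"], glu_in, rho("glutamate"))

    new["succinate"] = _retain(
        state["succinate"], _map_one(new["akg"], (1, 2, 3, 4)), rho("succinate")
    )
    new["fumarate"] = _retain(
        state["fumarate"], _scramble(new["succinate"]), rho("fumarate")
    )
    new["malate"] = _retain(state["malate"], _scramble(new["fumarate"]), rho("malate"))
    new["oaa"] = _retain(state["oaa"], new["malate"], rho("oaa"))

    f = params.f_got
    oaa_snap, asp_snap = new["oaa"], state["aspartate"]
    new["aspartate"] = _blend([(1.0 - f, asp_snap), (f, oaa_snap)], 4)
    new["oaa"] = _blend([(1.0 - f, oaa_snap), (f, asp_snap)], 4)
    return new


def _dist_to_mid(dist: Dist, n: int) -> np.ndarray:
    mid = np.zeros(n + 1)
    for mask, p in dist.items():
        mid[sum(mask)] += p
    return mid


def enumerate_oracle(
    config: TracerConfig,
    params: FluxParameterSet,
    monte_carlo: bool = False,
    n_molecules: int = 100_000,
    seed: int = 0,
):
    """Recompute every pool's MID by explicit path enumeration.

    With ``monte_carlo=True`` returns ``{pool: (mid, se)}`` from molecule
    sampling instead (required above the ``n_turns <= 4`` enumeration
    guard); otherwise returns ``{pool: mid}``.
    """
    if monte_carlo:
        return monte_carlo_oracle(config, params, n_molecules=n_molecules, seed=seed)
    if params.n_turns > 4:
        raise ValueError(
            "exhaustive enumeration is guarded to n_turns <= 4; use monte_carlo=True"
        )
    state: dict[str, Dist] = {
        name: _unlabeled(METABOLITES[name].n_carbons) for name in POOL_NAMES
    }
    for _ in range(params.n_turns):
        state = _enumerate_turn(state, params, config)
    return {
        name: _dist_to_mid(dist, METABOLITES[name].n_carbons)
        for name, dist in state.items()
    }


def _sample_source(n: int, labeled: bool, purity: float, rng, size: int) -> np.ndarray:
    if not labeled:
        return np.zeros(size, dtype=np.int64)
    full = (1 << n) - 1
    return np.where(rng.random(size) < purity, full, 0).astype(np.int64)


def _gather(masks: np.ndarray, carbons: tuple[int, ...]) -> np.ndarray:
    out = np.zeros_like(masks)
    for j, c in enumerate(carbons):
        out |= ((masks >> c) & 1) << j
    return out


def _reverse_bits(masks: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros_like(masks)
    for b in range(n):
        out |= ((masks >> b) & 1) << (n - 1 - b)
    return out


def monte_carlo_oracle(
    config: TracerConfig,
    params: FluxParameterSet,
    n_molecules: int = 100_000,
    seed: int = 0,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Molecule-level sampling oracle: ``{pool: (mid, standard_error)}``.

    Each turn draws, for every pool, ``n_molecules`` new molecules: with
    probability rho a resampled survivor of the old pool, otherwise a
    molecule built from sampled source molecules through the atom maps
    (symmetric steps flip orientation with probability 1/2).  Standard
    errors are the binomial SE of each sampled MID fraction.
    """
    rng = np.random.default_rng(seed)
    N = int(n_molecules)
    purity = config.tracer_purity
    labeled_src = {
        "glucose": config.tracer == "U13C_glucose",
        "medium_glutamine": config.tracer == "U13C_glutamine",
        "medium_glutamate": config.tracer == "U13C_glutamate",
    }

    state = {name: np.zeros(N, dtype=np.int64) for name in POOL_NAMES}

    def resample(arr: np.ndarray) -> np.ndarray:
        return arr[rng.integers(0, N, N)]

    def retained_or(pool: str, inflow: np.ndarray) -> np.ndarray:
        keep = rng.random(N) < params.rho_for(pool)
        return np.where(keep, resample(state[pool]), inflow)

    def choose(options: list[tuple[float, np.ndarray]]) -> np.ndarray:
        """Pick each molecule's provenance; missing weight = unlabeled."""
        weights = [w for w, _ in options]
        rest = 1.0 - sum(weights)
        u = rng.random(N)
        out = np.zeros(N, dtype=np.int64)
        lo = 0.0
        for w, arr in options:
            sel = (u >= lo) & (u < lo + w)
            out[sel] = arr[sel]
            lo += w
        if rest > 1e-12:
            out[u >= lo] = 0
        return out

    for _ in range(params.n_turns):
        new = dict(state)
        glc = _sample_source(6, labeled_src["glucose"], purity, rng, N)
        half = rng.random(N) < 0.5
        pyr_from_glc = np.where(half, _gather(glc, (2, 1, 0)), _gather(glc, (3, 4, 5)))
        new["pyruvate"] = retained_or(
            "pyruvate", choose([(params.f_glycolysis, pyr_from_glc)])
        )
        new["lactate"] = retained_or("lactate", resample(new["pyruvate"]))
        new["alanine"] = retained_or("alanine", resample(new["pyruvate"]))
        ac = _gather(resample(new["pyruvate"]), (1, 2))
        new["accoa"] = retained_or("accoa", choose([(1.0 - params.f_accoa_dilution, ac)]))
        cit = resample(state["oaa"]) | (resample(new["accoa"]) << 4)
        new["citrate"] = retained_or("citrate", cit)
        akg_cit = _gather(resample(new["citrate"]), (0, 1, 2, 4, 5))
        new["akg"] = retained_or(
            "akg",
            choose([(params.w_cit, akg_cit), (params.w_glu_in, resample(state["glutamate"]))]),
        )
        gln_med = _sample_source(5, labeled_src["medium_glutamine"], purity, rng, N)
        new["glutamine"] = retained_or(
            "glutamine",
            choose([(params.f_uptake_gln, gln_med), (params.f_gs, resample(state["glutamate"]))]),
        )
        glu_med = _sample_source(5, labeled_src["medium_glutamate"], purity, rng, N)
        new["glutamate"] = retained_or(
            "glutamate",
            choose(
                [
                    (params.f_glu_from_akg, resample(new["akg"])),
                    (params.f_pag, resample(new["glutamine"])),
                    (params.f_uptake_glu, glu_med),
                ]
            ),
        )
        suc = _gather(resample(new["akg"]), (1, 2, 3, 4))
        new["succinate"] = retained_or("succinate", suc)
        fum = resample(new["succinate"])
        flip = rng.random(N) < 0.5
        fum = np.where(flip, _reverse_bits(fum, 4), fum)
        new["fumarate"] = retained_or("fumarate", fum)
        mal = resample(new["fumarate"])
        flip = rng.random(N) < 0.5
        mal = np.where(flip, _reverse_bits(mal, 4), mal)
        new["malate"] = retained_or("malate", mal)
        new["oaa"] = retained_or("oaa", resample(new["malate"]))
        oaa_snap = new["oaa"]
        asp_snap = state["aspartate"]
        swap = rng.random(N) < params.f_got
        new["aspartate"] = np.where(swap, resample(oaa_snap), resample(asp_snap))
        swap = rng.random(N) < params.f_got
        new["oaa"] = np.where(swap, resample(asp_snap), resample(oaa_snap))
        state = new

    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, masks in state.items():
        n = METABOLITES[name].n_carbons
        counts = np.zeros(N, dtype=np.int64)
        for b in range(n):
            counts += (masks >> b) & 1
        mid = np.bincount(counts, minlength=n + 1) / N
        se = np.sqrt(mid * (1.0 - mid) / N)
        out[name] = (mid, se)
    return out
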