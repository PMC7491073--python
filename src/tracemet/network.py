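"""Carbon-skeleton network for positional ¹³C-isotopomer propagation.

Every metabolite pool is represented as a probability distribution over
*positional* labeling states, encoded as carbon bitmasks: for an n-carbon
metabolite the state space is the 2**n masks in which bit ``i`` set means
carbon C(i+1) carries a ¹³C atom.  Positional states (rather than mass-only
M+X states) are required because decarboxylation steps remove a *specific*
carbon and because succinate and fumarate are symmetric molecules whose
orientation is scrambled by the enzymes acting on them -- both effects make
mass-only propagation incorrect.

The module also defines the fixed atom-transition maps of the network:
glycolysis (glucose -> 2 pyruvate), pyruvate fates (lactate, alanine,
acetyl-CoA + CO2), the TCA cycle (citrate synthase condensation, the two
oxidative decarboxylations, the symmetric succinate/fumarate steps) and the
amino-acid exchanges (OAA<->aspartate via GOT/AAT, glutamate<->alpha-
ketoglutarate via GDH/AAT, glutamine<->glutamate via PAG/GS).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "Metabolite",
    "METABOLITES",
    "PositionalState",
    "AtomMap",
    "default_atom_maps",
    "apply_atom_map",
    "unlabeled_distribution",
    "fully_labeled_distribution",
    "distribution_to_mid",
    "expected_labeled_carbons",
    "reverse_permutation",
]


@dataclass(frozen=True)
class Metabolite:
    """A metabolite identified by name with a fixed carbon count."""

    name: str
    n_carbons: int

    def __post_init__(self) -> None:
        if self.n_carbons < 1:
            raise ValueError(f"{self.name}: n_carbons must be >= 1")

    @property
    def n_states(self) -> int:
        return 1 << self.n_carbons


#: The fixed metabolite set of the network (carbon counts as in the pathway).
METABOLITES: dict[str, Metabolite] = {
    m.name: m
    for m in [
        Metabolite("glucose", 6),
        Metabolite("pyruvate", 3),
        Metabolite("lactate", 3),
        Metabolite("alanine", 3),
        Metabolite("accoa", 2),
        Metabolite("citrate", 6),
        Metabolite("akg", 5),
        Metabolite("succinate", 4),
        Metabolite("fumarate", 4),
        Metabolite("malate", 4),
        Metabolite("oaa", 4),
        Metabolite("aspartate", 4),
        Metabolite("glutamate", 5),
        Metabolite("glutamine", 5),
    ]
}


@lru_cache(maxsize=None)
def _popcounts(n_carbons: int) -> np.ndarray:
    masks = np.arange(1 << n_carbons, dtype=np.int64)
    counts = np.zeros_like(masks)
    for bit in range(n_carbons):
        counts += (masks >> bit) & 1
    return counts


@lru_cache(maxsize=None)
def reverse_permutation(n_carbons: int) -> np.ndarray:
    """Permutation sending each mask to its carbon-order-reversed mask."""
    masks = np.arange(1 << n_carbons, dtype=np.int64)
    out = np.zeros_like(masks)
    for bit in range(n_carbons):
        out |= ((masks >> bit) & 1) << (n_carbons - 1 - bit)
    return out


def unlabeled_distribution(n_carbons: int) -> np.ndarray:
    d = np.zeros(1 << n_carbons)
    d[0] = 1.0
    return d


def fully_labeled_distribution(n_carbons: int, purity: float = 1.0) -> np.ndarray:
    """All-or-nothing labeling: fully ¹³C with probability ``purity``."""
    if not 0.0 <= purity <= 1.0:
        raise ValueError("purity must be in [0, 1]")
    d = np.zeros(1 << n_carbons)
    d[0] = 1.0 - purity
    d[-1] = purity
    return d


def distribution_to_mid(probs: np.ndarray) -> np.ndarray:
    """Marginalize a positional distribution to its M+0..M+n mass distribution."""
    n = int(probs.size).bit_length() - 1
    return np.bincount(_popcounts(n), weights=probs, minlength=n + 1)


def expected_labeled_carbons(probs: np.ndarray) -> float:
    n = int(probs.size).bit_length() - 1
    return float(_popcounts(n) @ probs)


@dataclass
class PositionalState:
    """A metabolite pool: probability distribution over carbon bitmasks."""

    metabolite: Metabolite
    probs: np.ndarray

    @classmethod
    def unlabeled(cls, metabolite: Metabolite) -> "PositionalState":
        return cls(metabolite, unlabeled_distribution(metabolite.n_carbons))

    @classmethod
    def fully_labeled(cls, metabolite: Metabolite, purity: float = 1.0) -> "PositionalState":
        return cls(metabolite, fully_labeled_distribution(metabolite.n_carbons, purity))

    def mid(self) -> np.ndarray:
        return distribution_to_mid(self.probs)

    def validate(self, atol: float = 1e-12) -> None:
        if self.probs.size != self.metabolite.n_states:
            raise ValueError(
                f"{self.metabolite.name}: state has {self.probs.size} entries, "
                f"expected {self.metabolite.n_states}"
            )
        if np.any(self.probs < -atol):
            raise ValueError(f"{self.metabolite.name}: negative probability")
        if abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError(f"{self.metabolite.name}: probabilities do not sum to 1")


@dataclass(frozen=True)
class AtomMap:
    """An atom-level transition: where each destination carbon comes from.

    ``carbon_from[j] = (si, ci)`` assigns destination carbon C(j+1) to carbon
    C(ci+1) of the ``si``-th source.  Carbons lost as CO2 are listed in
    ``co2_from`` so that label is explicitly accounted for.  ``symmetric``
    marks steps acting on a symmetric substrate: the product distribution is
    averaged with its carbon-order reversal (50/50 orientation scrambling).
    """

    name: str
    sources: tuple[str, ...]
    dest: str
    carbon_from: tuple[tuple[int, int], ...]
    co2_from: tuple[tuple[int, int], ...] = ()
    symmetric: bool = False

    def validate(self) -> None:
        n_dest = METABOLITES[self.dest].n_carbons
        if len(self.carbon_from) != n_dest:
            raise ValueError(f"{self.name}: maps {len(self.carbon_from)} carbons, dest has {n_dest}")
        for si, ci in self.carbon_from + self.co2_from:
            if not 0 <= si < len(self.sources):
                raise ValueError(f"{self.name}: bad source index {si}")
            if not 0 <= ci < METABOLITES[self.sources[si]].n_carbons:
                raise ValueError(f"{self.name}: bad carbon index {ci} for {self.sources[si]}")


def _identity(n: int) -> tuple[tuple[int, int], ...]:
    return tuple((0, i) for i in range(n))


def default_atom_maps() -> list[AtomMap]:
    """The fixed transition network.

    Carbon conventions (0-based indices = C1..Cn): glycolysis cleaves glucose
    into two pyruvates, the C1-C2-C3 half in reversed order and the C4-C5-C6
    half in order; pyruvate dehydrogenase releases pyruvate C1 as CO2 and
    passes C2,C3 into the two acetyl-CoA carbons; citrate synthase orders the
    citrate carbons as (o1..o4, a1, a2); the citrate -> alpha-ketoglutarate
    decarboxylation releases the OAA-derived carbon o4 (alpha-KG =
    (o1, o2, o3, a1, a2)) and the alpha-KG -> succinate step releases k1
    (= o1).  Taking the two CO2 from opposite ends of the OAA moiety
    reproduces both canonical patterns: on the first turn [1,2-¹³C]acetyl-
    CoA condensing with unlabeled OAA yields [4,5-¹³C]alpha-KG (M+2) and
    M+2 succinate, and on the second turn a doubly-labeled OAA (either
    scrambling orientation) yields M+3 succinate/fumarate/malate/aspartate
    alongside M+3/M+4 alpha-KG.  Succinate -> fumarate and fumarate ->
    malate are flagged symmetric.
    """
    maps = [
        AtomMap("glycolysis_c123", ("glucose",), "pyruvate", ((0, 2), (0, 1), (0, 0))),
        AtomMap("glycolysis_c456", ("glucose",), "pyruvate", ((0, 3), (0, 4), (0, 5))),
        AtomMap("ldh", ("pyruvate",), "lactate", _identity(3)),
        AtomMap("alat", ("pyruvate",), "alanine", _identity(3)),
        AtomMap("pdh", ("pyruvate",), "accoa", ((0, 1), (0, 2)), co2_from=((0, 0),)),
        AtomMap(
            "citrate_synthase",
            ("oaa", "accoa"),
            "citrate",
            ((0, 0), (0, 1), (0, 2), (0, 3), (1, 0), (1, 1)),
        ),
        AtomMap("idh", ("citrate",), "akg", ((0, 0), (0, 1), (0, 2), (0, 4), (0, 5)), co2_from=((0, 3),)),
        AtomMap("akgdh", ("akg",), "succinate", ((0, 1), (0, 2), (0, 3), (0, 4)), co2_from=((0, 0),)),
        AtomMap("sdh", ("succinate",), "fumarate", _identity(4), symmetric=True),
        AtomMap("fumarase", ("fumarate",), "malate", _identity(4), symmetric=True),
        AtomMap("mdh", ("malate",), "oaa", _identity(4)),
        AtomMap("got_oaa_to_asp", ("oaa",), "aspartate", _identity(4)),
        AtomMap("got_asp_to_oaa", ("aspartate",), "oaa", _identity(4)),
        AtomMap("gdh_glu_to_akg", ("glutamate",), "akg", _identity(5)),
        AtomMap("gdh_akg_to_glu", ("akg",), "glutamate", _identity(5)),
        AtomMap("pag", ("glutamine",), "glutamate", _identity(5)),
        AtomMap("gs", ("glutamate",), "glutamine", _identity(5)),
    ]
    for m in maps:
        m.validate()
    return maps


def apply_atom_map(amap: AtomMap, source_dists: list[np.ndarray]) -> tuple[np.ndarray, float]:
    """Push source mask distributions through an atom map.

    Returns the destination mask distribution and the expected number of
    labeled carbons released as CO2 per converted molecule.  Sources are
    treated as independent (condensation draws one molecule from each pool).
    """
    if len(source_dists) != len(amap.sources):
        raise ValueError(f"{amap.name}: expected {len(amap.sources)} source distributions")
    offsets = [1]
    joint = source_dists[0]
    for d in source_dists[1:]:
        offsets.append(joint.size)
        joint = np.kron(d, joint)  # combined index s = sum_i s_i * offsets[i]
    idx = np.arange(joint.size, dtype=np.int64)
    n_dest = len(amap.carbon_from)
    dest_idx = np.zeros(joint.size, dtype=np.int64)
    for j, (si, ci) in enumerate(amap.carbon_from):
        dest_idx |= (((idx // offsets[si]) >> ci) & 1) << j
    co2_bits = np.zeros(joint.size)
    for si, ci in amap.co2_from:
        co2_bits += ((idx // offsets[si]) >> ci) & 1
    dest = np.bincount(dest_idx, weights=joint, minlength=1 << n_dest)
    co2_labeled = float(joint @ co2_bits)
    if amap.symmetric:
        dest = 0.5 * (dest + dest[reverse_permutation(n_dest)])
    return dest, co2_labeled
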