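"""Natural-abundance correction of measured mass-isotopologue abundances.

GC-MS (and LC-MS) isotopologue intensities are a convolution of the
tracer-derived labeling with the natural heavy-isotope envelope of the
analyte (and, for derivatized analytes, of the derivatization group).  This
module builds the (n+1)x(n+1) correction matrix C whose column j is the
predicted observed mass distribution of a pure M+j species, and inverts
C x = observed under a non-negativity constraint to recover the underlying
mass-isotopologue distribution (MID).

Three matrix modes are provided:

``empirical_standard``
    The envelope measured on an unlabeled standard of the same analyte is
    normalized and used as every column, shifted by j mass units and
    truncated to the n+1 recorded channels.  This assumes the standard's
    envelope is shift-invariant across label states; columns are *not*
    renormalized after truncation, so a column can lose <0.1% of its mass.
``theoretical_carbon``
    Column j is the binomial ¹³C envelope of the n-j unlabeled backbone
    carbons at natural abundance (default p13 = 0.0107).
``theoretical_formula``
    As carbon mode, additionally convolved with the fixed isotope patterns
    of the non-tracer elements of an elemental formula (H, N, O, S, Si and
    any derivatization carbons beyond the backbone).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .network import METABOLITES, Metabolite

__all__ = [
    "P13_NATURAL",
    "CorrectionMatrix",
    "correction_matrix_theoretical",
    "correction_matrix_empirical",
    "correct_mid",
    "correct_dataset",
]

#: Natural ¹³C abundance used throughout unless overridden.
P13_NATURAL = 0.0107

# Mass-shift patterns (abundance at +0, +1, +2) per atom for the elements
# occurring in TBDMS/TMS-derivatized metabolites.
_ISOTOPE_PATTERNS: dict[str, np.ndarray] = {
    "H": np.array([0.999885, 0.000115]),
    "C": np.array([1.0 - P13_NATURAL, P13_NATURAL]),
    "N": np.array([0.99636, 0.00364]),
    "O": np.array([0.99757, 0.00038, 0.00205]),
    "S": np.array([0.9499, 0.0075, 0.0425, 0.0001]),
    "Si": np.array([0.92223, 0.04685, 0.03092]),
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass
class CorrectionMatrix:
    """A correction matrix with its provenance mode."""

    metabolite: Metabolite
    matrix: np.ndarray
    mode: str

    def validate(self) -> None:
        n = self.metabolite.n_carbons
        if self.matrix.shape != (n + 1, n + 1):
            raise ValueError(f"matrix shape {self.matrix.shape}, expected {(n + 1, n + 1)}")
        if np.any(self.matrix < -1e-12):
            raise ValueError("correction matrix has negative entries")
        if np.any(self.matrix.sum(axis=0) > 1.0 + 1e-9):
            raise ValueError("correction matrix column sums exceed 1")


def _resolve(metabolite: Metabolite | str) -> Metabolite:
    if isinstance(metabolite, str):
        try:
            return METABOLITES[metabolite]
        except KeyError:
            raise KeyError(f"unknown metabolite {metabolite!r}") from None
    return metabolite


def parse_formula(formula: str | dict[str, int]) -> dict[str, int]:
    if isinstance(formula, dict):
        return dict(formula)
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos or not m.group(1):
            break
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        pos = m.end()
    if pos != len(formula):
        raise ValueError(f"cannot parse elemental formula {formula!r}")
    return counts


def _binomial_pattern(n_atoms: int, p: float) -> np.ndarray:
    pattern = np.array([1.0])
    one = np.array([1.0 - p, p])
    for _ in range(n_atoms):
        pattern = np.convolve(pattern, one)
    return pattern


def _element_envelope(counts: dict[str, int], skip_carbons: int) -> np.ndarray:
    """Convolved isotope envelope of all non-tracer atoms in a formula."""
    env = np.array([1.0])
    for elem, n_atoms in counts.items():
        if elem == "C":
            n_atoms -= skip_carbons
            if n_atoms < 0:
                raise ValueError("formula has fewer carbons than the metabolite backbone")
        if n_atoms == 0:
            continue
        try:
            pat = _ISOTOPE_PATTERNS[elem]
        except KeyError:
            raise ValueError(f"no isotope pattern for element {elem!r}") from None
        for _ in range(n_atoms):
            env = np.convolve(env, pat)
    return env


def correction_matrix_theoretical(
    metabolite: Metabolite | str,
    p13: float = P13_NATURAL,
    elemental_formula: str | dict[str, int] | None = None,
) -> CorrectionMatrix:
    """Binomial natural-abundance matrix, optionally for a full formula.

    In carbon mode column j is the ¹³C binomial over the n-j carbons that
    are not tracer-labeled, shifted by j.  In formula mode each column is
    additionally convolved with the isotope envelope of the remaining atoms
    (truncated to the n+1 recorded mass channels, without renormalization).
    """
    met = _resolve(metabolite)
    if not 0.0 <= p13 < 0.5:
        raise ValueError("p13 must lie in [0, 0.5)")
    n = met.n_carbons
    envelope = None
    mode = "theoretical_carbon"
    if elemental_formula is not None:
        envelope = _element_envelope(parse_formula(elemental_formula), skip_carbons=n)
        mode = "theoretical_formula"
    C = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        col = _binomial_pattern(n - j, p13)
        if envelope is not None:
            col = np.convolve(col, envelope)
        col = np.concatenate([np.zeros(j), col])[: n + 1]
        C[:, j] = col
    out = CorrectionMatrix(met, C, mode)
    out.validate()
    return out


def correction_matrix_empirical(
    metabolite: Metabolite | str, standard: np.ndarray
) -> CorrectionMatrix:
    """Correction matrix from an unlabeled standard's measured envelope.

    The standard intensities are normalized to a distribution d and column
    j is d shifted down by j mass units, truncated to n+1 channels.
    """
    met = _resolve(metabolite)
    standard = np.asarray(standard, dtype=float)
    if standard.ndim != 1 or standard.size != met.n_carbons + 1:
        raise ValueError(
            f"standard for {met.name} must have {met.n_carbons + 1} channels"
        )
    if np.any(standard < 0):
        raise ValueError("standard intensities must be non-negative")
    total = standard.sum()
    if total <= 0:
        raise ValueError("zero-intensity standard")
    d = standard / total
    n = met.n_carbons
    C = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        C[j:, j] = d[: n + 1 - j]
    out = CorrectionMatrix(met, C, "empirical_standard")
    out.validate()
    return out


def correct_mid(
    obs: np.ndarray, C: CorrectionMatrix | np.ndarray, method: str = "nnls"
) -> tuple[np.ndarray, float]:
    """Invert the natural-abundance convolution.

    Solves ``C x = obs`` for x >= 0 (``nnls``, the default, robust to
    noise-induced negatives) or by direct linear solve with negatives
    clipped to zero (``solve_clip``, matching legacy spreadsheet
    corrections).  Returns the normalized MID and the total corrected
    abundance sum(x), which carries the pool quantity for absolute
    isotopologue amounts.
    """
    matrix = C.matrix if isinstance(C, CorrectionMatrix) else np.asarray(C, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if obs.ndim != 1 or obs.size != matrix.shape[0]:
        raise ValueError(f"observation length {obs.size} does not match matrix {matrix.shape}")
    if obs.sum() <= 0:
        raise ValueError("all-zero observation cannot be corrected")
    if method == "nnls":
        x, _ = scipy.optimize.nnls(matrix, obs)
    elif method == "solve_clip":
        x = np.linalg.solve(matrix, obs)
        x = np.clip(x, 0.0, None)
    else:
        raise ValueError(f"unknown method {method!r}")
    total = float(x.sum())
    if total <= 0:
        raise ValueError("corrected abundances sum to zero")
    return x / total, total


def correct_dataset(
    samples,
    standards=None,
    mode: str = "empirical_standard",
    method: str = "nnls",
    p13: float = P13_NATURAL,
    formulas: dict[str, str] | None = None,
):
    """Correct a tidy observed-abundance table replicate by replicate.

    ``samples`` columns: (group, line, tracer, metabolite, isotopologue,
    replicate, abundance); ``standards`` columns: (metabolite, isotopologue,
    replicate, abundance) -- required for the empirical mode, averaged over
    standard replicates.  Returns a tidy table of corrected fractions plus
    the total corrected abundance per measurement.
    """
    import pandas as pd

    matrices: dict[str, CorrectionMatrix] = {}
    for met_name in samples["metabolite"].unique():
        if mode == "empirical_standard":
            if standards is None:
                raise ValueError("empirical mode requires an unlabeled-standards table")
            sub = standards[standards["metabolite"] == met_name]
            if sub.empty:
                raise ValueError(f"no unlabeled standard for {met_name}")
            vec = (
                sub.groupby("isotopologue")["abundance"].mean().sort_index().to_numpy()
            )
            matrices[met_name] = correction_matrix_empirical(met_name, vec)
        elif mode == "theoretical_carbon":
            matrices[met_name] = correction_matrix_theoretical(met_name, p13=p13)
        elif mode == "theoretical_formula":
            if not formulas or met_name not in formulas:
                raise ValueError(f"formula mode requires an elemental formula for {met_name}")
            matrices[met_name] = correction_matrix_theoretical(
                met_name, p13=p13, elemental_formula=formulas[met_name]
            )
        else:
            raise ValueError(f"unknown correction mode {mode!r}")

    keys = [c for c in ("group", "line", "tracer", "metabolite", "replicate") if c in samples]
    rows = []
    for key_vals, sub in samples.groupby(keys, sort=False):
        met_name = key_vals[keys.index("metabolite")]
        vec = sub.sort_values("isotopologue")["abundance"].to_numpy()
        mid, total = correct_mid(vec, matrices[met_name], method=method)
        base = dict(zip(keys, key_vals))
        for iso, frac in enumerate(mid):
            rows.append({**base, "isotopologue": iso, "fraction": frac, "total_abundance": total})
    return pd.DataFrame(rows)
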