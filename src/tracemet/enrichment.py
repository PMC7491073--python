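"""Labeling statistics computed from corrected MIDs.

Covers the quantities reported by the metabolic-mapping assay: percentage
labeling of each isotopologue, the TCA cycling ratio, absolute
isotopologue amounts from total pool contents, and amino-acid amounts via
linear calibration curves.

The cycling ratio for a metabolite is

    ([M+1] + [M+3] + ... + [M+n]) / [M+2],

the labeling that arises in the second or later turns of the TCA cycle
relative to the first-turn (M+2) labeling -- a dimensionless proxy for
cycle turnover.  The M+1 term is part of the printed formula and is kept
even though a uniformly labeled glucose tracer produces no M+1 on the
first turn; M+0 is excluded.  Ratios are computed per replicate and then
summarized, never on pooled means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "labeling_percent",
    "cycling_ratio",
    "CyclingRatio",
    "absolute_isotopologue_amounts",
    "CalibrationCurve",
    "fit_calibration",
    "quantify",
    "labeling_table",
    "cycling_ratio_table",
    "amounts_table",
    "quantify_pools",
    "CYCLING_METABOLITES",
]

CYCLING_METABOLITES = ("glutamate", "fumarate", "malate")


def labeling_percent(mid: np.ndarray) -> np.ndarray:
    """Percentage labeling of each M+X isotopologue; sums to 100."""
    mid = np.asarray(mid, dtype=float)
    if np.any(mid < -1e-9) or abs(mid.sum() - 1.0) > 1e-6:
        raise ValueError("input is not a normalized MID")
    return 100.0 * mid


@dataclass(frozen=True)
class CyclingRatio:
    metabolite: str
    value: float
    defined: bool = True


def cycling_ratio(mid: np.ndarray, metabolite: str = "") -> CyclingRatio:
    """([M+1] + [M+3] + ... + [M+n]) / [M+2]; undefined when M+2 is zero."""
    mid = np.asarray(mid, dtype=float)
    if mid.size < 3:
        raise ValueError("cycling ratio needs at least M+0..M+2")
    m2 = mid[2]
    if m2 <= 0:
        return CyclingRatio(metabolite, float("nan"), defined=False)
    numerator = mid[1] + mid[3:].sum()
    return CyclingRatio(metabolite, float(numerator / m2), defined=True)


def absolute_isotopologue_amounts(mid: np.ndarray, total_pool: float) -> np.ndarray:
    """amount(M+X) = fraction(M+X) * total pool; conserves the total."""
    if total_pool < 0:
        raise ValueError("total pool must be >= 0")
    mid = np.asarray(mid, dtype=float)
    return mid * total_pool


@dataclass(frozen=True)
class CalibrationCurve:
    """area = slope * concentration + intercept, from a standard series."""

    analyte: str
    slope: float
    intercept: float
    r_squared: float
    concentration_range: tuple[float, float]


def fit_calibration(standards: pd.DataFrame, analyte: str | None = None) -> CalibrationCurve:
    """Ordinary least squares of peak area on standard concentration.

    ``standards`` columns: analyte (optional if given as argument),
    concentration, area.  Requires >= 3 distinct concentration levels and a
    positive fitted slope.
    """
    sub = standards
    if analyte is not None and "analyte" in standards:
        sub = standards[standards["analyte"] == analyte]
    if sub.empty:
        raise ValueError(f"no standards for analyte {analyte!r}")
    conc = sub["concentration"].to_numpy(dtype=float)
    area = sub["area"].to_numpy(dtype=float)
    if len(np.unique(conc)) < 3:
        raise ValueError("need at least 3 standard concentration levels")
    fit = scipy.stats.linregress(conc, area)
    if fit.slope <= 0:
        raise ValueError(f"non-positive calibration slope for {analyte!r}")
    return CalibrationCurve(
        analyte=analyte or "",
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        concentration_range=(float(conc.min()), float(conc.max())),
    )


def quantify(
    area: float, curve: CalibrationCurve, protein_mass: float
) -> tuple[float, bool]:
    """Peak area -> nmol/mg protein; flags areas below the calibrated range.

    Returns ``(amount, in_range)``; the concentration is (area - intercept)
    / slope, normalized per protein mass.
    """
    if protein_mass <= 0:
        raise ValueError("protein mass must be > 0")
    conc = (area - curve.intercept) / curve.slope
    lo, hi = curve.concentration_range
    in_range = lo <= conc <= hi
    return conc / protein_mass, in_range


# ---------------------------------------------------------------------------
# tidy-table wrappers


def labeling_table(corrected: pd.DataFrame) -> pd.DataFrame:
    """Corrected-fraction table -> labeling (%) rows (statistic column)."""
    out = corrected.copy()
    out["value"] = 100.0 * out["fraction"]
    out["statistic"] = "labeling_pct"
    return out.drop(columns=["fraction"])


def cycling_ratio_table(
    corrected: pd.DataFrame, metabolites=CYCLING_METABOLITES
) -> pd.DataFrame:
    """Per-replicate cycling ratios for the selected metabolites."""
    keys = [c for c in ("group", "line", "tracer", "metabolite", "replicate") if c in corrected]
    rows = []
    sub = corrected[corrected["metabolite"].isin(metabolites)]
    for key_vals, grp in sub.groupby(keys, sort=False):
        mid = grp.sort_values("isotopologue")["fraction"].to_numpy()
        met = key_vals[keys.index("metabolite")]
        cr = cycling_ratio(mid, met)
        rows.append(
            {**dict(zip(keys, key_vals)), "statistic": "cycling_ratio",
             "value": cr.value, "defined": cr.defined}
        )
    return pd.DataFrame(rows)


def amounts_table(corrected: pd.DataFrame, pool_sizes: pd.DataFrame) -> pd.DataFrame:
    """Absolute isotopologue amounts (nmol/mg) from fractions and pools."""
    keys = [c for c in ("group", "line", "metabolite") if c in corrected]
    merged = corrected.merge(pool_sizes, on=keys, how="left")
    if merged["pool_nmol_mg"].isna().any():
        missing = merged.loc[merged["pool_nmol_mg"].isna(), "metabolite"].unique()
        raise ValueError(f"no pool size for: {list(missing)}")
    out = merged.copy()
    out["value"] = out["fraction"] * out["pool_nmol_mg"]
    out["statistic"] = "amount_nmol_mg"
    return out.drop(columns=["fraction"])


def quantify_pools(
    pools: pd.DataFrame, standards: pd.DataFrame
) -> pd.DataFrame:
    """Quantify HPLC sample areas against per-analyte calibration curves."""
    curves = {a: fit_calibration(standards, a) for a in pools["analyte"].unique()}
    out = pools.copy()
    amounts, flags = [], []
    for _, row in pools.iterrows():
        amount, in_range = quantify(row["area"], curves[row["analyte"]], row["protein_mg"])
        amounts.append(amount)
        flags.append(in_range)
    out["amount_nmol_mg"] = amounts
    out["in_calibrated_range"] = flags
    return out
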