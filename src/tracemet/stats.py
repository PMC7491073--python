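"""Group-comparison statistics for the metabolic-mapping pipeline.

Implements the study's two statistical procedures on tidy tables:

* multiple unpaired two-sample t tests across strata (metabolite x
  isotopologue, or a metric panel) with Bonferroni-Dunn correction --
  i.e. raw p multiplied by the family size, capped at 1.  Pooled-variance
  t tests are the default (the populations are assumed to share scatter);
  Welch is available behind a flag.
* two-way ANOVA (Type II sums of squares, so unbalanced layouts are
  handled sensibly) with Sidak-adjusted pairwise group comparisons within
  each level of the second factor, using the residual mean square of the
  full model.

Summaries are mean +/- SEM with n.  All adjusted p-values are monotone
transforms of the raw p-values, and Sidak <= Bonferroni for any family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "summarize_groups",
    "bonferroni_dunn_adjust",
    "sidak_adjust",
    "multiple_t_tests",
    "two_way_anova",
    "ComparisonResult",
]


@dataclass(frozen=True)
class ComparisonResult:
    """One contrast: groups, stratum, statistic, raw/adjusted p, means."""

    stratum: tuple
    group_a: str
    group_b: str
    statistic: float
    raw_p: float
    adjusted_p: float
    direction: str  # 'a>b', 'a<b', or 'a=b'
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int


def summarize_groups(df: pd.DataFrame, value: str, by: list[str]) -> pd.DataFrame:
    """mean +/- SEM (sd/sqrt(n)) and n per cell; SEM is NaN for n < 2."""
    g = df.groupby(by, sort=False)[value]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out.drop(columns=["sd"])


def bonferroni_dunn_adjust(p: float, m: int) -> float:
    """Bonferroni-Dunn: p * m, capped at 1."""
    return min(1.0, p * m)


def sidak_adjust(p: float, m: int) -> float:
    """Sidak: 1 - (1 - p)^m."""
    return 1.0 - (1.0 - p) ** m


def _two_sample_t(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple[float, float]:
    if np.std(a) == 0 and np.std(b) == 0 and np.mean(a) == np.mean(b):
        return 0.0, 1.0  # identical degenerate groups
    res = scipy.stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def multiple_t_tests(
    df: pd.DataFrame,
    value: str = "value",
    group: str = "group",
    groups: tuple[str, str] | None = None,
    strata: list[str] | None = None,
    alpha: float = 0.05,
    correction: str = "bonferroni_dunn",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Unpaired t test per stratum with family-wise correction.

    The family size m is the number of strata actually tested; strata with
    fewer than two observations in either group are skipped (and do not
    count toward m).  Returns one row per stratum with means +/- SEM,
    t, raw and adjusted p, direction and a significance flag at ``alpha``.
    """
    if strata is None:
        strata = [c for c in ("tracer", "metabolite", "isotopologue") if c in df]
    if groups is None:
        levels = list(pd.unique(df[group]))
        if len(levels) != 2:
            raise ValueError(f"expected exactly 2 groups, found {levels}")
        groups = (levels[0], levels[1])
    ga, gb = groups
    adjuster = {
        "bonferroni_dunn": bonferroni_dunn_adjust,
        "sidak": sidak_adjust,
        "none": lambda p, m: p,
    }[correction]

    tested = []
    for key, sub in df.groupby(strata, sort=False):
        key = key if isinstance(key, tuple) else (key,)
        a = sub.loc[sub[group] == ga, value].to_numpy(dtype=float)
        b = sub.loc[sub[group] == gb, value].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            import warnings

            warnings.warn(f"stratum {key} skipped: fewer than 2 observations per group")
            continue
        t, p = _two_sample_t(a, b, equal_var)
        tested.append((key, a, b, t, p))

    m = len(tested)
    rows = []
    for key, a, b, t, p in tested:
        diff = float(np.mean(a) - np.mean(b))
        direction = "a>b" if diff > 0 else ("a<b" if diff < 0 else "a=b")
        adj = adjuster(p, m)
        rows.append(
            {
                **dict(zip(strata, key)),
                "group_a": ga,
                "group_b": gb,
                "mean_a": float(np.mean(a)),
                "sem_a": float(np.std(a, ddof=1) / np.sqrt(len(a))),
                "n_a": len(a),
                "mean_b": float(np.mean(b)),
                "sem_b": float(np.std(b, ddof=1) / np.sqrt(len(b))),
                "n_b": len(b),
                "t": t,
                "raw_p": p,
                "adjusted_p": adj,
                "direction": direction,
                "significant": adj < alpha,
                "family_size": m,
            }
        )
    return pd.DataFrame(rows)


def two_way_anova(
    df: pd.DataFrame,
    value: str = "value",
    factor_a: str = "group",
    factor_b: str = "isotopologue",
    sidak: bool = True,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-factor ANOVA plus Sidak-adjusted pairwise contrasts.

    The ANOVA table (Type II sums of squares) comes from an ordinary
    least-squares fit with full interaction.  When factor_a has exactly two
    levels, pairwise comparisons between them are computed within each
    level of factor_b using the model residual mean square, with Sidak
    adjustment over the number of levels tested.  Degenerate inputs (a
    single-level factor, or zero residual variance) raise or flag instead
    of producing 0/0 F statistics.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for factor in (factor_a, factor_b):
        if df[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} has a single level")
    work = df[[value, factor_a, factor_b]].rename(
        columns={value: "y", factor_a: "fa", factor_b: "fb"}
    )
    work["fa"] = work["fa"].astype(str)
    work["fb"] = work["fb"].astype(str)
    model = smf.ols("y ~ C(fa) * C(fb)", data=work).fit()
    if model.df_resid <= 0:
        raise ValueError("no residual degrees of freedom (no replication)")
    mse = float(model.ssr / model.df_resid)
    anova = sm.stats.anova_lm(model, typ=2)
    anova = anova.rename(
        index={
            "C(fa)": factor_a,
            "C(fb)": factor_b,
            "C(fa):C(fb)": f"{factor_a}:{factor_b}",
            "Residual": "residual",
        }
    )
    # zero residual variance (constant cells) cannot support F statistics
    scale = max(float(np.abs(work["y"]).max()), 1.0)
    degenerate = mse <= (1e-12 * scale) ** 2
    if degenerate:
        anova["F"] = np.nan
        anova["PR(>F)"] = np.nan

    levels_a = sorted(work["fa"].unique())
    pairwise_rows = []
    if len(levels_a) == 2:
        ga, gb = levels_a
        cells = []
        for lev, sub in work.groupby("fb", sort=False):
            a = sub.loc[sub["fa"] == ga, "y"].to_numpy(dtype=float)
            b = sub.loc[sub["fa"] == gb, "y"].to_numpy(dtype=float)
            if len(a) >= 1 and len(b) >= 1:
                cells.append((lev, a, b))
        m = len(cells)
        for lev, a, b in cells:
            if degenerate:
                t = np.nan
                p = np.nan
                adj = np.nan
            else:
                se = np.sqrt(mse * (1.0 / len(a) + 1.0 / len(b)))
                t = float((np.mean(a) - np.mean(b)) / se)
                p = float(2.0 * scipy.stats.t.sf(abs(t), model.df_resid))
                adj = sidak_adjust(p, m) if sidak else p
            diff = float(np.mean(a) - np.mean(b))
            pairwise_rows.append(
                {
                    factor_b: lev,
                    "group_a": ga,
                    "group_b": gb,
                    "mean_a": float(np.mean(a)),
                    "mean_b": float(np.mean(b)),
                    "t": t,
                    "raw_p": p,
                    "adjusted_p": adj,
                    "direction": "a>b" if diff > 0 else ("a<b" if diff < 0 else "a=b"),
                    "significant": bool(adj < alpha) if np.isfinite(adj) else False,
                    "family_size": m,
                    "degenerate": degenerate,
                }
            )
    return anova, pd.DataFrame(pairwise_rows)
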