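"""NUE metrics, design statistics and correlation reports for pot screens.

Nitrogen use efficiency is expressed per pot as the ratio of harvested mass
to nitrogen supplied: NUE_b = W_biomass / W_N and NUE_g = W_grain / W_N, both
in g/g.  Harvest index is grain yield as a percentage of total above-ground
dry biomass.  Treatment effects are assessed with a fixed-effects two-way
ANOVA (N level x variety, with interaction), from which the standard error
of a difference (s.e.d.), least significant difference (l.s.d.) and
coefficient of variation are derived.  Validation of the digital traits uses
Pearson correlation matrices and time-resolved correlations of estimated
biomass against harvest traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = [
    "N_INPUT_G",
    "nue",
    "harvest_index",
    "nue_table",
    "AnovaSummary",
    "two_way_anova",
    "CorrelationReport",
    "correlation_matrix",
    "timecourse_correlation",
    "rank_report",
    "outlier_screen",
    "paired_condition_correlation",
    "significance_stars",
]

#: grams of N supplied per pot over the experiment at each level
N_INPUT_G = {"low": 0.147, "optimum": 0.588}

#: 1.4826 x raw MAD estimates the SD of a normal sample, so the 3-MAD fence
#: is a 3-sigma fence on clean data
MAD_SCALE = 1.4826


def nue(weight_g: float, n_input_g: float) -> float:
    """Nitrogen use efficiency: grams of product per gram of N supplied."""
    if n_input_g <= 0:
        raise ValueError("n_input_g must be positive")
    if weight_g < 0:
        raise ValueError("weight_g must be non-negative")
    return weight_g / n_input_g


def harvest_index(gy_g: float, dw_g: float) -> float:
    """Grain yield as a percentage of total above-ground dry biomass."""
    if dw_g <= 0:
        raise ValueError("dw_g must be positive")
    if gy_g < 0:
        raise ValueError("gy_g must be non-negative")
    return 100.0 * gy_g / dw_g


def nue_table(
    harvest: pd.DataFrame, n_input_g: dict[str, float] = N_INPUT_G
) -> pd.DataFrame:
    """Per-row NUE_b, NUE_g and harvest index for a harvest table.

    ``harvest`` needs ``n_level, dw_g, gy_g`` (identifier columns are carried
    through).  ``n_input_g`` maps each N level to grams of N supplied per pot.
    """
    missing = {"n_level", "dw_g", "gy_g"} - set(harvest.columns)
    if missing:
        raise ValueError(f"harvest table is missing columns: {sorted(missing)}")
    unknown = set(harvest["n_level"].unique()) - set(n_input_g)
    if unknown:
        raise ValueError(f"no N input defined for levels: {sorted(unknown)}")
    out = harvest.copy()
    ninp = out["n_level"].map(n_input_g).astype(float)
    out["n_input_g"] = ninp
    out["nue_b"] = out["dw_g"] / ninp
    out["nue_g"] = out["gy_g"] / ninp
    out["harvest_index_pct"] = 100.0 * out["gy_g"] / out["dw_g"]
    return out


@dataclass(frozen=True)
class AnovaSummary:
    """Two-way fixed-effects ANOVA with the derived screening statistics.

    ``table`` holds sum of squares, df, F and p per effect;  ``sed`` the
    standard error of a difference between two means of each factor
    (sqrt(2 MSE / n)); ``lsd`` the least significant difference at p = 0.05;
    ``cv_pct`` is 100 sqrt(MSE) / grand mean.
    """

    table: pd.DataFrame
    mse: float
    df_error: int
    grand_mean: float
    sed: dict[str, float]
    lsd: dict[str, float]
    cv_pct: float


def two_way_anova(
    data: pd.DataFrame,
    trait: str,
    *,
    factor_a: str = "n_level",
    factor_b: str = "variety",
    allow_unbalanced: bool = False,
) -> AnovaSummary:
    """Fixed-effects two-way ANOVA with interaction for one trait.

    Requires a balanced design (equal replication in every cell) so the
    Type-I sum-of-squares partition is exact and order-free; pass
    ``allow_unbalanced=True`` to fall back to Type-II sums of squares for
    unbalanced data.  s.e.d. and l.s.d. are reported for each main factor and
    the interaction, using the number of observations per compared mean.
    """
    for col in (trait, factor_a, factor_b):
        if col not in data.columns:
            raise ValueError(f"column {col!r} not in data")
    clean = data[[factor_a, factor_b, trait]].dropna()
    counts = clean.groupby([factor_a, factor_b], sort=False).size()
    if counts.min() < 2:
        raise ValueError("at least 2 replicates per cell are required")
    balanced = counts.nunique() == 1
    if not balanced and not allow_unbalanced:
        raise ValueError(
            "design is unbalanced; rerun with allow_unbalanced=True for Type-II SS"
        )

    df = clean.rename(columns={factor_a: "A", factor_b: "B", trait: "y"})
    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=1 if balanced else 2)
    aov = aov.rename(
        index={
            "C(A)": factor_a,
            "C(B)": factor_b,
            "C(A):C(B)": f"{factor_a}:{factor_b}",
            "Residual": "residual",
        }
    )
    mse = float(aov.loc["residual", "sum_sq"] / aov.loc["residual", "df"])
    df_error = int(aov.loc["residual", "df"])
    grand_mean = float(df["y"].mean())

    n_total = len(df)
    n_per = {
        factor_a: n_total / df["A"].nunique(),
        factor_b: n_total / df["B"].nunique(),
        f"{factor_a}:{factor_b}": n_total / (df["A"].nunique() * df["B"].nunique()),
    }
    t_crit = sps.t.ppf(0.975, df_error)
    sed = {k: float(np.sqrt(2.0 * mse / n)) for k, n in n_per.items()}
    lsd = {k: float(t_crit * s) for k, s in sed.items()}
    cv_pct = 100.0 * np.sqrt(mse) / grand_mean if grand_mean != 0 else np.inf
    return AnovaSummary(
        table=aov,
        mse=mse,
        df_error=df_error,
        grand_mean=grand_mean,
        sed=sed,
        lsd=lsd,
        cv_pct=float(cv_pct),
    )


def significance_stars(p: float) -> str:
    """Figure-legend convention: * p<=0.05, ** p<=0.01, *** p<=0.001."""
    if np.isnan(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class CorrelationReport:
    """Pairwise Pearson correlations with tests and per-cell sample sizes."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    stars: pd.DataFrame


def correlation_matrix(data: pd.DataFrame, traits: list[str]) -> CorrelationReport:
    """Pairwise-complete Pearson correlation matrix over the given traits.

    Each pair is tested two-sided (t distribution on n - 2 df).  A pair with
    fewer than 3 complete rows or a zero-variance trait gets r = NaN and a
    warning is recorded via ``warnings.warn``.
    """
    import warnings

    k = len(traits)
    r = pd.DataFrame(np.eye(k), index=traits, columns=traits)
    p = pd.DataFrame(np.zeros((k, k)), index=traits, columns=traits)
    n = pd.DataFrame(0, index=traits, columns=traits)
    for t in traits:
        if t not in data.columns:
            raise ValueError(f"trait {t!r} not in data")
        n.loc[t, t] = int(data[t].notna().sum())
    for i in range(k):
        for j in range(i + 1, k):
            a, b = traits[i], traits[j]
            pair = data[[a, b]].dropna()
            n.loc[a, b] = n.loc[b, a] = len(pair)
            if len(pair) < 3:
                warnings.warn(f"fewer than 3 complete rows for ({a}, {b})")
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            if pair[a].nunique() == 1 or pair[b].nunique() == 1:
                warnings.warn(f"zero variance in ({a}, {b}); correlation undefined")
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            rr, pp = sps.pearsonr(pair[a], pair[b])
            r.loc[a, b] = r.loc[b, a] = rr
            p.loc[a, b] = p.loc[b, a] = pp
    stars = p.map(significance_stars)
    for t in traits:
        stars.loc[t, t] = ""
    return CorrelationReport(r=r, p=p, n=n, stars=stars)


def timecourse_correlation(
    trait_series: pd.DataFrame,
    harvest: pd.DataFrame,
    *,
    harvest_traits: tuple[str, ...] = ("dw_g", "gy_g"),
    by_n_level: bool = True,
    variety_means: bool = False,
) -> pd.DataFrame:
    """Correlation of estimated biomass at each imaging day with harvest traits.

    ``trait_series`` needs ``pot_id, n_level, das, eb_kpix`` (and ``variety``
    when ``variety_means``); ``harvest`` needs ``pot_id`` plus the harvest
    trait columns.  Pots are matched by ``pot_id``; by default pots are
    pooled within N level, or set ``variety_means=True`` to correlate variety
    means.  Returns a tidy frame with columns ``n_level, das, trait, r, p,
    n, stars`` ordered by DAS.
    """
    if not set(trait_series["pot_id"]) & set(harvest["pot_id"]):
        raise ValueError("no overlapping pots between trait series and harvest table")
    merged = trait_series.merge(
        harvest[["pot_id", *harvest_traits]], on="pot_id", how="inner"
    )
    group_cols = (["n_level"] if by_n_level else []) + ["das"]
    rows = []
    for key, grp in merged.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        if variety_means:
            grp = grp.groupby("variety", as_index=False)[["eb_kpix", *harvest_traits]].mean()
        for htrait in harvest_traits:
            pair = grp[["eb_kpix", htrait]].dropna()
            if len(pair) < 3 or pair["eb_kpix"].nunique() == 1 or pair[htrait].nunique() == 1:
                rr, pp = np.nan, np.nan
            else:
                rr, pp = sps.pearsonr(pair["eb_kpix"], pair[htrait])
            rows.append(
                {
                    **({"n_level": key[0]} if by_n_level else {}),
                    "das": key[-1],
                    "trait": htrait,
                    "r": rr,
                    "p": pp,
                    "n": len(pair),
                    "stars": significance_stars(pp) if np.isfinite(pp) else "",
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values(group_cols + ["trait"]).reset_index(drop=True)


def rank_report(
    table: pd.DataFrame,
    trait: str,
    n_level: str,
    *,
    k_extremes: int = 3,
    descending: bool = True,
) -> pd.DataFrame:
    """Rank varieties by a trait at a reference N level, flagging extremes.

    Replicates are averaged to one value per variety first.  Ties are broken
    alphabetically by variety name and reported in a ``tied`` column.  The top
    and bottom ``k_extremes`` varieties are annotated (the "dark green" and
    "dark red" cells of a screening table).
    """
    sub = table[table["n_level"] == n_level]
    if sub.empty:
        raise ValueError(f"no rows at n_level {n_level!r}")
    means = sub.groupby("variety", as_index=False)[trait].mean()
    means = means.sort_values(
        [trait, "variety"], ascending=[not descending, True], kind="mergesort"
    ).reset_index(drop=True)
    means["rank"] = np.arange(1, len(means) + 1)
    dup = means[trait].duplicated(keep=False)
    means["tied"] = dup
    k = min(k_extremes, len(means))
    flag = np.array([""] * len(means), dtype=object)
    flag[:k] = "high" if descending else "low"
    flag[-k:] = "low" if descending else "high"
    means["extreme"] = flag
    return means


def outlier_screen(
    table: pd.DataFrame,
    trait: str,
    group_cols: list[str],
    *,
    n_mad: float = 3.0,
    min_group: int = 4,
) -> pd.DataFrame:
    """Flag values beyond median +/- ``n_mad`` scaled MADs within each group.

    The MAD is scaled by 1.4826 so the fence corresponds to ``n_mad`` SDs on
    normal data (~0.3% false flags at 3).  Groups smaller than ``min_group``
    are never flagged.  Returns the input with an ``outlier`` boolean column;
    rows are reported, never dropped.
    """
    out = table.copy()
    out["outlier"] = False
    for _, idx in out.groupby(group_cols, sort=False).groups.items():
        vals = out.loc[idx, trait].astype(float)
        if len(vals) < min_group:
            continue
        med = vals.median()
        mad = (vals - med).abs().median() * MAD_SCALE
        if mad == 0:
            continue
        out.loc[idx, "outlier"] = (vals - med).abs() > n_mad * mad
    return out


def paired_condition_correlation(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    traits: list[str],
    *,
    on: str = "variety",
    suffixes: tuple[str, str] = ("_a", "_b"),
) -> pd.DataFrame:
    """Correlate variety means of the same traits between two conditions.

    Generic machinery for comparing, e.g., a controlled-environment screen
    with a field trial: both tables are reduced to one mean per ``on`` key,
    joined, and each trait correlated across conditions.  Returns a tidy
    frame with ``trait, r, p, n, stars``.
    """
    ma = table_a.groupby(on, as_index=False)[traits].mean()
    mb = table_b.groupby(on, as_index=False)[traits].mean()
    merged = ma.merge(mb, on=on, suffixes=suffixes)
    rows = []
    for t in traits:
        pair = merged[[t + suffixes[0], t + suffixes[1]]].dropna()
        if len(pair) < 3:
            rr, pp = np.nan, np.nan
        else:
            rr, pp = sps.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
        rows.append(
            {
                "trait": t,
                "r": rr,
                "p": pp,
                "n": len(pair),
                "stars": significance_stars(pp) if np.isfinite(pp) else "",
            }
        )
    return pd.DataFrame(rows)
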