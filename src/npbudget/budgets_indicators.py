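"""Annual agronomic N and P budgets and derived indicators.

The agronomic soil N budget of a unit-year is

    N_budget = N_fix + N_dep + N_fert + N_man − N_withdr

and for P, with fixation and deposition absent,

    P_budget = P_fert + P_man − P_withdr
    P_residual = P_budget − P_runoff

A positive budget is a surplus, a negative one a deficit. Nutrient use
efficiency (NUE, PUE) is harvested output divided by total input; regional
indicators are always ratios of summed masses, never averages of ratios.
Cumulative residual soil P is the running sum of residual flux × cropland
area, reported in Tg (1 Tg = 1e9 kg). The molar N:P ratio uses atomic
masses 14.007 and 30.974 g/mol.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core_data import ATOMIC_MASS_N, ATOMIC_MASS_P, KG_PER_TG, RegionMap

#: BudgetTerms columns, absolute kg/yr per (unit, year), plus cropland area (ha)
N_INPUT_TERMS = ["N_fix", "N_dep", "N_fert", "N_man"]
P_INPUT_TERMS = ["P_fert", "P_man"]
TERM_COLUMNS = N_INPUT_TERMS + ["N_withdr"] + P_INPUT_TERMS + [
    "P_withdr", "P_runoff", "area"]


def check_terms(terms: pd.DataFrame) -> pd.DataFrame:
    """Validate a BudgetTerms table: all term columns present, non-negative."""
    missing = [c for c in TERM_COLUMNS if c not in terms.columns]
    if missing:
        raise KeyError(f"budget terms table missing columns: {missing}")
    neg = [c for c in TERM_COLUMNS if (terms[c] < 0).any()]
    if neg:
        raise ValueError(f"negative values in budget terms: {neg}")
    return terms


def n_budget(terms: pd.DataFrame) -> pd.Series:
    """N_fix + N_dep + N_fert + N_man − N_withdr (same units as the terms)."""
    check_terms(terms)
    return (terms[N_INPUT_TERMS].sum(axis=1) - terms["N_withdr"]).rename("N_budget")


def p_budget(terms: pd.DataFrame) -> pd.Series:
    """P_fert + P_man − P_withdr."""
    check_terms(terms)
    return (terms[P_INPUT_TERMS].sum(axis=1) - terms["P_withdr"]).rename("P_budget")


def residual_p(p_budget_series: pd.Series, p_runoff: pd.Series) -> pd.Series:
    """Residual soil P flux: agronomic P budget minus runoff losses."""
    if (np.asarray(p_runoff) < 0).any():
        raise ValueError("P_runoff must be non-negative")
    return (p_budget_series - p_runoff).rename("P_residual")


def nue_pue(inputs: float, withdrawal: float) -> float:
    """Nutrient use efficiency: harvested output / total input.

    Undefined (NaN) when inputs are zero.
    """
    if inputs < 0 or withdrawal < 0:
        raise ValueError("masses must be non-negative")
    if inputs == 0:
        return math.nan
    return withdrawal / inputs


def cumulative_residual_p(residual_kg_ha: Iterable[float],
                          area_ha: Iterable[float]) -> np.ndarray:
    """Running sum of residual flux × area, in Tg.

    Both series are aligned by year; a negative residual draws the
    cumulative stock down.
    """
    res = np.asarray(list(residual_kg_ha), dtype=float)
    area = np.asarray(list(area_ha), dtype=float)
    if res.shape != area.shape:
        raise ValueError("residual and area series are misaligned")
    return np.cumsum(res * area) / KG_PER_TG


def np_molar_ratio(N_mass: float, P_mass: float) -> float:
    """Molar N:P ratio of two masses (kg, Tg — any common unit)."""
    if P_mass <= 0:
        return math.nan
    return (N_mass / ATOMIC_MASS_N) / (P_mass / ATOMIC_MASS_P)


def fixation_share(N_fix: float, N_dep: float, N_fert: float, N_man: float) -> float:
    """Contribution of biological N fixation to total N inputs."""
    total = N_fix + N_dep + N_fert + N_man
    if total <= 0:
        return math.nan
    return N_fix / total


def compute_budgets(terms: pd.DataFrame) -> pd.DataFrame:
    """Attach N_budget, P_budget and P_residual columns (absolute kg/yr) and
    their per-ha counterparts to a BudgetTerms table indexed (unit, year)."""
    out = terms.copy()
    out["N_budget"] = n_budget(terms)
    out["P_budget"] = p_budget(terms)
    out["P_residual"] = residual_p(out["P_budget"], terms["P_runoff"])
    for col in ("N_budget", "P_budget", "P_residual"):
        with np.errstate(divide="ignore", invalid="ignore"):
            out[col + "_per_ha"] = np.where(out["area"] > 0,
                                            out[col] / out["area"], np.nan)
    return out


def aggregate_regions(terms: pd.DataFrame, region_map: RegionMap,
                      archetypes: Iterable[str] = ("world", "high_income",
                                                   "china_india", "transition",
                                                   "ssa"),
                      fertilizer_np: pd.DataFrame | None = None) -> pd.DataFrame:
    """Aggregate unit-level budget terms to region archetypes and compute
    the indicator series.

    Absolute masses are summed over member countries; per-ha terms, budgets
    and efficiency ratios are then recomputed from the sums (a region's NUE
    is Σ withdrawal / Σ inputs, never a mean of country NUEs). ``world``
    covers every mapped country. ``fertilizer_np``, if given, must carry
    absolute fertilizer N and P columns to form the molar N:P fertilizer
    ratio; otherwise N_fert/P_fert of the terms are used.

    Returns a tidy frame indexed (archetype, year) with budgets (kg/ha/yr),
    NUE, PUE, fixation share, cumulative residual P (Tg) and the fertilizer
    molar N:P ratio.
    """
    check_terms(terms)
    units = terms.index.get_level_values(0)
    unmapped = sorted(set(units) - set(region_map.units))
    if unmapped:
        raise KeyError(f"units missing from RegionMap: {unmapped}")

    rows = []
    for arch in archetypes:
        members = set(region_map.archetype_members(arch))
        sub = terms.loc[[u in members for u in units]]
        if sub.empty:
            continue
        agg = sub.groupby(level=1).sum(numeric_only=True).sort_index()
        n_in = agg[N_INPUT_TERMS].sum(axis=1)
        p_in = agg[P_INPUT_TERMS].sum(axis=1)
        nb = n_in - agg["N_withdr"]
        pb = p_in - agg["P_withdr"]
        pres = pb - agg["P_runoff"]
        cum = np.cumsum(pres.values) / KG_PER_TG
        if fertilizer_np is not None:
            fsub = fertilizer_np.loc[[u in members for u in
                                      fertilizer_np.index.get_level_values(0)]]
            fagg = fsub.groupby(level=1).sum(numeric_only=True).reindex(agg.index)
            fert_n, fert_p = fagg["N_fert"], fagg["P_fert"]
        else:
            fert_n, fert_p = agg["N_fert"], agg["P_fert"]
        for i, (year, row) in enumerate(agg.iterrows()):
            area = row["area"]
            rows.append({
                "archetype": arch, "year": int(year),
                "area_ha": area,
                "N_budget_kg_ha": nb[year] / area if area > 0 else np.nan,
                "P_budget_kg_ha": pb[year] / area if area > 0 else np.nan,
                "P_residual_kg_ha": pres[year] / area if area > 0 else np.nan,
                "NUE": nue_pue(n_in[year], row["N_withdr"]),
                "PUE": nue_pue(p_in[year], row["P_withdr"]),
                "fixation_share": fixation_share(row["N_fix"], row["N_dep"],
                                                 row["N_fert"], row["N_man"]),
                "cumulative_residual_P_Tg": cum[i],
                "NP_fertilizer_molar_ratio": np_molar_ratio(fert_n[year],
                                                            fert_p[year]),
            })
    return pd.DataFrame(rows).set_index(["archetype", "year"]).sort_index()


def plot_indicators(indicators: pd.DataFrame, path) -> None:
    """Three-panel PNG: per-ha budgets, NUE/PUE, cumulative residual P."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 3.6))
    for arch in indicators.index.get_level_values(0).unique():
        sub = indicators.xs(arch)
        axes[0].plot(sub.index, sub["N_budget_kg_ha"], label=f"{arch} N")
        axes[0].plot(sub.index, sub["P_budget_kg_ha"], "--", label=f"{arch} P")
        axes[1].plot(sub.index, sub["NUE"], label=f"{arch} NUE")
        axes[1].plot(sub.index, sub["PUE"], "--", label=f"{arch} PUE")
        axes[2].plot(sub.index, sub["cumulative_residual_P_Tg"], label=arch)
    axes[0].set_ylabel("budget (kg/ha/yr)")
    axes[1].set_ylabel("use efficiency (-)")
    axes[1].axhline(1.0, color="k", lw=0.5)
    axes[2].set_ylabel("cumulative residual P (Tg)")
    for ax in axes:
        ax.set_xlabel("year")
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def indicators_to_tidy(indicators: pd.DataFrame) -> pd.DataFrame:
    """Long-format (region, year, indicator, value) view for CSV export."""
    tidy = indicators.reset_index().melt(
        id_vars=["archetype", "year"], var_name="indicator", value_name="value")
    return tidy.rename(columns={"archetype": "region"}).sort_values(
        ["region", "indicator", "year"]).reset_index(drop=True)
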