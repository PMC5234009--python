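"""Synthetic input worlds with known ground truth.

The generator emits a complete, internally consistent input bundle — crop
production, harvested areas, livestock stocks, national fertilizer totals,
fertilizer-use-by-crop rates, a deposition/soil grid, region map and
parameter config — shaped like the national statistics the budget pipeline
consumes, for a configurable number of countries per development archetype
over 1970–2010.

Each archetype carries its own temporal trends (piecewise-linear knots with
optional lognormal multiplicative noise): high-income countries see P
fertilizer decline while yields keep rising; China/India-type countries see
steeply rising inputs outpacing uptake; transition countries collapse their
inputs after 1990; sub-Saharan-Africa-type countries stay near zero.

Ground truth budgets and indicators are computed inside the generator by a
deliberately naive, self-contained implementation of the same accounting
(straight-line loops, no shared helpers with the pipeline modules), so the
pipeline can be validated against an independent oracle. Optional
missing-year injection and perturbed subnational splits exercise the
gap-filling and scaling machinery; with neither, a pipeline run over the
bundle must reproduce the ground truth to floating-point accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_data import STAT_COLUMNS

# ---------------------------------------------------------------------------
# Shared synthetic parameter tables (also shipped as bundle config)
# ---------------------------------------------------------------------------

CROP_DEFS = {
    #             group          N        P      fodder  soy
    "wheat":   ("upland",       0.020, 0.0035, False, False),
    "maize":   ("upland",       0.015, 0.0030, False, False),
    "rice":    ("wetland_rice", 0.012, 0.0030, False, False),
    "soybean": ("legume",       0.062, 0.0060, False, True),
    "pulses":  ("legume",       0.035, 0.0040, False, False),
    "alfalfa": ("legume",       0.025, 0.0025, True,  False),
}

EXCRETION_RATES = {
    # category: (kg N/head/yr, kg P/head/yr, share of total excreted N)
    "cattle":      (50.0, 8.0, 0.70),
    "dairy":       (70.0, 10.0, 0.15),
    "pigs":        (12.0, 3.0, 0.10),
    "sheep_goats": (8.0, 1.5, 0.04),
    "other":       (40.0, 6.0, 0.01),
}

GRAZING_FRACTION = 0.30
OUTSIDE_FRACTION = 0.10
FUEL_FRACTION = 0.05
STORAGE_NH3_LOSS = 0.20
CROPLAND_SHARE = {"high_income": 0.50, "developing": 0.95}
EU_CAP = 170.0  # kg N/ha/yr

HARVEST_INDEX = 0.5
ROOT_RATIO = 0.19
SEED_N = {"pulses": 0.035, "soybean": 0.062}
STRAW_N = 0.008
ROOT_N = 0.008
FIX_COEF = 0.6
NONSYMB = {"upland": 5.0, "wetland_rice": 25.0, "legume": 0.0}

RECENT_RUNOFF_FRACTION = 0.10
SOIL_MASS_30CM = 3.9e6
WEATHER_EA = 50_000.0
WEATHER_TREF = 284.15
R_GAS = 8.314

ARCH_PREFIX = {"high_income": "HI", "china_india": "CI", "transition": "TR",
               "ssa": "SA", "other": "OT"}


@dataclass
class ArchetypeTrends:
    """Piecewise-linear trend knots [(year, value), ...] for one archetype."""

    fert_N: list        # national N fertilizer, kg N/ha of cropland
    fert_P: list        # kg P/ha
    uptake_N: list      # crop N withdrawal intensity, kg N/ha
    manure_N: list      # target manure N applied to cropland, kg N/ha
    dep_rate_2000: float   # N deposition in 2000, kg N/ha/yr
    emission_index: list   # dimensionless, = 1 in 2000
    crop_area_shares: dict
    crop_uptake_weights: dict  # share of N withdrawal by crop
    soil_loss_mean: float      # kg soil/ha/yr
    mat_mean: float            # degC
    income_class: str
    eu_fraction: float = 0.0


def _default_trends() -> dict[str, ArchetypeTrends]:
    hi_shares = {"wheat": 0.35, "maize": 0.25, "rice": 0.05, "soybean": 0.08,
                 "pulses": 0.07, "alfalfa": 0.20}
    hi_weights = {"wheat": 0.40, "maize": 0.30, "rice": 0.0, "soybean": 0.10,
                  "pulses": 0.05, "alfalfa": 0.15}
    ci_shares = {"wheat": 0.25, "maize": 0.20, "rice": 0.30, "soybean": 0.10,
                 "pulses": 0.10, "alfalfa": 0.05}
    ci_weights = {"wheat": 0.30, "maize": 0.20, "rice": 0.30, "soybean": 0.10,
                  "pulses": 0.05, "alfalfa": 0.05}
    tr_shares = {"wheat": 0.45, "maize": 0.25, "rice": 0.0, "soybean": 0.0,
                 "pulses": 0.12, "alfalfa": 0.18}
    tr_weights = {"wheat": 0.50, "maize": 0.25, "rice": 0.0, "soybean": 0.0,
                  "pulses": 0.10, "alfalfa": 0.15}
    sa_shares = {"wheat": 0.20, "maize": 0.40, "rice": 0.10, "soybean": 0.0,
                 "pulses": 0.30, "alfalfa": 0.0}
    sa_weights = {"wheat": 0.20, "maize": 0.40, "rice": 0.10, "soybean": 0.0,
                  "pulses": 0.30, "alfalfa": 0.0}
    wd_shares = {"wheat": 0.30, "maize": 0.25, "rice": 0.15, "soybean": 0.08,
                 "pulses": 0.12, "alfalfa": 0.10}
    wd_weights = {"wheat": 0.35, "maize": 0.25, "rice": 0.15, "soybean": 0.08,
                  "pulses": 0.07, "alfalfa": 0.10}
    idx = [(1970, 0.6), (2000, 1.0), (2010, 1.05)]
    return {
        "high_income": ArchetypeTrends(
            fert_N=[(1970, 60), (1990, 75), (2010, 80)],
            fert_P=[(1970, 15), (1980, 16), (2010, 4)],
            uptake_N=[(1970, 55), (1990, 75), (2010, 95)],
            manure_N=[(1970, 25), (2010, 25)],
            dep_rate_2000=8.0, emission_index=idx,
            crop_area_shares=hi_shares, crop_uptake_weights=hi_weights,
            soil_loss_mean=1500.0, mat_mean=10.0,
            income_class="high_income", eu_fraction=0.5),
        "china_india": ArchetypeTrends(
            fert_N=[(1970, 15), (1990, 90), (2010, 190)],
            fert_P=[(1970, 7), (1990, 25), (2010, 35)],
            uptake_N=[(1970, 25), (1990, 65), (2010, 90)],
            manure_N=[(1970, 10), (2010, 25)],
            dep_rate_2000=10.0, emission_index=idx,
            crop_area_shares=ci_shares, crop_uptake_weights=ci_weights,
            soil_loss_mean=1000.0, mat_mean=16.0,
            income_class="developing"),
        "transition": ArchetypeTrends(
            fert_N=[(1970, 50), (1990, 80), (1995, 15), (2010, 18)],
            fert_P=[(1970, 12), (1990, 18), (1995, 3), (2010, 3)],
            uptake_N=[(1970, 35), (1990, 45), (1995, 42), (2010, 50)],
            manure_N=[(1970, 30), (1990, 30), (1995, 10), (2010, 10)],
            dep_rate_2000=5.0, emission_index=idx,
            crop_area_shares=tr_shares, crop_uptake_weights=tr_weights,
            soil_loss_mean=1800.0, mat_mean=7.0,
            income_class="developing"),
        "ssa": ArchetypeTrends(
            fert_N=[(1970, 3), (1990, 5), (2010, 8)],
            fert_P=[(1970, 1.5), (1990, 2), (2010, 3)],
            uptake_N=[(1970, 12), (1990, 15), (2010, 20)],
            manure_N=[(1970, 4), (2010, 5)],
            dep_rate_2000=3.0, emission_index=idx,
            crop_area_shares=sa_shares, crop_uptake_weights=sa_weights,
            soil_loss_mean=2500.0, mat_mean=24.0,
            income_class="developing"),
        "other": ArchetypeTrends(
            fert_N=[(1970, 25), (1990, 50), (2010, 70)],
            fert_P=[(1970, 8), (1990, 12), (2010, 12)],
            uptake_N=[(1970, 30), (1990, 45), (2010, 60)],
            manure_N=[(1970, 12), (2010, 18)],
            dep_rate_2000=5.0, emission_index=idx,
            crop_area_shares=wd_shares, crop_uptake_weights=wd_weights,
            soil_loss_mean=2000.0, mat_mean=15.0,
            income_class="developing"),
    }


@dataclass
class WorldSpec:
    """Recipe for one synthetic world. Same seed → identical bundle."""

    seed: int = 0
    n_countries: dict = field(default_factory=lambda: {
        "high_income": 2, "china_india": 2, "transition": 2, "ssa": 2,
        "other": 2})
    years: tuple = (1970, 2010)
    cells_per_country: int = 6
    base_area_ha: float = 1.0e6
    country_sd: float = 0.05     # lognormal spread of country-level levels
    noise_sd: float = 0.02       # lognormal year-to-year noise on trends
    missing_prob: float = 0.0    # probability an interior year is dropped
    subnational_per_archetype: int = 1   # countries split into subunits
    subnational_parts: int = 3
    subnational_perturb: float = 0.0     # noise on subunit shares (re-scaled away)
    linear_trends: bool = False  # collapse knots to a single 1970→2010 segment
    trends: dict = field(default_factory=_default_trends)

    def validate(self) -> None:
        if self.years[1] <= self.years[0]:
            raise ValueError("years range must be increasing")
        for nm, tr in self.trends.items():
            for attr in ("fert_N", "fert_P", "uptake_N", "manure_N",
                         "emission_index"):
                vals = [v for _, v in getattr(tr, attr)]
                if any(v < 0 for v in vals):
                    raise ValueError(
                        f"trend {attr} of archetype {nm!r} goes negative")
        if not 0 <= self.missing_prob < 1:
            raise ValueError("missing_prob must be in [0, 1)")


def _knots_to_series(knots, years, linear=False) -> np.ndarray:
    xs = np.array([k[0] for k in knots], dtype=float)
    ys = np.array([k[1] for k in knots], dtype=float)
    if linear:
        xs, ys = xs[[0, -1]], ys[[0, -1]]
    return np.interp(np.asarray(years, dtype=float), xs, ys)


# ---------------------------------------------------------------------------
# World construction
# ---------------------------------------------------------------------------


@dataclass
class TrueWorld:
    """Complete (gap-free) series and static fields of a synthetic world."""

    years: list
    countries: list
    meta: dict          # country -> dict(region, archetype, income, eu)
    subunits: dict      # country -> list of subunit ids
    production: dict    # (country, crop) -> ndarray over years, kg/yr
    areas: dict         # (country, crop) -> ndarray, ha
    stocks: dict        # (country, category) -> ndarray, head
    fert: dict          # (country, "N"|"P") -> ndarray, kg/yr
    dep_index: dict     # region -> ndarray over years
    cells: pd.DataFrame
    fubc: pd.DataFrame


def build_true_world(spec: WorldSpec) -> TrueWorld:
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    years = list(range(spec.years[0], spec.years[1] + 1))
    ny = len(years)
    yr2000_i = years.index(2000) if 2000 in years else ny - 1

    def noisy(base: np.ndarray) -> np.ndarray:
        if spec.noise_sd == 0:
            return base.copy()
        return base * np.exp(spec.noise_sd * rng.standard_normal(ny))

    countries, meta, subunits = [], {}, {}
    production, areas, stocks, fert = {}, {}, {}, {}
    cell_rows, fubc_rows = [], []
    # raster-scan cursor over a mid-latitude band so cell areas vary
    grid_positions = iter((r, c) for r in range(100, 300) for c in range(720))

    stored_frac = 1.0 - GRAZING_FRACTION - OUTSIDE_FRACTION - FUEL_FRACTION

    for arch, n in spec.n_countries.items():
        tr = spec.trends[arch]
        for i in range(n):
            cid = f"{ARCH_PREFIX[arch]}{i:03d}"
            countries.append(cid)
            eu = tr.income_class == "high_income" and (
                i < round(tr.eu_fraction * n))
            meta[cid] = {"region": arch, "archetype": arch,
                         "income_class": tr.income_class, "eu_member": eu}
            m_area, m_int, m_fert, m_man = np.exp(
                spec.country_sd * rng.standard_normal(4))
            a_total = spec.base_area_ha * m_area

            upt = _knots_to_series(tr.uptake_N, years, spec.linear_trends) * m_int
            for crop, (grp, ncont, _p, _f, _s) in CROP_DEFS.items():
                w = tr.crop_uptake_weights.get(crop, 0.0)
                a = tr.crop_area_shares.get(crop, 0.0)
                if a == 0.0 and w == 0.0:
                    continue
                areas[(cid, crop)] = np.full(ny, a * a_total)
                production[(cid, crop)] = noisy(upt * w * a_total / ncont)

            fn = _knots_to_series(tr.fert_N, years, spec.linear_trends)
            fp = _knots_to_series(tr.fert_P, years, spec.linear_trends)
            fert[(cid, "N")] = noisy(fn * a_total * m_fert)
            fert[(cid, "P")] = noisy(fp * a_total * m_fert)

            man = _knots_to_series(tr.manure_N, years, spec.linear_trends) * m_man
            share = CROPLAND_SHARE[tr.income_class]
            excreted_n = man * a_total / (
                stored_frac * (1.0 - STORAGE_NH3_LOSS) * share)
            for cat, (rate_n, _rate_p, cat_share) in EXCRETION_RATES.items():
                stocks[(cid, cat)] = noisy(cat_share * excreted_n / rate_n)

            # grid cells: static cropland split and soil properties
            wts = rng.uniform(0.5, 1.5, spec.cells_per_country)
            wts /= wts.sum()
            for j, wcell in enumerate(wts):
                row, col = next(grid_positions)
                cell_rows.append({
                    "cell_id": f"{cid}_c{j}", "row": row, "col": col,
                    "country": cid, "crop_area_ha": wcell * a_total,
                    "ndep_2000": tr.dep_rate_2000 * rng.uniform(0.8, 1.2),
                    "soil_loss": tr.soil_loss_mean * rng.uniform(0.6, 1.4),
                    "soil_C": rng.uniform(0.015, 0.025),
                    "initial_P_content": 2.5e-4 * rng.uniform(0.7, 1.3),
                    "lithology_P_conc": rng.uniform(0.005, 0.02),
                    "shielding": rng.uniform(0.5, 1.0),
                    "runoff_mm": rng.uniform(200.0, 600.0),
                    "MAT": tr.mat_mean + rng.uniform(-3.0, 3.0),
                    "recent_fraction": RECENT_RUNOFF_FRACTION,
                })

            # FUBC rates (anchor 2000); every 4th country deliberately missing
            if not (n > 1 and i % 4 == 3):
                group_area = {"upland": 0.0, "wetland_rice": 0.0, "legume": 0.0}
                for crop, (grp, *_rest) in CROP_DEFS.items():
                    g = "upland" if CROP_DEFS[crop][3] else grp
                    group_area[g] += tr.crop_area_shares.get(crop, 0.0) * a_total
                pref = {"upland": 1.2, "wetland_rice": 1.0, "legume": 0.3}
                for g, ga in group_area.items():
                    for nut, series in (("N", fn), ("P", fp)):
                        fubc_rows.append({
                            "country": cid, "group": g, "nutrient": nut,
                            "rate": series[yr2000_i] * pref[g],
                            "area": ga})

            if i < spec.subnational_per_archetype and spec.subnational_parts > 1:
                subunits[cid] = [f"{cid}_s{k}"
                                 for k in range(spec.subnational_parts)]
                for sid in subunits[cid]:
                    meta[sid] = dict(meta[cid])
            else:
                subunits[cid] = []

    dep_index = {arch: _knots_to_series(spec.trends[arch].emission_index,
                                        years, spec.linear_trends)
                 for arch in spec.n_countries}
    return TrueWorld(years=years, countries=countries, meta=meta,
                     subunits=subunits, production=production, areas=areas,
                     stocks=stocks, fert=fert, dep_index=dep_index,
                     cells=pd.DataFrame(cell_rows),
                     fubc=pd.DataFrame(fubc_rows))


# ---------------------------------------------------------------------------
# Naive ground-truth accounting (independent oracle; no shared helpers)
# ---------------------------------------------------------------------------


def naive_ground_truth(world: TrueWorld) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward budget accounting written as plain loops.

    Returns (terms, indicators): terms indexed (unit, year) with every
    budget term (kg/yr), cropland area, budgets and residual P; indicators
    indexed (archetype, year) with the regional series.
    """
    years = world.years
    terms_rows = {}
    # per-cell soil P pools, evolved in place
    cellp = {}
    for _, c in world.cells.iterrows():
        cellp[c["cell_id"]] = c["initial_P_content"] * SOIL_MASS_30CM

    for cid in world.countries:
        atotal = 0.0
        group_area = {"upland": 0.0, "wetland_rice": 0.0, "legume": 0.0}
        for crop in CROP_DEFS:
            if (cid, crop) in world.areas:
                a = float(world.areas[(cid, crop)][0])
                atotal += a
                grp = CROP_DEFS[crop][0]
                if CROP_DEFS[crop][3]:
                    grp = "upland"
                group_area[grp] += a
        meta = world.meta[cid]
        ccells = world.cells[world.cells["country"] == cid]
        dep2000_mass = 0.0
        for _, c in ccells.iterrows():
            dep2000_mass += c["ndep_2000"] * c["crop_area_ha"]

        for t, year in enumerate(years):
            # withdrawal
            n_w = p_w = 0.0
            for crop, (grp, ncont, pcont, _f, _s) in CROP_DEFS.items():
                if (cid, crop) in world.production:
                    prod = float(world.production[(cid, crop)][t])
                    n_w += prod * ncont
                    p_w += prod * pcont
            # fixation
            n_fix = 0.0
            for crop in ("pulses", "soybean"):
                if (cid, crop) in world.production:
                    grain = float(world.production[(cid, crop)][t])
                    above = grain / HARVEST_INDEX
                    straw = above - grain
                    roots = ROOT_RATIO * above
                    plant_n = (grain * SEED_N[crop] + straw * STRAW_N
                               + roots * ROOT_N)
                    n_fix += FIX_COEF * plant_n
            if (cid, "alfalfa") in world.production:
                n_fix += float(world.production[(cid, "alfalfa")][t]) \
                    * CROP_DEFS["alfalfa"][1]
            n_fix += (NONSYMB["upland"] * group_area["upland"]
                      + NONSYMB["wetland_rice"] * group_area["wetland_rice"])
            # manure
            exc_n = exc_p = 0.0
            for cat, (rn, rp, _sh) in EXCRETION_RATES.items():
                if (cid, cat) in world.stocks:
                    h = float(world.stocks[(cid, cat)][t])
                    exc_n += h * rn
                    exc_p += h * rp
            stored = 1.0 - GRAZING_FRACTION - OUTSIDE_FRACTION - FUEL_FRACTION
            avail_n = exc_n * stored * (1.0 - STORAGE_NH3_LOSS)
            avail_p = exc_p * stored
            share = CROPLAND_SHARE[meta["income_class"]]
            crop_n = avail_n * share
            if meta["eu_member"] and atotal > 0:
                crop_n = min(crop_n, EU_CAP * atotal)
            crop_p = avail_p * crop_n / avail_n if avail_n > 0 else avail_p * share
            # fertilizer and deposition
            n_fert = float(world.fert[(cid, "N")][t])
            p_fert = float(world.fert[(cid, "P")][t])
            n_dep = dep2000_mass * float(world.dep_index[meta["region"]][t])
            # soil P runoff from cells
            p_in_rate = (p_fert + crop_p) / atotal
            p_up_rate = p_w / atotal
            p_runoff = 0.0
            for _, c in ccells.iterrows():
                pool = cellp[c["cell_id"]]
                recent = c["recent_fraction"] * p_in_rate
                ero = c["soil_loss"] * pool / SOIL_MASS_30CM
                repl = c["soil_loss"] * c["initial_P_content"]
                pool = pool + p_in_rate - p_up_rate - recent - ero + repl
                if pool < 0:
                    pool = 0.0
                cellp[c["cell_id"]] = pool
                p_runoff += (recent + ero) * c["crop_area_ha"]
            terms_rows[(cid, year)] = {
                "N_fix": n_fix, "N_dep": n_dep, "N_fert": n_fert,
                "N_man": crop_n, "N_withdr": n_w, "P_fert": p_fert,
                "P_man": crop_p, "P_withdr": p_w, "P_runoff": p_runoff,
                "area": atotal,
            }

    terms = pd.DataFrame.from_dict(terms_rows, orient="index")
    terms.index = pd.MultiIndex.from_tuples(terms.index, names=["unit_id", "year"])
    terms = terms.sort_index()
    terms["N_budget"] = (terms["N_fix"] + terms["N_dep"] + terms["N_fert"]
                         + terms["N_man"] - terms["N_withdr"])
    terms["P_budget"] = terms["P_fert"] + terms["P_man"] - terms["P_withdr"]
    terms["P_residual"] = terms["P_budget"] - terms["P_runoff"]

    # regional indicator series, ratios always recomputed from summed masses
    archetypes = ["world"] + sorted({world.meta[c]["archetype"]
                                     for c in world.countries})
    ind_rows = []
    for arch in archetypes:
        members = [c for c in world.countries
                   if arch == "world" or world.meta[c]["archetype"] == arch]
        cum = 0.0
        for year in years:
            tot = {k: 0.0 for k in ("N_fix", "N_dep", "N_fert", "N_man",
                                    "N_withdr", "P_fert", "P_man", "P_withdr",
                                    "P_runoff", "area")}
            for cid in members:
                row = terms_rows[(cid, year)]
                for k in tot:
                    tot[k] += row[k]
            n_in = tot["N_fix"] + tot["N_dep"] + tot["N_fert"] + tot["N_man"]
            p_in = tot["P_fert"] + tot["P_man"]
            nb = n_in - tot["N_withdr"]
            pb = p_in - tot["P_withdr"]
            pres = pb - tot["P_runoff"]
            cum += pres / 1.0e9
            ind_rows.append({
                "archetype": arch, "year": year, "area_ha": tot["area"],
                "N_budget_kg_ha": nb / tot["area"],
                "P_budget_kg_ha": pb / tot["area"],
                "P_residual_kg_ha": pres / tot["area"],
                "NUE": tot["N_withdr"] / n_in if n_in > 0 else math.nan,
                "PUE": tot["P_withdr"] / p_in if p_in > 0 else math.nan,
                "fixation_share": tot["N_fix"] / n_in if n_in > 0 else math.nan,
                "cumulative_residual_P_Tg": cum,
                "NP_fertilizer_molar_ratio":
                    (tot["N_fert"] / 14.007) / (tot["P_fert"] / 30.974)
                    if tot["P_fert"] > 0 else math.nan,
            })
    indicators = pd.DataFrame(ind_rows).set_index(["archetype", "year"]).sort_index()
    return terms, indicators


# ---------------------------------------------------------------------------
# Bundle writing (with optional missingness / subnational injection)
# ---------------------------------------------------------------------------


def _stat_rows(series: dict, unit_label: str, keep_mask) -> list:
    rows = []
    for (uid, item), arr in series.items():
        for keep, year, v in keep_mask(uid, item, arr):
            if keep:
                rows.append((uid, year, item, v, unit_label))
    return rows


def write_bundle(world: TrueWorld, spec: WorldSpec, out_dir) -> Path:
    """Write the pipeline-readable input bundle for a true world.

    Injects missing interior years (probability ``spec.missing_prob``) and
    perturbed subnational splits (``spec.subnational_perturb``); the national
    totals remain authoritative, as in the statistics being emulated.
    """
    out = Path(out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    (out / "config").mkdir(exist_ok=True)
    (out / "grid").mkdir(exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 917]))
    years = world.years

    def keep_years(n_years):
        keep = np.ones(n_years, dtype=bool)
        if spec.missing_prob > 0:
            keep[1:-1] = rng.random(n_years - 2) >= spec.missing_prob
        return keep

    def dump(series: dict, unit_label: str, path: Path,
             subnational_items: set | None = None) -> None:
        rows = []
        for (uid, item), arr in sorted(series.items()):
            keep = keep_years(len(arr))
            for t, y in enumerate(years):
                if keep[t]:
                    rows.append((uid, y, item, float(arr[t]), unit_label))
            # subnational split rows (perturbed; rescaled by the pipeline)
            if subnational_items is not None and item in subnational_items:
                subs = world.subunits.get(uid, [])
                if subs:
                    w = rng.uniform(0.5, 1.5, len(subs))
                    w /= w.sum()
                    for k, sid in enumerate(subs):
                        skeep = keep_years(len(arr))
                        for t, y in enumerate(years):
                            if not skeep[t]:
                                continue
                            pert = (np.exp(spec.subnational_perturb
                                           * rng.standard_normal())
                                    if spec.subnational_perturb > 0 else 1.0)
                            rows.append((sid, y, item,
                                         float(arr[t]) * w[k] * pert,
                                         unit_label))
        pd.DataFrame(rows, columns=STAT_COLUMNS).to_csv(path, index=False)

    # fodder statistics exist only nationally; other crops also subnationally
    non_fodder = {c for c in CROP_DEFS if not CROP_DEFS[c][3]}
    dump(world.production, "kg/yr", out / "tables" / "production.csv",
         subnational_items=non_fodder)
    dump(world.areas, "ha", out / "tables" / "area.csv",
         subnational_items=non_fodder)
    dump(world.stocks, "head", out / "tables" / "stocks.csv",
         subnational_items=set(EXCRETION_RATES))
    dump(world.fert, "kg/yr", out / "tables" / "fertilizer.csv")

    world.fubc.to_csv(out / "tables" / "fubc.csv", index=False)
    dep_rows = [(r, y, float(world.dep_index[r][t]))
                for r in sorted(world.dep_index)
                for t, y in enumerate(years)]
    pd.DataFrame(dep_rows, columns=["region", "year", "index"]).to_csv(
        out / "tables" / "deposition_index.csv", index=False)
    world.cells.to_csv(out / "grid" / "cells.csv", index=False)

    region_yaml = {"units": {
        uid: {"parent_country": uid.split("_s")[0], "region": m["region"],
              "archetype": m["archetype"], "income_class": m["income_class"],
              "eu_member": m["eu_member"]}
        for uid, m in sorted(world.meta.items())}}
    with open(out / "config" / "region_map.yml", "w") as fh:
        yaml.safe_dump(region_yaml, fh, sort_keys=True)

    params = {
        "crops": {c: {"group": g, "N_content": n, "P_content": p,
                      "is_fodder": f, "is_soybean": s}
                  for c, (g, n, p, f, s) in CROP_DEFS.items()},
        "excretion": {
            "rates": {c: {"N_excretion": rn, "P_excretion": rp}
                      for c, (rn, rp, _s) in EXCRETION_RATES.items()},
            "grazing_fraction": GRAZING_FRACTION,
            "outside_system_fraction": OUTSIDE_FRACTION,
            "fuel_other_fraction": FUEL_FRACTION,
            "storage_NH3_loss": STORAGE_NH3_LOSS,
            "cropland_share_high_income": CROPLAND_SHARE["high_income"],
            "cropland_share_developing": CROPLAND_SHARE["developing"],
            "eu_cap_kgN_per_ha_yr": EU_CAP,
        },
        "fixation": {
            "harvest_index": HARVEST_INDEX, "root_to_aboveground": ROOT_RATIO,
            "seed_N_pulse": SEED_N["pulses"], "seed_N_soybean": SEED_N["soybean"],
            "straw_N": STRAW_N, "root_N": ROOT_N,
            "fixation_coefficient": FIX_COEF,
            "nonsymbiotic_upland_kgN_per_ha_yr": NONSYMB["upland"],
            "nonsymbiotic_rice_kgN_per_ha_yr": NONSYMB["wetland_rice"],
        },
        "residues": {"burn_fraction": 0.10, "feed_fraction": 0.20},
        "soil": {"soil_mass_30cm": SOIL_MASS_30CM,
                 "weathering_Ea_J_mol": WEATHER_EA,
                 "weathering_T_ref_K": WEATHER_TREF},
        "fodder_classes": {"alfalfa": "cattle"},
        "stock_proxies": {"other": ["cattle", "sheep_goats"]},
    }
    with open(out / "config" / "params.yml", "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=True)
    return out


def generate_world(spec: WorldSpec, out_dir) -> tuple[Path, pd.DataFrame, pd.DataFrame]:
    """Build a synthetic world, write its input bundle, and return
    (bundle path, ground-truth terms, ground-truth indicators)."""
    world = build_true_world(spec)
    bundle = write_bundle(world, spec, out_dir)
    terms, indicators = naive_ground_truth(world)
    terms.to_csv(Path(out_dir) / "ground_truth_terms.csv")
    indicators.to_csv(Path(out_dir) / "ground_truth_indicators.csv")
    return bundle, terms, indicators


def generate_archetype_scenarios(seed: int = 0,
                                 n_countries: int = 8,
                                 cells_per_country: int = 6,
                                 ) -> dict[str, WorldSpec]:
    """The five shipped scenario worlds, one per regional archetype plus a
    mixed world, whose emergent indicator trajectories mirror the canonical
    regional patterns: rising-then-mined residual P in high-income
    countries, steep surplus build-up in China/India, the post-1990 input
    collapse of the transition economies, and near-zero budgets in
    sub-Saharan Africa."""
    specs = {}
    for k, arch in enumerate(("high_income", "china_india", "transition", "ssa")):
        specs[arch] = WorldSpec(
            seed=seed + k + 1,
            n_countries={arch: n_countries},
            cells_per_country=cells_per_country)
    specs["world"] = WorldSpec(
        seed=seed,
        n_countries={"high_income": n_countries // 2,
                     "china_india": 2,
                     "transition": n_countries // 2,
                     "ssa": n_countries // 2,
                     "other": n_countries // 2},
        cells_per_country=cells_per_country)
    return specs
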