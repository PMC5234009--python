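"""Core data structures and statistical plumbing for nutrient-budget accounting.

This module holds the containers and generic operations every budget term
builds on:

* :class:`StatTable` — long-format (unit, year, item, value) time series for
  crop production, harvested areas, livestock stocks and national fertilizer
  totals, in the style of FAOSTAT country tables.
* :class:`RegionMap` — country metadata: parent country for subnational units,
  reporting region, development archetype, income class and EU membership.
* :class:`GridField` — a global 0.5° × 0.5° raster with a validity mask and
  latitude-dependent cell areas.
* Gap filling (:func:`interpolate_gaps`), trend-based backcasting
  (:func:`backcast_with_proxy`), subnational-to-national scaling
  (:func:`scale_subnational`) and country-to-grid disaggregation
  (:func:`disaggregate_to_grid`).

Internal mass unit is kg throughout the package; reporting units are
kg/ha/yr and Tg (1 Tg = 1e9 kg). Unit conversions are centralized here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import xarray as xr
import yaml

logger = logging.getLogger("npbudget")

# ---------------------------------------------------------------------------
# Units and constants
# ---------------------------------------------------------------------------

KG_PER_TG = 1.0e9  #: 1 Tg = 10^12 g = 10^9 kg
M2_PER_HA = 1.0e4
EARTH_RADIUS_M = 6_371_000.0

#: atomic masses used for molar N:P ratios (g/mol)
ATOMIC_MASS_N = 14.007
ATOMIC_MASS_P = 30.974

#: default analysis window
FIRST_YEAR = 1970
LAST_YEAR = 2010

ARCHETYPES = ("world", "high_income", "china_india", "transition", "ssa", "other")
INCOME_CLASSES = ("high_income", "developing")


def kg_to_tg(kg: float) -> float:
    """Convert a mass in kg to teragrams."""
    return kg / KG_PER_TG


def tg_to_kg(tg: float) -> float:
    return tg * KG_PER_TG


# ---------------------------------------------------------------------------
# StatTable
# ---------------------------------------------------------------------------

STAT_COLUMNS = ["unit_id", "year", "item", "value", "unit"]


class StatTable:
    """Long-format statistics table keyed by (unit_id, year, item).

    ``unit_id`` is a country / state / province code, ``item`` a crop, animal
    category or nutrient code, ``value`` a non-negative quantity in the
    declared ``unit`` (e.g. ``kg/yr`` or ``head``).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in STAT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"StatTable missing columns: {missing}")
        df = df.loc[:, STAT_COLUMNS].copy()
        df["year"] = df["year"].astype(int)
        df["value"] = df["value"].astype(float)
        if (df["value"] < 0).any():
            bad = df.loc[df["value"] < 0].head()
            raise ValueError(f"negative values in StatTable:\n{bad}")
        if df.duplicated(["unit_id", "year", "item"]).any():
            dups = df.loc[df.duplicated(["unit_id", "year", "item"], keep=False)]
            raise ValueError(f"duplicate (unit_id, year, item) keys:\n{dups.head()}")
        self.df = df.reset_index(drop=True)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "StatTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    # -- access ------------------------------------------------------------
    def units(self) -> list[str]:
        return sorted(self.df["unit_id"].unique())

    def items(self) -> list[str]:
        return sorted(self.df["item"].unique())

    def series(self, unit_id: str, item: str) -> dict[int, float]:
        """Year → value mapping for one (unit, item) pair (may be gappy)."""
        sel = self.df[(self.df["unit_id"] == unit_id) & (self.df["item"] == item)]
        return dict(zip(sel["year"].astype(int), sel["value"].astype(float)))

    def pivot(self, item: str) -> pd.DataFrame:
        """Wide unit × year table for a single item."""
        sel = self.df[self.df["item"] == item]
        return sel.pivot(index="unit_id", columns="year", values="value")

    def complete(self, years: Iterable[int]) -> "StatTable":
        """Gap-fill every (unit, item) series onto ``years`` by linear
        interpolation between observed neighbours (observed values kept).

        Years outside a series' observed span are held at the nearest observed
        endpoint; such extensions are logged as fallbacks.  Use
        :func:`backcast_with_proxy` when a trend proxy is available instead.
        """
        years = sorted(int(y) for y in years)
        out = []
        unit_col = self.df["unit"].iloc[0] if len(self.df) else ""
        for (u, it), grp in self.df.groupby(["unit_id", "item"], sort=True):
            ser = dict(zip(grp["year"].astype(int), grp["value"]))
            obs = sorted(ser)
            inner = [y for y in years if obs[0] <= y <= obs[-1]]
            filled = interpolate_gaps(ser, inner) if inner else {}
            for y in years:
                if y in filled:
                    v = filled[y]
                elif y < obs[0]:
                    v = ser[obs[0]]
                    logger.debug("fallback: %s/%s held at %d value for %d", u, it, obs[0], y)
                else:
                    v = ser[obs[-1]]
                    logger.debug("fallback: %s/%s held at %d value for %d", u, it, obs[-1], y)
                out.append((u, y, it, v, grp["unit"].iloc[0] if len(grp) else unit_col))
        return StatTable(pd.DataFrame(out, columns=STAT_COLUMNS))


# ---------------------------------------------------------------------------
# RegionMap
# ---------------------------------------------------------------------------


@dataclass
class UnitInfo:
    parent_country: str
    region: str
    archetype: str
    income_class: str
    eu_member: bool = False

    def __post_init__(self):
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.income_class not in INCOME_CLASSES:
            raise ValueError(f"unknown income class {self.income_class!r}")


@dataclass
class RegionMap:
    """unit_id → region / archetype / income metadata.

    Archetypes follow the standard grouping for this analysis: high-income
    countries (USA, Canada, Western Europe, Japan, Australia, New Zealand),
    China+India, transition countries (Eastern Europe and former Soviet
    Union), sub-Saharan Africa (Africa excluding the northern tier and South
    Africa), and ``other``.
    """

    units: dict[str, UnitInfo] = field(default_factory=dict)

    def __getitem__(self, unit_id: str) -> UnitInfo:
        try:
            return self.units[unit_id]
        except KeyError:
            raise KeyError(f"unit {unit_id!r} not in RegionMap") from None

    def __contains__(self, unit_id: str) -> bool:
        return unit_id in self.units

    def countries(self) -> list[str]:
        """Top-level country codes (units that are their own parent)."""
        return sorted(u for u, i in self.units.items() if i.parent_country == u)

    def subunits(self, country: str) -> list[str]:
        return sorted(
            u for u, i in self.units.items() if i.parent_country == country and u != country
        )

    def archetype_members(self, archetype: str) -> list[str]:
        if archetype == "world":
            return self.countries()
        return sorted(
            u for u in self.countries() if self.units[u].archetype == archetype
        )

    @classmethod
    def from_yaml(cls, path) -> "RegionMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        units = {}
        for uid, rec in raw["units"].items():
            units[uid] = UnitInfo(
                parent_country=rec.get("parent_country", uid),
                region=rec["region"],
                archetype=rec["archetype"],
                income_class=rec["income_class"],
                eu_member=bool(rec.get("eu_member", False)),
            )
        return cls(units)

    def to_yaml(self, path) -> None:
        raw = {
            "units": {
                uid: {
                    "parent_country": i.parent_country,
                    "region": i.region,
                    "archetype": i.archetype,
                    "income_class": i.income_class,
                    "eu_member": i.eu_member,
                }
                for uid, i in self.units.items()
            }
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# GridField — global 0.5° raster
# ---------------------------------------------------------------------------

NLAT, NLON = 360, 720
CELL_DEG = 0.5


def lat_centers() -> np.ndarray:
    """Cell-center latitudes, row 0 at +89.75°."""
    return 89.75 - CELL_DEG * np.arange(NLAT)


def lon_centers() -> np.ndarray:
    """Cell-center longitudes, col 0 at −179.75°."""
    return -179.75 + CELL_DEG * np.arange(NLON)


def cell_area_ha() -> np.ndarray:
    """Cell area (ha) per latitude row from the spherical-cap band formula.

    Band area between latitudes φ1 < φ2 is 2πR²(sin φ2 − sin φ1); a 0.5° cell
    is 1/720 of the band.
    """
    lats = lat_centers()
    phi1 = np.deg2rad(lats - CELL_DEG / 2)
    phi2 = np.deg2rad(lats + CELL_DEG / 2)
    band = 2.0 * np.pi * EARTH_RADIUS_M**2 * (np.sin(phi2) - np.sin(phi1))
    return band / NLON / M2_PER_HA


class GridField:
    """A named 0.5° global raster (360 × 720) with validity mask and units.

    ``data`` holds the cell values; ``mask`` is True where the cell is valid.
    Masked cells are excluded from every aggregation.
    """

    def __init__(self, data: np.ndarray, mask: np.ndarray | None = None,
                 units: str = "", name: str = "field"):
        data = np.asarray(data, dtype=float)
        if data.shape != (NLAT, NLON):
            raise ValueError(f"GridField must be {NLAT}x{NLON}, got {data.shape}")
        if mask is None:
            mask = np.isfinite(data)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (NLAT, NLON):
            raise ValueError("mask shape mismatch")
        self.data = np.where(mask, data, np.nan)
        self.mask = mask
        self.units = units
        self.name = name

    @classmethod
    def zeros(cls, units: str = "", name: str = "field") -> "GridField":
        return cls(np.zeros((NLAT, NLON)), np.ones((NLAT, NLON), bool), units, name)

    @classmethod
    def full_like(cls, other: "GridField", value: float, units: str = "",
                  name: str = "field") -> "GridField":
        return cls(np.full((NLAT, NLON), value), other.mask.copy(), units, name)

    # -- aggregation & conversion -----------------------------------------
    def total(self) -> float:
        """Sum of valid cell values."""
        return float(np.nansum(np.where(self.mask, self.data, 0.0)))

    def area_ha(self) -> np.ndarray:
        """Full (360, 720) array of cell areas in ha."""
        return np.broadcast_to(cell_area_ha()[:, None], (NLAT, NLON)).copy()

    def rate_to_mass(self, area: "GridField | None" = None) -> "GridField":
        """Per-ha rate → per-cell mass. ``area`` gives ha per cell (e.g.
        cropland area); default is the full geometric cell area."""
        a = area.data if area is not None else self.area_ha()
        return GridField(self.data * a, self.mask & (np.isfinite(a)),
                         self.units.replace("/ha", ""), self.name)

    def mass_to_rate(self, area: "GridField | None" = None) -> "GridField":
        a = area.data if area is not None else self.area_ha()
        with np.errstate(divide="ignore", invalid="ignore"):
            out = self.data / a
        return GridField(out, self.mask & (a > 0), self.units + "/ha", self.name)

    # -- I/O ---------------------------------------------------------------
    def to_dataarray(self) -> xr.DataArray:
        return xr.DataArray(
            self.data, dims=("lat", "lon"),
            coords={"lat": lat_centers(), "lon": lon_centers()},
            name=self.name, attrs={"units": self.units},
        )

    def to_netcdf(self, path) -> None:
        self.to_dataarray().to_netcdf(path)

    @classmethod
    def from_netcdf(cls, path, var: str | None = None) -> "GridField":
        ds = xr.open_dataset(path)
        name = var or list(ds.data_vars)[0]
        da = ds[name]
        gf = cls(da.values, units=str(da.attrs.get("units", "")), name=name)
        ds.close()
        return gf

    def to_text(self, path) -> None:
        """Plain-text matrix (NaN for masked cells) — test-friendly format."""
        np.savetxt(path, self.data, fmt="%.10g")

    @classmethod
    def from_text(cls, path, units: str = "", name: str = "field") -> "GridField":
        return cls(np.loadtxt(path), units=units, name=name)


# ---------------------------------------------------------------------------
# Gap filling and scaling operations
# ---------------------------------------------------------------------------


def interpolate_gaps(series: Mapping[int, float],
                     years: Iterable[int] | None = None) -> dict[int, float]:
    """Linearly interpolate missing interior years of a year → value series.

    Observed years pass through unchanged; requested years must lie inside the
    observed span (extrapolation is the job of :func:`backcast_with_proxy`).
    """
    if not series:
        raise ValueError("cannot interpolate an empty series")
    obs_years = np.array(sorted(series), dtype=float)
    obs_vals = np.array([series[int(y)] for y in obs_years], dtype=float)
    if years is None:
        years = range(int(obs_years[0]), int(obs_years[-1]) + 1)
    years = [int(y) for y in years]
    lo, hi = obs_years[0], obs_years[-1]
    outside = [y for y in years if y < lo or y > hi]
    if outside:
        raise ValueError(
            f"years {outside} outside observed span [{int(lo)}, {int(hi)}]; "
            "use backcast_with_proxy for extrapolation"
        )
    vals = np.interp(np.array(years, dtype=float), obs_years, obs_vals)
    out = {y: float(v) for y, v in zip(years, vals)}
    # exact pass-through of observed values
    for y in years:
        if y in series:
            out[y] = float(series[y])
    return out


def backcast_with_proxy(target: Mapping[int, float], proxy: Mapping[int, float],
                        years: Iterable[int] | None = None) -> dict[int, float]:
    """Extend a series beyond its observed span using the trend of a proxy.

    A year outside the target's span gets
    ``anchor_value * proxy[year] / proxy[anchor]`` where the anchor is the
    target's earliest (for backcasting) or latest (for forecasting) observed
    year. This is the standard trick for filling missing animal-stock years
    from the trend in the stocks of the other animal categories.
    """
    if not target:
        raise ValueError("target series is empty")
    obs = sorted(target)
    first, last = obs[0], obs[-1]
    if years is None:
        years = [y for y in sorted(proxy) if y < first or y > last]
    out = {int(y): float(v) for y, v in target.items()}
    for y in years:
        y = int(y)
        if first <= y <= last:
            continue
        anchor = first if y < first else last
        if y not in proxy or anchor not in proxy:
            raise ValueError(f"proxy does not cover year {y} and anchor {anchor}")
        if proxy[anchor] == 0:
            raise ValueError(f"proxy is zero at anchor year {anchor}: ratio undefined")
        out[y] = float(target[anchor]) * float(proxy[y]) / float(proxy[anchor])
        logger.debug("backcast %d from anchor %d via proxy ratio %.4g",
                     y, anchor, proxy[y] / proxy[anchor])
    return out


def scale_subnational(subnational: Mapping[str, float],
                      national_total: float) -> dict[str, float]:
    """Scale subnational values so their sum matches the national total.

    Proportions are preserved; the output sum equals ``national_total``
    exactly (to floating-point precision).
    """
    total = float(sum(subnational.values()))
    if national_total == 0:
        return {k: 0.0 for k in subnational}
    if total <= 0:
        raise ValueError(
            "subnational sum is zero with a positive national total: "
            "no distribution key"
        )
    f = float(national_total) / total
    return {k: float(v) * f for k, v in subnational.items()}


def disaggregate_to_grid(country_value: float, weights: GridField) -> GridField:
    """Distribute a country total over grid cells proportionally to weights.

    Cell value = total × weight / Σweights; the sum over cells reproduces the
    country total. A zero total yields an all-zero field.
    """
    w = np.where(weights.mask, weights.data, 0.0)
    if (w < 0).any():
        raise ValueError("negative disaggregation weights")
    wsum = w.sum()
    if country_value == 0:
        return GridField(np.zeros((NLAT, NLON)), weights.mask.copy(),
                         weights.units, weights.name)
    if wsum <= 0:
        raise ValueError("zero weight sum: cannot disaggregate a nonzero total")
    return GridField(country_value * w / wsum, weights.mask.copy(),
                     weights.units, weights.name)
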