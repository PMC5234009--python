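"""Animal manure N and P: excretion, storage losses, and allocation.

Manure production is animal stocks × constant per-head excretion rates.
The cropland input excludes manure excreted during grazing, manure deposited
outside the agricultural system, and manure used as fuel; what remains is
the stored/collected fraction, from which 20% of N volatilizes as NH3 in
storage (P has no gas phase and is conserved). Available manure is split
between cropland and grassland: 50% to cropland in high-income countries,
95% in developing countries, with EU members subject to a maximum cropland
application rate (Nitrates-directive style cap, default 170 kg N/ha/yr);
N above the cap spills to grassland and P follows N proportionally within
each destination.

Shipped excretion rates are documented placeholders, overridable from YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd
import yaml

from .core_data import StatTable


@dataclass
class CategoryRates:
    N_excretion: float  # kg N / head / yr
    P_excretion: float  # kg P / head / yr


@dataclass
class ExcretionParams:
    rates: dict[str, CategoryRates] = field(default_factory=dict)
    #: fraction of excretion deposited in the meadow during grazing
    grazing_fraction: float = 0.30
    #: fraction excreted outside the agricultural system (urban, roadside, lagoons)
    outside_system_fraction: float = 0.10
    #: fraction used as fuel or for other purposes
    fuel_other_fraction: float = 0.05
    #: NH3-N volatilized from storage systems
    storage_NH3_loss: float = 0.20
    cropland_share_high_income: float = 0.50
    cropland_share_developing: float = 0.95
    #: maximum cropland application rate for EU members, kg N/ha/yr
    eu_cap_kgN_per_ha_yr: float = 170.0

    def __post_init__(self):
        for nm in ("grazing_fraction", "outside_system_fraction",
                   "fuel_other_fraction", "storage_NH3_loss",
                   "cropland_share_high_income", "cropland_share_developing"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm}={v} outside [0, 1]")
        s = (self.grazing_fraction + self.outside_system_fraction
             + self.fuel_other_fraction)
        if s > 1.0:
            raise ValueError(f"grazing+outside+fuel fractions sum to {s} > 1")

    @classmethod
    def default(cls) -> "ExcretionParams":
        return cls(rates={
            "cattle":      CategoryRates(50.0, 8.0),
            "dairy":       CategoryRates(70.0, 10.0),
            "pigs":        CategoryRates(12.0, 3.0),
            "poultry":     CategoryRates(0.5, 0.15),
            "sheep_goats": CategoryRates(8.0, 1.5),
            "other":       CategoryRates(40.0, 6.0),
        })

    @classmethod
    def from_yaml(cls, path) -> "ExcretionParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        rates = {k: CategoryRates(**v) for k, v in raw.pop("rates").items()}
        return cls(rates=rates, **raw)


def excretion(stocks: StatTable, params: ExcretionParams) -> pd.DataFrame:
    """Total manure production per (unit, year): Σ categories stocks × rate.

    Returns a DataFrame indexed (unit_id, year) with columns
    ``manure_N`` and ``manure_P`` in kg/yr.
    """
    unknown = sorted(set(stocks.items()) - set(params.rates))
    if unknown:
        raise KeyError(f"animal categories without excretion rates: {unknown}")
    df = stocks.df
    n_rate = df["item"].map(lambda c: params.rates[c].N_excretion)
    p_rate = df["item"].map(lambda c: params.rates[c].P_excretion)
    out = pd.DataFrame({
        "unit_id": df["unit_id"], "year": df["year"],
        "manure_N": df["value"] * n_rate,
        "manure_P": df["value"] * p_rate,
    })
    return out.groupby(["unit_id", "year"]).sum(numeric_only=True).sort_index()


def available_for_application(total_N: float, total_P: float,
                              params: ExcretionParams) -> tuple[float, float]:
    """Manure available for spreading after exclusions and storage NH3 loss.

    stored = total × (1 − grazing − outside − fuel); available N is stored N
    minus the 20% storage volatilization; P is conserved in storage.
    """
    if total_N < 0 or total_P < 0:
        raise ValueError("totals must be non-negative")
    stored_frac = 1.0 - (params.grazing_fraction
                         + params.outside_system_fraction
                         + params.fuel_other_fraction)
    if stored_frac < 0:
        raise ValueError("loss fractions sum above 1")
    n_avail = total_N * stored_frac * (1.0 - params.storage_NH3_loss)
    p_avail = total_P * stored_frac
    return n_avail, p_avail


def allocate_manure(avail_N: float, avail_P: float, income_class: str,
                    cropland_area_ha: float, eu_member: bool,
                    params: ExcretionParams) -> dict[str, float]:
    """Split available manure between cropland and grassland.

    The cropland share is 0.50 for high-income and 0.95 for developing
    units. For EU members the cropland N application rate is capped; excess
    N spills to grassland and P follows N proportionally within each
    destination. Mass is conserved exactly.
    """
    if income_class == "high_income":
        share = params.cropland_share_high_income
    elif income_class == "developing":
        share = params.cropland_share_developing
    else:
        raise ValueError(f"unknown income class {income_class!r}")
    crop_n = avail_N * share
    if eu_member and cropland_area_ha > 0:
        cap_mass = params.eu_cap_kgN_per_ha_yr * cropland_area_ha
        crop_n = min(crop_n, cap_mass)
    grass_n = avail_N - crop_n
    if avail_N > 0:
        crop_p = avail_P * crop_n / avail_N
    else:
        crop_p = avail_P * share
    return {
        "cropland_N": crop_n, "cropland_P": crop_p,
        "grassland_N": grass_n, "grassland_P": avail_P - crop_p,
    }


def fill_stock_gaps(stocks: StatTable, years, proxy_categories: Mapping[str, tuple[str, ...]]
                    | None = None) -> StatTable:
    """Complete stock series onto ``years``: interior gaps by linear
    interpolation; years before/after a category's span by the trend of a
    proxy (sum of the configured proxy categories, e.g. cattle + sheep/goats
    for minor classes), falling back to endpoint persistence when no proxy
    covers the gap."""
    from .core_data import STAT_COLUMNS, backcast_with_proxy, interpolate_gaps
    years = sorted(int(y) for y in years)
    proxy_categories = proxy_categories or {}
    out_rows = []
    df = stocks.df
    for u, grp in df.groupby("unit_id", sort=True):
        cat_series = {
            it: dict(zip(g["year"].astype(int), g["value"]))
            for it, g in grp.groupby("item")
        }
        for it, ser in cat_series.items():
            obs = sorted(ser)
            inner = [y for y in years if obs[0] <= y <= obs[-1]]
            filled = interpolate_gaps(ser, inner) if inner else dict(ser)
            outer = [y for y in years if y < obs[0] or y > obs[-1]]
            if outer:
                proxy = None
                names = proxy_categories.get(it)
                if names:
                    present = [n for n in names if n in cat_series]
                    if present:
                        pyears = set.intersection(*(set(cat_series[n]) for n in present))
                        proxy = {y: sum(cat_series[n][y] for n in present)
                                 for y in pyears}
                covered = proxy is not None and all(
                    y in proxy for y in outer) and (
                    (obs[0] in proxy) if any(y < obs[0] for y in outer) else True) and (
                    (obs[-1] in proxy) if any(y > obs[-1] for y in outer) else True)
                if covered:
                    filled.update({y: v for y, v in
                                   backcast_with_proxy(ser, proxy, outer).items()
                                   if y in outer})
                else:
                    for y in outer:
                        filled[y] = ser[obs[0]] if y < obs[0] else ser[obs[-1]]
            unit = grp.loc[grp["item"] == it, "unit"].iloc[0]
            out_rows.extend((u, y, it, filled[y], unit) for y in years)
    return StatTable(pd.DataFrame(out_rows, columns=STAT_COLUMNS))
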