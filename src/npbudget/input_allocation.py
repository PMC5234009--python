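"""Fertilizer distribution over crop groups and atmospheric N deposition.

National fertilizer totals (from FAOSTAT-style statistics) are distributed
over the three crop groups using fertilizer-use-by-crop (FUBC) application
rates anchored in the year 2000. Countries without survey data inherit the
area-weighted regional mean rate. For years other than 2000 the group shares
are scaled by the group's nutrient yield (kg nutrient per ha) relative to
2000, so fertilizer follows where crop nutrient removal grows; shares are
renormalized so the national total is conserved exactly.

Atmospheric N deposition is a base-year (2000) gridded field scaled per
region and year by an N-gas emission index (index = 1 in 2000). P deposition
is a minor flux globally and is set to zero.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .core_data import GridField, RegionMap
from .crop_uptake import CROP_GROUPS

#: guardrails on the yield-based temporal scaling factor
YIELD_SCALING_CLIP = (0.1, 10.0)

FUBC_COLUMNS = ["country", "group", "nutrient", "rate", "area"]


class FUBCRates:
    """Per (country, crop group, nutrient): application rate (kg/ha) in the
    anchor year 2000 and the fertilized area (ha)."""

    ANCHOR_YEAR = 2000

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in FUBC_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"FUBCRates missing columns: {missing}")
        df = df.loc[:, FUBC_COLUMNS].copy()
        if (df["rate"] < 0).any() or (df["area"] < 0).any():
            raise ValueError("FUBC rates and areas must be non-negative")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "FUBCRates":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def rate(self, country: str, group: str, nutrient: str) -> float | None:
        sel = self.df[(self.df["country"] == country)
                      & (self.df["group"] == group)
                      & (self.df["nutrient"] == nutrient)]
        if sel.empty:
            return None
        return float(sel["rate"].iloc[0])


def fill_missing_rates(rates: FUBCRates, region_map: RegionMap,
                       countries: list[str] | None = None,
                       nutrients: tuple[str, ...] = ("N", "P")) -> FUBCRates:
    """Assign the area-weighted regional mean rate to countries without data.

    Existing entries are never overwritten. A region with no data at all for
    some (group, nutrient) is an error — there is no rate to average.
    """
    df = rates.df.copy()
    if countries is None:
        countries = sorted(df["country"].unique())
    have = set(zip(df["country"], df["group"], df["nutrient"]))
    region_of = {c: region_map[c].region for c in countries}
    # area-weighted mean per (region, group, nutrient)
    df["_region"] = df["country"].map(lambda c: region_map[c].region
                                      if c in region_map else None)
    grp = df.dropna(subset=["_region"]).groupby(["_region", "group", "nutrient"])
    wsum = grp.apply(lambda g: float((g["rate"] * g["area"]).sum()),
                     include_groups=False)
    asum = grp["area"].sum()
    new_rows = []
    for c in countries:
        for g in CROP_GROUPS:
            for nut in nutrients:
                if (c, g, nut) in have:
                    continue
                key = (region_of[c], g, nut)
                if key not in asum.index:
                    raise ValueError(
                        f"region {region_of[c]!r} has no FUBC data for "
                        f"group={g!r}, nutrient={nut!r}; cannot fall back")
                if asum[key] > 0:
                    mean_rate = wsum[key] / asum[key]
                else:
                    # all survey areas zero: unweighted mean of reported rates
                    sel = df[(df["_region"] == region_of[c])
                             & (df["group"] == g) & (df["nutrient"] == nut)]
                    mean_rate = float(sel["rate"].mean())
                new_rows.append((c, g, nut, mean_rate, 0.0))
    if not new_rows:
        return FUBCRates(df.drop(columns="_region"))
    out = pd.concat([df.drop(columns="_region"),
                     pd.DataFrame(new_rows, columns=FUBC_COLUMNS)],
                    ignore_index=True)
    return FUBCRates(out)


def distribute_fertilizer(national_total: float, areas: Mapping[str, float],
                          rates2000: Mapping[str, float],
                          yield_scaling: Mapping[str, float] | None = None,
                          ) -> dict[str, float]:
    """Split a national fertilizer total (kg/yr) over crop groups.

    Group share ∝ rate2000 × area × yield_scaling, then normalized so the
    group masses sum to the national total exactly. ``yield_scaling`` is the
    group nutrient yield in the target year relative to 2000 (≡ 1 in the
    anchor year), clipped to [0.1, 10] to keep shares finite on sparse data.
    A group with zero area receives nothing.
    """
    if national_total < 0:
        raise ValueError("national_total must be non-negative")
    groups = list(areas)
    scal = {g: 1.0 for g in groups} if yield_scaling is None else {
        g: float(np.clip(yield_scaling.get(g, 1.0), *YIELD_SCALING_CLIP))
        for g in groups}
    key = {g: rates2000.get(g, 0.0) * areas[g] * scal[g] for g in groups}
    ksum = sum(key.values())
    if national_total == 0:
        return {g: 0.0 for g in groups}
    if ksum <= 0:
        raise ValueError("zero distribution key for a nonzero fertilizer total")
    return {g: national_total * key[g] / ksum for g in groups}


def scale_deposition(base: GridField, emission_index: Mapping[str, Mapping[int, float]],
                     year: int, cell_region: np.ndarray) -> GridField:
    """Scale the year-2000 N deposition field to ``year``.

    ``emission_index[region][year]`` is the dimensionless N-gas emission
    index (1 in 2000); ``cell_region`` assigns each grid cell its region
    (object array of region codes, None/'' outside).
    """
    factor = np.ones_like(base.data)
    regions = {r for r in np.unique(cell_region[base.mask]) if r}
    for r in regions:
        try:
            f = emission_index[r][year]
        except KeyError:
            raise KeyError(f"no emission index for region {r!r}, year {year}") from None
        factor[cell_region == r] = f
    return GridField(base.data * factor, base.mask.copy(), base.units, base.name)
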