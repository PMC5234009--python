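"""Crop grouping and nutrient withdrawal in harvested parts.

Crops are grouped into three classes — legumes, wetland rice and upland
crops — and the N and P mass withdrawn from the field by harvest is the
product of production and the crop's nutrient content. Harvested fodder
crops, including leguminous fodders (clover, alfalfa, silage legumes), are
counted with the upland group. Seed flows are budget neutral by construction
and never appear as terms.

Crop residue burning and feed use are computed as diagnostics only: the
default budget ignores them (a small, documented underestimate of
withdrawal), with a pipeline switch to include them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd
import yaml

from .core_data import StatTable, scale_subnational

CROP_GROUPS = ("legume", "wetland_rice", "upland")

#: animal categories defining the spatial distribution key for each fodder
#: class: "cattle" fodders follow cattle+dairy, "all" fodders add pigs.
FODDER_CLASS_ANIMALS = {
    "cattle": ("cattle", "dairy"),
    "all": ("cattle", "dairy", "pigs"),
}


@dataclass
class CropInfo:
    group: str
    N_content: float          # fraction of harvested mass
    P_content: float
    residue_N_content: float = 0.008
    residue_P_content: float = 0.001
    residue_ratio: float = 1.0  # residue mass : harvested mass
    is_fodder: bool = False
    is_soybean: bool = False

    def __post_init__(self):
        if self.group not in CROP_GROUPS:
            raise ValueError(f"unknown crop group {self.group!r}")
        for nm in ("N_content", "P_content", "residue_N_content", "residue_P_content"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 0.15:
                raise ValueError(f"{nm}={v} outside [0, 0.15]")


@dataclass
class CropParams:
    """crop_id → :class:`CropInfo`; shipped defaults are editable placeholders
    (cereal grain 2.0% N / 0.35% P etc.), overridable from YAML."""

    crops: dict[str, CropInfo] = field(default_factory=dict)

    def __getitem__(self, crop_id: str) -> CropInfo:
        return self.crops[crop_id]

    def __contains__(self, crop_id: str) -> bool:
        return crop_id in self.crops

    @classmethod
    def default(cls) -> "CropParams":
        return cls({
            "wheat":   CropInfo("upland", 0.020, 0.0035),
            "maize":   CropInfo("upland", 0.015, 0.0030),
            "rice":    CropInfo("wetland_rice", 0.012, 0.0030),
            "soybean": CropInfo("legume", 0.062, 0.0060, is_soybean=True),
            "pulses":  CropInfo("legume", 0.035, 0.0040),
            "alfalfa": CropInfo("legume", 0.025, 0.0025, is_fodder=True),
        })

    @classmethod
    def from_dict(cls, raw: Mapping) -> "CropParams":
        return cls({cid: CropInfo(**rec) for cid, rec in raw.items()})

    @classmethod
    def from_yaml(cls, path) -> "CropParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {cid: vars(info).copy() for cid, info in self.crops.items()}


def effective_group(info: CropInfo) -> str:
    """Reporting group for budget aggregation: fodder crops (incl. leguminous
    fodders) are counted with upland crops."""
    return "upland" if info.is_fodder else info.group


def compute_uptake(production: StatTable, area: StatTable,
                   params: CropParams) -> pd.DataFrame:
    """N and P withdrawal by harvest, aggregated to the three crop groups.

    Parameters
    ----------
    production : StatTable with item = crop id, value = harvested mass (kg/yr)
    area : StatTable with item = crop id, value = harvested area (ha)
    params : nutrient contents and grouping

    Returns
    -------
    DataFrame indexed (unit_id, year, group) with columns
    ``N_withdrawal`` (kg N), ``P_withdrawal`` (kg P), ``harvested_area`` (ha).
    """
    unknown = sorted(set(production.items()) - set(params.crops))
    if unknown:
        raise KeyError(f"crops without parameters: {unknown}")

    prod = production.df
    info = {c: params[c] for c in params.crops}
    group = prod["item"].map(lambda c: effective_group(info[c]))
    ncont = prod["item"].map(lambda c: info[c].N_content)
    pcont = prod["item"].map(lambda c: info[c].P_content)
    per_crop = pd.DataFrame({
        "unit_id": prod["unit_id"], "year": prod["year"], "group": group,
        "N_withdrawal": prod["value"] * ncont,
        "P_withdrawal": prod["value"] * pcont,
    })
    up = per_crop.groupby(["unit_id", "year", "group"]).sum(numeric_only=True)

    ar = area.df
    known = ar["item"].isin(info)
    ar = ar[known]
    agr = ar["item"].map(lambda c: effective_group(info[c]))
    areas = (
        pd.DataFrame({"unit_id": ar["unit_id"], "year": ar["year"],
                      "group": agr, "harvested_area": ar["value"]})
        .groupby(["unit_id", "year", "group"]).sum(numeric_only=True)
    )
    out = up.join(areas, how="outer").fillna(0.0)
    return out.sort_index()


def allocate_fodder(national_fodder: float,
                    livestock_weights: Mapping[str, float]) -> dict[str, float]:
    """Split national fodder production over subunits proportionally to
    livestock stocks (the configured animal categories for the fodder class).

    This mirrors how fodder statistics, absent at state/province level, are
    distributed following cattle, dairy and pig numbers.
    """
    return scale_subnational(livestock_weights, national_fodder)


def residue_flows(production: StatTable, params: CropParams,
                  burn_fraction: float, feed_fraction: float) -> pd.DataFrame:
    """Diagnostic N/P flows in crop residues: burning loss and feed removal.

    N in burned residues is lost to the atmosphere; P has no gas phase and is
    returned to the soil in the ash, so the P burning loss is identically
    zero. Residue mass is production × residue_ratio per crop. These flows
    are NOT part of the default withdrawal term.

    Returns a DataFrame indexed (unit_id, year) with columns
    ``N_burned``, ``N_fed``, ``P_fed`` (kg/yr).
    """
    for nm, v in (("burn_fraction", burn_fraction), ("feed_fraction", feed_fraction)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{nm}={v} outside [0, 1]")
    if burn_fraction + feed_fraction > 1.0:
        raise ValueError("burn_fraction + feed_fraction exceeds 1")
    prod = production.df
    info = {c: params[c] for c in params.crops}
    res_mass = prod["value"] * prod["item"].map(lambda c: info[c].residue_ratio)
    res_n = res_mass * prod["item"].map(lambda c: info[c].residue_N_content)
    res_p = res_mass * prod["item"].map(lambda c: info[c].residue_P_content)
    flows = pd.DataFrame({
        "unit_id": prod["unit_id"], "year": prod["year"],
        "N_burned": res_n * burn_fraction,
        "N_fed": res_n * feed_fraction,
        "P_fed": res_p * feed_fraction,  # P burning loss is zero by definition
    })
    return flows.groupby(["unit_id", "year"]).sum(numeric_only=True).sort_index()
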