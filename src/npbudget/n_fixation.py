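"""Biological nitrogen fixation estimated from legume harvest statistics.

Symbiotic fixation by grain legumes (pulses, groundnuts, soybean) is derived
from the N in the harvested product: with a harvest index of 0.5 and a
root:aboveground ratio of 0.19 the grain, straw and root biomass follow from
grain mass, and total plant N from component N contents (seed 3.5%, soybean
seed 6.2%, straw and roots 0.8%). Fixation is then either a fixed 0.6
fraction of plant N (the default) or the soybean regression
0.66 × plant-N − 19 kg N/ha, clamped at zero.

Fodder legumes fix their entire harvested N; non-leguminous cropland receives
a background non-symbiotic rate of 5 kg N/ha/yr, and wetland rice 25.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class FixationParams:
    harvest_index: float = 0.5            # grain : aboveground biomass
    root_to_aboveground: float = 0.19
    seed_N_pulse: float = 0.035
    seed_N_soybean: float = 0.062
    straw_N: float = 0.008
    root_N: float = 0.008
    fixation_coefficient: float = 0.6     # fixed N : plant N
    salvagiotti_slope: float = 0.66
    salvagiotti_intercept_kgN_per_ha: float = 19.0
    nonsymbiotic_upland_kgN_per_ha_yr: float = 5.0
    nonsymbiotic_rice_kgN_per_ha_yr: float = 25.0

    def __post_init__(self):
        if not 0.0 < self.harvest_index <= 1.0:
            raise ValueError("harvest_index must be in (0, 1]")
        for nm, v in vars(self).items():
            if v < 0:
                raise ValueError(f"{nm} must be non-negative, got {v}")


def plant_nitrogen(grain_mass: float, is_soybean: bool,
                   params: FixationParams | None = None) -> float:
    """Total N (kg) in grain + straw + roots of a grain legume crop.

    aboveground = grain / HI; straw = aboveground − grain;
    roots = root_ratio × aboveground; plant N = Σ component mass × N content.
    Works equally per hectare (kg/ha in → kg N/ha out) or per country
    (kg in → kg N out) since every step is linear in grain mass; accepts
    scalars or numpy arrays.
    """
    import numpy as np
    if np.any(np.asarray(grain_mass) < 0):
        raise ValueError("grain_mass must be non-negative")
    p = params or FixationParams()
    aboveground = grain_mass / p.harvest_index
    straw = aboveground - grain_mass
    roots = p.root_to_aboveground * aboveground
    seed_n = p.seed_N_soybean if is_soybean else p.seed_N_pulse
    return grain_mass * seed_n + straw * p.straw_N + roots * p.root_N


def legume_fixation(plant_N: float, mode: str = "coefficient",
                    params: FixationParams | None = None) -> float:
    """N fixed by a grain legume, from its total plant N.

    ``coefficient`` mode (default): 0.6 × plant N — linear in yield, so any
    change in fixation is the result of yield changes.
    ``salvagiotti`` mode: max(0, 0.66 × plant N − 19) with plant N in
    kg N/ha (the regression's printed units); negative predictions at very
    low plant N are clamped to zero.
    """
    if plant_N < 0:
        raise ValueError("plant_N must be non-negative")
    p = params or FixationParams()
    if mode == "coefficient":
        return p.fixation_coefficient * plant_N
    if mode == "salvagiotti":
        return max(0.0, p.salvagiotti_slope * plant_N
                   - p.salvagiotti_intercept_kgN_per_ha)
    raise ValueError(f"unknown fixation mode {mode!r}")


def fodder_legume_fixation(fodder_production: float,
                           fodder_N_content: float) -> float:
    """Fixation by leguminous fodder crops (clover, alfalfa, silage legumes):
    assumed equal to the harvested fodder N (production × N content), and
    attributed to the upland group where fodders are counted."""
    if fodder_production < 0 or fodder_N_content < 0:
        raise ValueError("inputs must be non-negative")
    return fodder_production * fodder_N_content


def nonsymbiotic_fixation(upland_area: float, rice_area: float,
                          params: FixationParams | None = None) -> float:
    """Background non-symbiotic fixation: 5 kg N/ha/yr on non-leguminous
    upland cropland and 25 kg N/ha/yr on wetland rice."""
    if upland_area < 0 or rice_area < 0:
        raise ValueError("areas must be non-negative")
    p = params or FixationParams()
    return (p.nonsymbiotic_upland_kgN_per_ha_yr * upland_area
            + p.nonsymbiotic_rice_kgN_per_ha_yr * rice_area)
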