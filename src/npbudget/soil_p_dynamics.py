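"""Runoff nutrient losses and the top-30-cm residual soil P pool.

Three loss pathways are represented per grid cell:

* losses from recent nutrient applications (a fixed fraction of the year's
  P inputs reaching runoff);
* erosion of soil material — N in eroded soil follows the (time-constant)
  soil organic C content through land-use specific C:N ratios (arable 12,
  grassland 14, natural vegetation 14); P in eroded soil follows the current
  P concentration of the top-30-cm pool;
* a background weathering P flux to surface water via subsurface runoff and
  aquifers, from a lithology-class P concentration, water runoff, a soil
  shielding factor and an Arrhenius temperature correction.

The soil P budget operates on the top 30 cm: each year the pool gains the
agronomic inputs, loses crop uptake and the two runoff pathways tied to the
topsoil (recent-input runoff and erosion), and is replenished at the bottom
with fresh soil material carrying the initial (year-1900) P concentration to
replace the eroded mass. The weathering flux bypasses the agronomic topsoil
pool and is reported as a separate delivery to water. A pool cannot go
negative: unmet withdrawal is recorded as a mining deficit.

All functions accept scalars or equally-shaped numpy arrays, so a whole
raster of cells can be stepped at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

#: soil C:N ratio of eroded material by land use
C_TO_N_BY_LAND_USE = {"arable": 12.0, "grassland": 14.0, "natural": 14.0}

#: kg soil per ha in the top 30 cm (bulk density 1.3 g/cm3 x 0.3 m)
DEFAULT_SOIL_MASS_30CM = 3.9e6

#: mg/L x mm/yr -> kg/ha/yr
MG_L_MM_TO_KG_HA = 0.01

R_GAS = 8.314  # J/mol/K


@dataclass
class WeatheringParams:
    activation_energy_J_mol: float = 50_000.0
    T_ref_K: float = 284.15


@dataclass
class CellSoil:
    """State and static properties of one cropland cell's top 30 cm."""

    soil_loss: Any = 0.0              # kg soil/ha/yr eroded
    P_pool: Any = 0.0                 # kg P/ha in top 30 cm
    initial_P_content: Any = 0.0      # kg P/kg soil (year-1900 inventory)
    soil_mass_30cm: Any = DEFAULT_SOIL_MASS_30CM  # kg soil/ha
    soil_C_content: Any = 0.02        # kg C/kg soil, constant in time
    land_use: str = "arable"
    recent_input_runoff_fraction: Any = 0.10
    lithology_P_conc: Any = 0.01      # mg P/L in aquifer runoff
    shielding: Any = 1.0              # [0, 1] soil shielding correction
    runoff_depth: Any = 300.0         # mm/yr
    MAT: Any = 11.0                   # mean annual temperature, degC

    @property
    def c_to_n(self) -> float:
        return C_TO_N_BY_LAND_USE[self.land_use]


def erosion_n_loss(cell: CellSoil):
    """N in eroded soil material (kg N/ha/yr): soil loss × C content / C:N."""
    return cell.soil_loss * cell.soil_C_content / cell.c_to_n


def erosion_p_loss(cell: CellSoil):
    """P in eroded soil material (kg P/ha/yr): soil loss × current pool
    concentration (P_pool / soil mass of the 30 cm layer)."""
    return cell.soil_loss * cell.P_pool / cell.soil_mass_30cm


def recent_input_runoff(P_inputs, fraction):
    """Runoff loss from the current year's P applications: fraction × inputs."""
    frac = np.asarray(fraction, dtype=float)
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("runoff fraction outside [0, 1]")
    return P_inputs * fraction


def weathering_p_flux(cell: CellSoil,
                      params: WeatheringParams | None = None):
    """Background P delivery by weathering and subsurface/aquifer transport.

    flux = lithology concentration (mg/L) × runoff (mm/yr) × 0.01
           × shielding × f_T, with the Arrhenius factor
    f_T = exp[(Ea/R)(1/T_ref − 1/T)] (T in kelvin, f_T(T_ref) = 1).
    """
    p = params or WeatheringParams()
    t_k = np.asarray(cell.MAT, dtype=float) + 273.15
    f_t = np.exp(p.activation_energy_J_mol / R_GAS
                 * (1.0 / p.T_ref_K - 1.0 / t_k))
    return (cell.lithology_P_conc * cell.runoff_depth * MG_L_MM_TO_KG_HA
            * cell.shielding * f_t)


def update_soil_p_pool(cell: CellSoil, inputs, uptake,
                       weathering: WeatheringParams | None = None,
                       ) -> tuple[CellSoil, dict]:
    """Advance the top-30-cm P pool by one year.

    pool' = pool + inputs − uptake − recent-input runoff − erosion P
            + soil_loss × initial_P_content   (fresh-material replacement)

    clamped at zero; the clamped shortfall is returned as ``mining_deficit``.
    The annual residual-P flux (agronomic budget minus runoff losses) is
    ``inputs − uptake − P_runoff`` with P_runoff = recent runoff + erosion P.

    Returns the updated cell and a loss breakdown (all kg/ha/yr):
    recent_runoff, erosion_P, erosion_N, weathering_P, replacement,
    P_runoff, residual_P, mining_deficit.
    """
    inputs = np.asarray(inputs, dtype=float)
    uptake = np.asarray(uptake, dtype=float)
    if np.any(inputs < 0) or np.any(uptake < 0):
        raise ValueError("inputs and uptake must be non-negative")
    recent = recent_input_runoff(inputs, cell.recent_input_runoff_fraction)
    ero_p = erosion_p_loss(cell)
    ero_n = erosion_n_loss(cell)
    weath = weathering_p_flux(cell, weathering)
    replacement = cell.soil_loss * cell.initial_P_content
    p_runoff = recent + ero_p
    residual = inputs - uptake - p_runoff
    raw = cell.P_pool + residual + replacement
    new_pool = np.maximum(raw, 0.0)
    deficit = np.maximum(-raw, 0.0)
    losses = {
        "recent_runoff": recent, "erosion_P": ero_p, "erosion_N": ero_n,
        "weathering_P": weath, "replacement": replacement,
        "P_runoff": p_runoff, "residual_P": residual,
        "mining_deficit": deficit,
    }
    new_cell = replace(cell, P_pool=new_pool)
    return new_cell, losses


def simulate_cell(cell: CellSoil, inputs_by_year, uptake_by_year,
                  weathering: WeatheringParams | None = None):
    """Run :func:`update_soil_p_pool` over aligned annual series.

    Returns (final cell, list of per-year loss breakdowns).
    """
    if len(inputs_by_year) != len(uptake_by_year):
        raise ValueError("inputs and uptake series must be aligned")
    history = []
    for inp, upt in zip(inputs_by_year, uptake_by_year):
        cell, losses = update_soil_p_pool(cell, inp, upt, weathering)
        history.append(losses)
    return cell, history
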