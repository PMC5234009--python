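# Methods

## Scope and model

`npbudget` computes annual **agronomic soil nutrient budgets** for
cropland: the difference between nutrient inputs and the nutrients removed
in harvested crop parts, per accounting unit (country, subnational unit, or
0.5° grid cell) and calendar year over a configurable window (default
1970–2010, annual step).

N inputs are biological fixation, atmospheric deposition, synthetic
fertilizer and animal manure; the only output is harvest withdrawal. P
inputs are fertilizer and manure (P deposition is a globally minor flux and
is set to zero); residual soil P additionally subtracts runoff losses and
is accumulated year over year into the legacy soil P stock. The budgets are
*agronomic*: N leaching, denitrification and gaseous emissions are not
subtracted — they are part of the N surplus, not of the budget equation —
and in-stream transport/retention of exported nutrients is out of scope, as
are 5-arc-minute grids and map projections.

## Data model and statistical plumbing

Statistics enter as long-format `(unit, year, item, value)` tables
(`StatTable`), mirroring national statistical yearbooks. Three generic
repairs are applied before accounting, in this order:

1. **Interior gaps** in a series are filled by linear interpolation between
   the nearest observed neighbours; observed values are never modified.
2. **Years outside a series' span** are filled by the trend of a proxy
   (`filled = anchor × proxy_year / proxy_anchor`), e.g. minor livestock
   categories following the summed cattle + sheep/goats trend; where no
   proxy covers the gap, the nearest endpoint persists (logged as a
   fallback).
3. **Subnational data** (states, provinces) are rescaled each year so their
   sum matches the national total, which remains authoritative; national
   fodder production, which has no subnational statistics, is distributed
   over subunits proportionally to cattle + dairy (and for some fodder
   classes pig) stocks.

Grids are fixed 360 × 720 rasters (cell centres at ±0.25° offsets from
89.75°N / 179.75°W) with latitude-dependent cell areas from the spherical
band formula (R = 6371 km). Country totals are spread over cells
proportionally to non-negative weights (cropland area); both scaling and
disaggregation conserve totals to floating-point accuracy, which the test
suite checks at 1e-9 relative.

Internally every mass is kg; reporting units are kg/ha/yr and Tg (10⁹ kg).
Molar N:P ratios use atomic masses 14.007 and 30.974 g/mol.

## Budget terms

**Crop withdrawal.** Crops carry fixed N and P contents (fractions of
harvested mass) and belong to one of three groups — legumes, wetland rice,
upland crops — with harvested fodder crops, including leguminous fodders,
booked with the upland group. Withdrawal is production × content, summed to
groups. Seed flows are budget-neutral by construction and never appear.
The shipped content table (cereal grain 2.0% N / 0.35% P, soybean 6.2% N,
pulses 3.5% N, …) is a documented placeholder in YAML: users with
authoritative crop-specific contents should override it. Residue burning
and feed use are computed as diagnostics (burned residue P returns to the
soil in ash, so only N is lost in burning); the default budget *excludes*
them, consistent with treating withdrawal as harvested-parts only, and a
config switch (`include_residue_flows`) adds them to withdrawal.

**Biological N fixation.** For grain legumes, grain mass determines
aboveground biomass through a harvest index of 0.5, roots are 0.19 ×
aboveground, and plant N follows from component N contents (seed 3.5%,
soybean 6.2%, straw and roots 0.8%). Fixation is 0.6 × plant N by default;
the alternative regression max(0, 0.66 × plant-N − 19) kg N/ha is applied
on per-hectare plant N (its native units) and clamped at zero, a choice the
source regression leaves open. The 0.6 coefficient is applied to all grain
legumes including soybean. Leguminous fodder crops fix exactly their
harvested N. Non-symbiotic fixation adds 5 kg N/ha/yr on upland area and
25 kg N/ha/yr on wetland rice. Both modes agree at plant N = 19/0.06
kg/ha; coefficient-mode fixation is strictly linear in yield.

**Manure.** Excretion is stocks × constant per-head rates (placeholders in
YAML; e.g. non-dairy cattle 50 kg N and 8 kg P per head-year). Excretion
during grazing (0.30), outside the agricultural system (0.10) and fuel/other
uses (0.05) are excluded; stored N loses 20% as NH₃, stored P is conserved.
Available manure goes 50% to cropland in high-income units and 95% in
developing units. EU members cap the cropland application rate at 170 kg
N/ha/yr (the lower bound of the 170–250 regulatory range, overridable per
run); N above the cap spills to grassland and P follows N proportionally
within each destination, conserving mass exactly.

**Fertilizer.** National totals are authoritative. Group shares follow
fertilizer-use-by-crop application rates anchored in 2000 (countries
without survey data inherit the area-weighted regional mean; reported rates
are never overwritten), scaled in other years by the group's nutrient yield
relative to 2000. The scaling factor is clipped to [0.1, 10] — the yield
mechanism is well defined but needs a guardrail against degenerate shares
when sparse data put a near-zero yield in the denominator. Shares are
renormalized so the national total is conserved exactly.

**Deposition.** A year-2000 N deposition field is scaled per region and
year by an N-gas emission index (≡ 1 in 2000). The field itself is an
input, not computed here.

## Runoff losses and the soil P pool

Each cropland cell carries a top-30-cm soil P pool, initialised at the
year-1900 inventory concentration × soil mass. The layer holds 3.9 × 10⁶ kg
soil/ha (bulk density 1.3 g/cm³ × 0.3 m — the layer depth is standard, the
bulk density is this package's default and is configurable). Annually:

* recent-input runoff removes a fixed fraction (default 0.10, per-cell
  overridable) of that year's P inputs;
* erosion removes soil_loss × current pool concentration as P, and
  soil_loss × soil C content / C:N as N (C:N 12 arable, 14 grassland, 14
  natural vegetation; soil C constant in time). Eroded mass is replaced at
  the bottom of the layer with fresh material at the initial P content;
* the pool then gains inputs and loses crop uptake; it is clamped at zero
  with any shortfall reported as a mining deficit.

`P_runoff` in the residual-P equation is recent-input runoff + erosion P.
A background **weathering P flux** (lithology-class concentration × runoff
depth × 0.01 × shielding × Arrhenius factor exp[(Ea/R)(1/T_ref − 1/T)];
defaults Ea = 50 kJ/mol, T_ref = 284.15 K, both placeholders and
configurable) is computed per cell but reported as a separate delivery to
water: it travels via subsurface flow and aquifers and does not pass
through the agronomic topsoil pool, so including it in the pool equation
would break the exact stock/flux identity the package guarantees
(pool change = Σ residual flux + Σ replacement + Σ mining deficit, to
1e-9). With the defaults, cells with normal P inputs lose 10–30% of inputs
to runoff, and low-input cells more — erosion dominates when inputs are
small.

N erosion losses are diagnostics only; the N budget does not subtract them
(no leaching/denitrification model is present, by design).

## Indicators and aggregation

NUE and PUE are harvested output over total input; runoff is *not* part of
the efficiency denominator (it appears only in residual P). Non-symbiotic
fixation counts as an N input. Regional series are always ratios of summed
masses — a region's NUE is Σ withdrawal / Σ inputs, never an average of
country NUEs. Cumulative residual P is the running sum of residual flux ×
area in Tg. Region archetypes: high-income (USA, Canada, Western Europe,
Japan, Australia, New Zealand), China+India, transition (Eastern Europe and
former Soviet Union), sub-Saharan Africa (Africa minus the northern tier
and South Africa), other; `world` is the union.

## Synthetic worlds

The generator emulates the statistical *structure* of the real data
streams, not their geography or noise spectra: per-archetype
piecewise-linear trends in fertilizer, uptake intensity, manure and
deposition, with lognormal multiplicative year noise (keeping series
positive) and lognormal country-level spread; static cropland maps of a few
grid cells per country; livestock stocks back-derived from a target manure
input so the archetype's budget trajectory emerges from the forward
accounting. All draws flow from the single spec seed; the same seed yields
a byte-identical bundle.

Ground truth is computed inside the generator by a deliberately naive
straight-line implementation of the same equations (plain loops, no shared
helpers), serving as an independent oracle: on a lossless bundle the
pipeline must agree with it to 1e-9 relative on every term and indicator,
which the acceptance suite checks on a 200-country, 41-year, ~2000-cell
world. Injected missingness (dropping interior years) and perturbed
subnational splits exercise the repairs of the statistics layer; on
linear-trend worlds the repairs are exact up to interpolation of the trend,
and recovered budgets must stay within 5% RMS of truth.

The five shipped scenarios (`generate_archetype_scenarios`) encode the
canonical regional trajectories as constructed trends: high-income P
fertilizer declining after 1980 against rising yields (PUE crossing 1,
late-period residual P negative), China/India inputs outpacing uptake
(declining NUE, monotone cumulative residual P), a transition-economy input
collapse over 1990–1995 (a PUE jump), and near-zero sub-Saharan budgets
(|P budget| well inside ±3 kg P/ha/yr). Passing these shape checks shows
the accounting machinery propagates such regimes correctly — it says
nothing about the actual historical magnitudes, which require the real
national statistics.

Default problem sizes (ten countries and ~60 cells per scenario world, 200
countries for the oracle check) keep a full validation run around a minute
on one CPU while leaving every code path load-bearing; all sizes are fields
of `WorldSpec`.

## Numerical and degenerate-case choices

* Proportional scaling with a zero distribution key and a nonzero total is
  an error everywhere (no silent uniform fallback); a zero total yields
  zeros.
* Proxy backcasting with a zero proxy anchor is an error (undefined ratio).
* Efficiencies and molar ratios with zero denominators are reported as
  missing (NaN), not raised.
* The soil P pool is clamped at zero; the clamp amount is reported, so the
  bookkeeping identity remains exact.
* Pipeline runs are single-threaded and deterministic: rerunning a config
  produces byte-identical numeric outputs.

## Known limitations

Excretion rates, crop nutrient contents and the weathering constants are
editable placeholders, not a curated parameter database. The budget is
cropland-only (no grassland fertilization), has no manure trade or human
excreta inputs, no P leaching or wind erosion, and no in-stream retention;
subnational proxies are always reconciled to national totals even where
sources disagree. The synthetic worlds make no claim to geographic realism
and cannot reproduce published historical magnitudes without the underlying
statistics.
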