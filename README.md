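# npbudget

Annual agronomic **nitrogen and phosphorus budgets for cropland**, from
FAOSTAT-style agricultural statistics and gridded land/soil fields to
nutrient-use-efficiency and residual-soil-P indicator series at country and
region level.

The package is for agricultural biogeochemists and nutrient-cycle modellers
who want a tested, reusable implementation of soil nutrient budget
accounting: crop nutrient withdrawal, biological N fixation from legume
harvests, manure from livestock stocks, fertilizer distribution over crop
groups, atmospheric deposition, erosion/runoff losses, and the multi-decade
build-up (or mining) of residual soil phosphorus.

## The accounting

For each accounting unit (country, state/province, or 0.5° grid cell) and
year, the agronomic soil budgets are

```
N_budget   = N_fix + N_dep + N_fert + N_man − N_withdr
P_budget   = P_fert + P_man − P_withdr
P_residual = P_budget − P_runoff
```

A positive budget is a surplus, a negative one a deficit. Nutrient use
efficiency is output over input, `NUE = N_withdr / (N_fix + N_dep + N_fert
+ N_man)` and `PUE = P_withdr / (P_fert + P_man)`; `PUE > 1` signals soil P
mining. Residual P accumulated over years, `Σ P_residual × area`, is the
legacy soil P stock (reported in Tg; 1 Tg = 10⁹ kg).

The individual terms follow standard practice: legume N fixation is derived
from harvested grain via a harvest index of 0.5, a root:aboveground ratio
of 0.19 and component N contents, with fixation = 0.6 × plant N (or the
regression 0.66 × plant-N − 19 kg N/ha); non-symbiotic fixation contributes
5 kg N/ha/yr on upland crops and 25 on wetland rice. Manure is stocks ×
excretion rates, minus grazing/outside/fuel exclusions and 20% storage NH₃
loss, split 50:50 (high-income) or 95:5 (developing) between cropland and
grassland with an EU application-rate cap. Erosion exports N via land-use
specific soil C:N ratios and P via the current topsoil concentration; the
top-30-cm P pool is replenished at depth with fresh material at its initial
(year-1900) P content.

Because the underlying national statistics cannot be redistributed, the
package ships a first-class synthetic-data generator
(`npbudget.synthetic_data`) that emulates those data streams per
development archetype (high-income, China/India, transition, sub-Saharan
Africa) with known ground truth, computed by an independent naive
implementation used as a validation oracle.

## Worked example

```python
import tempfile
from npbudget import WorldSpec, generate_world, run_pipeline, RunConfig

with tempfile.TemporaryDirectory() as d:
    spec = WorldSpec(seed=1)          # ten countries, two per archetype
    bundle, truth, _ = generate_world(spec, f"{d}/bundle")
    res = run_pipeline(RunConfig(bundle=f"{d}/bundle", out_dir=f"{d}/out"))
    ind = res["indicators"].xs("world")
    print(ind.loc[[1970, 1990, 2010],
                  ["N_budget_kg_ha", "P_budget_kg_ha", "NUE", "PUE",
                   "cumulative_residual_P_Tg"]].round(3))
```

prints

```
      N_budget_kg_ha  P_budget_kg_ha    NUE    PUE  cumulative_residual_P_Tg
year
1970          33.270           6.910  0.483  0.433                     0.052
1990          52.421           9.450  0.481  0.469                     1.325
2010          53.101           4.275  0.542  0.717                     1.958
```

i.e. an N surplus stabilising around 50 kg N/ha/yr, NUE near 0.5, PUE
rising as P inputs flatten, and about 2 Tg of residual P accumulated in
this ten-country world over 1970–2010. The same run writes `terms.csv`
(every budget term per country-year), `indicators.csv`, the per-cell soil P
state and a run manifest to the output directory.

The same workflow is available from the shell:

```sh
npbudget generate --scenario china_india --seed 1 --out bundle/
npbudget run --config cfg.yml
npbudget indicators --terms out/terms.csv --region-map bundle/config/region_map.yml --out ind.csv
```

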