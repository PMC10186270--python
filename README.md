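# tgfs

An integrative, process-based simulator of tomato plant growth and fruit
sugar metabolism, for crop ecophysiologists and horticultural modellers who
want to explore how weather, atmospheric CO2, soil water and nitrogen
management jointly shape fruit size *and* taste quality.

The whole plant is four coupled compartments — a "big leaf" canopy, stem,
root, and a "big truss" of identical fruits — linked by water and carbon
fluxes:

- **Stomatal conductance** (Jarvis-type): gs = gs_max · f(Rn′) · f(Ta) ·
  f(VPD) · f(θ) · f(N) · f(CO2), each reduction factor in [0, 1].
- **Photosynthesis** (Farquhar–von Caemmerer–Berry): A = min(Ac, Aj) − Rd
  with age-declining Vcmax and Jmax, coupled to conductance by solving
  A(Ci) = (Ca − Ci)·gs/1.6 for the intercellular CO2.
- **Water transport** (quasi-steady): Tr = gs·(VPD/P_atm)·LA·18.015·3600,
  ψ_soil from a van Genuchten retention curve, ψ_stem = ψ_soil − Rp·Tr.
- **Carbon allocation**: leaf structural/non-structural pools, saturable
  phloem loading, and sink unloading proportional to sink size, a logistic
  developmental activity and the phloem sucrose concentration Cp, which is
  solved each instant from the closure
  Loading = Uptake_stem + Uptake_root + Uptake_fruit.
- **Fruit biophysics**: water influx A·Lp·(ψ_stem − ψ_fruit) with a
  Lockhart turgor closure and ageing wall extensibility; sucrose import by
  active transport, mass flow and diffusion; inversion to hexose, starch
  synthesis/remobilisation and respiration yielding FW, DW, and the
  soluble-sugar and starch concentrations SSc and Stac (g per 100 g FW).

On top of the simulator sit a seeded real-coded genetic algorithm for
whole-plant calibration (variance-normalised seven-variable criterion,
MAE/RRMSE diagnostics), a synthetic weather and pseudo-observation
generator, and an 81-scenario nitrogen × irrigation sweep with
Pareto-front selection of scenarios that gain both fruit weight and sugar.

## Worked example

```python
from tgfs import SeasonConfig, generate_synthetic_season, run_season
from tgfs.params import default_parameters

forcing = generate_synthetic_season(SeasonConfig(n_days=90, seed=1))
result = run_season(forcing, default_parameters())
for key in ("final_FW", "final_SSc", "final_LA", "g_sNCO2_m", "Tc_L"):
    print(f"{key:12s} {result.aggregates[key]:.3f}")
```

prints

```
final_FW     250.207
final_SSc    2.842
final_LA     0.422
g_sNCO2_m    0.177
Tc_L         37.143
```

i.e. over a 90-day post-anthesis season under the default synthetic
weather, each fruit reaches 250 g fresh weight with 2.8 g soluble sugar
per 100 g FW (rising through ripening, after a mid-development starch peak
of ~2 g/100 g), the canopy ends at 0.42 m² leaf area, daytime stomatal
conductance averages 0.18 mol H2O m⁻² s⁻¹ and the plant transpires 37 L
over the season.  `result.df` holds the full hourly trajectory (pools,
potentials, Cp, gs, Pn, fluxes); whole-plant carbon and fruit water
budgets close to round-off by construction.

A CLI mirrors the library:

```sh
tgfs weather synth --seed 42 -o season.csv
tgfs simulate --forcing season.csv -o out/
tgfs calibrate --obs obs.csv --spec spec.yml --forcing season.csv -o fit/
tgfs scenarios --forcing season.csv -o sweep.csv
tgfs fixtures -o fixtures/
```

## Layout

- `src/tgfs/drivers.py` — forcing validation, synthetic seasons, future climates
- `src/tgfs/gas_exchange.py` — conductance, photosynthesis, Ci coupling
- `src/tgfs/plant_water.py` — transpiration and water potentials
- `src/tgfs/plant_carbon.py` — leaf/stem/root carbon, phloem closure
- `src/tgfs/fruit.py` — fruit water relations and sugar metabolism
- `src/tgfs/simulate.py` — season integrator and aggregates
- `src/tgfs/calibration.py` — metrics, GA, leaf-level fitters
- `src/tgfs/scenarios.py` — N×water sweep and Pareto front
- `src/tgfs/fixtures.py` — pseudo-observations and treatment bundles
- `docs/methods.md` — model equations, assumptions and limitations
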