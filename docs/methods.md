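# Methods

`tgfs` simulates one post-anthesis season of an indeterminate tomato as a
coupled plant-fruit system: a "big leaf" canopy exchanging CO2 and water
vapour, stem and root carbon sinks, and a "big truss" of identical fruits
accumulating water, sugars and starch.  This note records the model
equations as implemented, the assumptions behind them, the parameter and
design choices that were genuinely open, and what the synthetic test data
can and cannot demonstrate.

## Gas exchange

Stomatal conductance is multiplicative (Jarvis-type):

    gs = gs_max * f(Rn') * f(Ta) * f(VPD) * f(theta) * f(N) * f(CO2)

with each reduction function mapping into [0, 1].  The functional forms are
package defaults — hyperbolic saturation in intercepted net radiation, a
symmetric quadratic about the temperature optimum, a hyperbolic decline in
VPD, a piecewise-linear soil-water response between the wilting point
theta_w and a critical content theta_c, a biphasic (interior-optimum)
quadratic in soil mineral N, and a logarithmic decline in CO2 above a
reference concentration.  Any form can be replaced at run time through
`StomatalParams.forms` without code changes; the defaults should be treated
as substitutions for experimentally fitted response curves.  The biphasic N
response means supra-optimal fertilisation closes stomata too, which is why
moderate N reduction can out-perform the reference in scenario sweeps.

Net assimilation is the standard C3 biochemical model: the minimum of the
Rubisco-limited and RuBP-regeneration-limited rates minus day respiration,
with electron transport from a non-rectangular hyperbola of absorbed PAR.
Vcmax and Jmax decline linearly with days after anthesis (clipped at zero),
representing canopy ageing.  Simplifications, all deliberate: leaf
temperature equals air temperature (no energy balance); the kinetic
constants Kc, Ko, Gamma* are held at 25 degC values (no Arrhenius
temperature response); O2 is fixed at 210 mmol mol-1; leaf-scale Rd
defaults to 0 because maintenance respiration is accounted separately in
the leaf carbon balance — setting both would double-count.  Rd is
configurable for users fitting gas-exchange data.

Supply and demand are closed by solving A(Ci) = (Ca - Ci) gs / 1.6 for Ci
with a bracketed Brent solve on [Gamma*, Ca] (extended above Ca for a
respiring leaf in darkness); the residual at the root is required to be
below 1e-9.  PAR is derived from intercepted radiation at 635 umol photons
per MJ h-1 (0.5 PAR fraction x 4.57 umol J-1).

## Water transport

Flow is quasi-steady (no plant capacitance): root uptake equals canopy
transpiration each hour.  Transpiration uses the mole-fraction driving
force, Tr = gs (VPD/P_atm) LA * 18.015 * 3600 g h-1.  Soil water potential
comes from a pluggable retention curve — van Genuchten-Mualem with loam
constants by default (theta_r 0.078, theta_s 0.43, alpha 0.036 cm-1,
n 1.56), Campbell, or a user table — and stem water potential is
psi_stem = psi_soil - Rp * Tr.  The hydraulic resistance Rp
(0.002 MPa h g-1) is a placeholder of plausible magnitude for a pot-grown
plant, not a fitted value.  Below the residual water content the potential
clamps to a -3 MPa floor with a logged warning.

## Carbon allocation

The leaf holds structural carbon C_str (sets leaf area, LA = C_str * SLAs)
and a non-structural reserve C_ns.  Structural growth is
C_str * K_ml * C_ns/(C_ns + C_str); phloem loading is saturable in the
reserve fraction; maintenance respiration scales with dry weight and a Q10
temperature factor, growth respiration with the structural increment.  The
reserve balance is dC_ns/dt = Pn*LA - Loading - Mresp - dC_str/dt.

Stem and root unload sucrose from the phloem in proportion to their size, a
logistic developmental attenuation, and the phloem sap sucrose
concentration Cp.  Their respiration references their own growth increment,
which is implicit as written; it is resolved explicitly as
dC_x/dt = (uptake - maintenance)/(1 + q_g) while growing, and plain
uptake - maintenance when shrinking (no growth respiration on a declining
pool).

Cp is not a state: at every derivative evaluation it solves the
instantaneous balance Loading = Uptake_stem + Uptake_root + Uptake_fruit.
Because the stem, root, mass-flow and diffusion terms are linear in Cp and
the active fruit transport is Michaelis-Menten, the balance is a quadratic
solved in closed form (machine-precision residual); a bracketed numerical
fallback covers user-supplied uptake forms.  Treating the closure
algebraically rather than as a lagged state keeps the source-sink balance
exact at every accepted step.

Maintenance respiration terms carry a saturable substrate-availability
factor (half-saturation ~2 mg C) so that pools approach zero smoothly
instead of going negative; under default parameters no clipping events
occur in a 90-day season.  Carbon fractions: leaf 0.36 g C per g DW; stem
and root default to 0.42 (generic plant tissue) pending tissue-specific
values.

## Fruit

Each of the Fn identical fruits (12 per plant by default, fixed — no
abortion) carries water W and four carbon pools: sucrose, hexose, starch,
and structural/other.  Water enters along the stem-to-fruit potential
gradient through a composite conductivity Lp acting on the allometric
surface A = lam * FW^n (cm2), and leaves by surface transpiration
proportional to area and VPD.  The fruit water potential is P - pi with
osmotic pressure pi from van 't Hoff on the soluble sugars plus a fixed
0.30 MPa offset for acids and ions that are not book-kept.  Turgor P
follows a quasi-steady Lockhart closure: when the growth solution exceeds
the yield threshold Y, irreversible expansion W * phi(t) * (P - Y) balances
the net water flux; below threshold there is no expansion and P floats in
[0, Y] at the no-net-flux value.  Wall extensibility phi(t) is constant
until tau_s hours after anthesis and then declines exponentially to a
floor, terminating expansion near maturity.

Sucrose import sums three routes: active transport
vm(t) * DW * Cp/(Km + Cp) with a logistic developmental shutdown at t*;
phloem mass flow (the phloem share of the water influx, 1/(1 + axp),
advecting sugar at phloem concentration on the way in and at fruit sap
concentration on the way out); and passive surface diffusion down the sap
concentration difference.  Inside the fruit, sucrose is inverted to hexose
(first order), hexose feeds starch synthesis with an early-maximal
coefficient k5 * k5m0/(k5m0 + exp(u5m (daa - tau5m))) and structural growth
(first order), and starch remobilises late through the complementary
logistic.  This produces the characteristic rise-then-fall of starch
concentration and the late rise of soluble sugar.  Pool derivatives sum to
imported carbon minus fruit respiration by construction, so fruit carbon
conservation is exact.  Stoichiometric carbon fractions: sucrose 0.4211,
hexose 0.4001, starch 0.4444, whole dry matter 0.44 g C g-1.

## Integration

State vector: [C_str, C_ns, C_stem, C_root, W, C_suc, C_hex, C_sta,
C_other] plus six cumulative integrals (assimilation, total respiration,
fruit carbon import, fruit water influx, fruit transpiration, canopy
transpiration).  Forcing is hourly with zero-order hold; gs and the Ci
closure are evaluated once per hour, the pool ODEs advance with classical
RK4 (2 substeps per hour by default; 1 substep is used inside calibration
loops, which changes 90-day endpoints by well under 0.1%).  Because the
cumulators are integrated by the same quadrature as the states, the
whole-plant carbon balance and fruit water balance close to round-off and
are asserted in the test suite (1e-8 and 1e-6 relative, respectively).
The run is fully deterministic.

Seasonal aggregates: "final" values are means over the last 5 simulated
days; Tc is cumulative transpiration in litres; mean gs is taken over
daylight hours; FruitC_net and FruitW_net are the plant-level net fruit
carbon and water influxes.

## Synthetic data

The season generator produces hourly forcing from daily sinusoids: a
truncated half-sine radiation curve between sunrise and sunset (daylength
from latitude and day of year) with per-day lognormal cloudiness, daily
temperature extremes with seasonal modulation and Gaussian noise
interpolated by a sinusoid peaking at 13:00 and bottoming at 01:00,
humidity anti-phased with temperature, constant CO2, a weekly
irrigation-cycle wobble on soil water and a fortnightly fertigation
sawtooth on soil N.  Everything is reproducible from one seed.  The
four-treatment suite (three N levels at 60/120/180 mg kg-1 under full
irrigation, theta 0.32, plus a deficit treatment at theta 0.18) shares one
weather realisation so treatments are controlled contrasts.

Pseudo-observations sample seven variables (leaf/stem/root/fruit dry
weight, fruit fresh weight, soluble sugar and starch concentrations) every
7 days from day 10 with multiplicative lognormal noise of configurable CV
and replication — emulating destructive harvest campaigns.  What this does
not emulate: instrument-specific error structure, within-truss fruit
heterogeneity, missing data, or real weather autocorrelation beyond the
daily cycle.  Passing calibration-recovery tests therefore demonstrates
identifiability and correctness of the machinery under the stated noise
model, not performance on real experiments.

## Calibration

Goodness of fit: MAE and RRMSE (RMSE over the observed mean).  The
whole-plant objective is the variance-normalised squared error summed over
the seven observed variables, observations matched to the nearest simulated
hour within 0.5 day.  The normalising variance is taken over the per-time
replicate means with the sample convention (ddof = 1), configurable to the
population convention; the normalisation makes the criterion invariant to
per-variable unit rescaling.

The optimiser is a seeded real-coded genetic algorithm: tournament
selection (k = 3), BLX-0.5 blend crossover (rate 0.9), Gaussian mutation
(rate 0.15, scale 10% of each bound range annealed geometrically to 0.5%
by the final generation), elitism 1.  Failed simulations score +inf and are
recorded.  With a 40 x 30 budget on a 90-day season, the stem-sink rate and
attenuation coefficients and the fruit active-uptake capacity are recovered
within 15% from noiseless or 5%-CV pseudo-observations; the full-season
window matters because the stem attenuation midpoint (~46 days) is only
expressed in the second half of the season.  A two-stage protocol is
supported: leaf-level utilities fit Vcmax/Jmax by two-limb change-point
least squares on A-Ci curves and stomatal parameters by Nelder-Mead on
observed conductances, after which the whole-plant GA runs with those
fixed.

## Scenarios

The sustainability sweep is the full 9 x 9 factorial of N and water
multipliers (100% to 60%, step 5%).  N scales the soil-N forcing directly.
Water, by default, scales the excess of theta over the wilting point
("deficit" mode), so reduced irrigation cannot push the soil below wilting;
plain scaling is available.  Outcomes are percentage changes of mature
fruit FW and SSc relative to the reference scenario in the first climate
year, with the final value averaged over the last five climate years
(configurable).  The trade-off is summarised by the non-dominated set
maximising both deltas; ties are kept; the selection is verified against a
brute-force dominance scan.  Future climates ramp CO2 linearly to a target
(550 umol mol-1 by 2100 by default, from 413.38) and add a linear warming
trend before VPD is recomputed at unchanged relative humidity.

## Numerical and default-parameter notes

Default parameters were chosen once to yield a realistic greenhouse
tomato under the default synthetic season: final single-fruit fresh weight
~250 g at ~5.8% dry matter, soluble sugar ~2.8 g per 100 g FW rising
through ripening, starch peaking ~2 g per 100 g FW around day 30, leaf
area ~0.42 m2, daytime mean conductance ~0.18 mol m-2 s-1.  They are
documented substitutions, not fitted values; every constant is exposed in
the parameter YAML.

Degenerate inputs: empty leaf or fruit return zero rates rather than
dividing by zero; a massless fruit reports flagged zero concentrations;
theta at or below residual clamps with a warning; gs = 0 skips the Ci
solve and returns -Rd.  Problem sizes used by the test suite and the
acceptance script — 10-day runs for conservation checks, 90-day runs for
developmental patterns and calibration recovery, one-year compact sweeps
for the scenario table — were chosen as the smallest sizes at which each
property is meaningfully expressed.

Known limitations: no canopy structure (big leaf), no truss heterogeneity
(big truss), no nitrogen mass balance inside the plant (soil N acts only
through stomata), no stress-dependent reallocation priority, no fruit set
or abortion, no cell division phase, and no interactive effects between
the stomatal reduction factors.
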