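# Methods

This note documents the models behind `heatstrain`, the defaults and the
reasoning where the design was genuinely open. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`.

## Data model and completeness

The atom of computation is a station-hour (ta in °C, vp in hPa, v10 in
m·s⁻¹, cloud as a fraction). Timestamps are stored in UTC; "midday" means
12 UTC throughout, which in a Central European summer corresponds to 14:00
local daylight time — close to the diurnal maximum of temperature and
radiation. Local-time inputs must carry an explicit offset; bare
timestamps are interpreted as UTC. Cloud cover may be supplied in oktas
(0–8) and is normalised to a fraction on read; the dialect is declared,
never guessed. Missing values are explicit sentinels.

A station-day enters daily statistics when at least 18 of 24 hours are
valid (configurable; recorded in run metadata). The 12-UTC statistics use
only the midday record and are left missing when there is none — never
imputed. Incomplete days are excluded from indicator counts and reported.

## Radiation and mean radiant temperature

Synoptic stations do not observe T_mrt, so it is estimated from cloud
cover and humidity:

1. **Solar position** by the truncated-series ephemeris formulas (NOAA
   form of Meeus); accuracy a few tenths of a degree, which the tests
   check against closed-form solstice/equinox geometry to ±0.5°.
   Refraction is ignored (irrelevant above ~5° elevation).
2. **Clear-sky irradiance** S₀·τ^(1/sin h)·sin h with S₀ = 1361 W·m⁻² and
   bulk transmittance τ = 0.75, a standard one-parameter model chosen
   because the inputs carry no aerosol information.
3. **Cloud attenuation** by the Kasten–Czeplak factor 1 − 0.75·N^3.4,
   the widely used form that needs only total cloud cover.
4. **T_mrt** for a standing person: upper hemisphere = sky at air
   temperature with emissivity ε = ε₀ + (1 − ε₀)·N, ε₀ = 0.52 + 0.065·√vp
   (Brunt); lower hemisphere = ground as a black body at air temperature;
   plus absorbed short-wave (1 − α)·f_p·K_glob/ε_p with person albedo
   α = 0.3, projected-area factor f_p = 0.25 and ε_p = 0.97. Solving
   σT⁴ = Σ gives T_mrt.

The linear cloud correction makes the overcast night an exact enclosure
(T_mrt = ta), a property the tests assert; clear nights cool several K
below ta, and a clear noon at 30 °C yields T_mrt ≈ 18 K above ta —
both in the range reported for summer mid-latitude conditions. All
constants live in one `RadiationConstants` block and are echoed into every
run's metadata. This chain is deliberately simple; it reproduces the sign,
magnitude and diurnal structure of the radiant load, not any particular
proprietary implementation.

## UTCI

UTCI is evaluated with the operational 6th-order polynomial approximation
in ta, va (10 m), ΔT_mrt and pa (kPa), shipped as a versioned,
checksummed coefficient table. Inputs outside the fitting domain
(ta ∈ [−50, 50] °C, va ∈ [0.5, 17] m·s⁻¹, ΔT_mrt ∈ [−30, 70] K,
pa ≤ 5 kPa) are clipped to the boundary and flagged rather than rejected,
because station records routinely contain calm hours below 0.5 m·s⁻¹.

Categories use half-open-left, closed-right bands, so printed one-decimal
bounds behave as expected (26.0 → no thermal stress, 26.1 → moderate heat
stress). The cold half of the scale is collapsed to a single "below SCS"
label; a June analysis never uses it. Whether a day's category comes from
the midday value or the daily maximum is configurable; the default is the
12-UTC value, the hour of greatest heat load.

**Fidelity envelope.** The coefficient table is a transcription of the
published operational listing, cross-checked against a second, independent
encoding of the same listing (agreement < 10⁻¹² °C on random in-domain
points, so the two transcriptions are mutually consistent). Its functional
fidelity was assessed through the reference-scale identity (UTCI = ta at
T_mrt = ta, va = 0.5 m·s⁻¹, 50 % RH): the shipped table reproduces it to
±0.86 °C for ta ≤ 26 °C but drifts to about −3.9 °C at ta = 35 °C,
indicating that some high-order humid-heat terms of the original listing
are not captured exactly. Consequences: UTCI values in the strong-heat
range may read a few K low in very warm, humid conditions, and
strong-heat-day counts derived from them are conservative. Monotonicity in
wind, humidity (at moderate temperatures) and radiant load is unaffected,
as is every category-boundary rule. The acceptance suite carries the
identity check over the full 15–35 °C range at ±1 °C and reports the
measured deviation rather than hiding it.

## Heat strain

Net heat storage S = M + Q + E + C + Res (W·m⁻², gains positive) for a
reference person walking 4 km·h⁻¹ (M = 135 W·m⁻²):

- **Wind at 1.2 m** from the 10-m value by a neutral logarithmic profile
  with roughness length 0.01 m (factor ≈ 0.69) — the index formulas need
  body-height wind but stations report 10 m.
- **Q** — radiant exchange ε_p·f_eff·σ(T_mrt⁴ − T_sk⁴) with effective
  radiating fraction f_eff = 0.71, reduced by a clothing transfer factor
  0.6 when clothed.
- **C** — forced convection h_c·(ta − T_sk) with h_c = 8.3·v₁.₂^0.6
  (floor 3 W·m⁻²·K⁻¹ for free convection), same clothing factor.
- **Res** — the standard respiratory loss
  −[0.0014·M·(34 − ta) + 1.72·10⁻⁵·M·(5867 − 100·vp)], clipped to ≤ 0.
- **T_sk** — an empirical linear closure
  26.4 + 0.18·ta + 0.04·T_mrt + 0.01·(M − 135), capped at 36.5 °C.
- **E** — the evaporation required for equilibrium
  (E_req = M + Q + C + Res), realisable at most up to
  E_max = k·v₁.₂·0.6·(56 − vp); the unmet demand remains as positive
  storage S. This convention ties S and the sultriness index to the same
  E_max machinery and keeps HSI within [0, 100] by construction: HSI = 0
  when no sweating is demanded, 100 when the air is saturated
  (vp ≥ 56 hPa) or demand reaches capacity.

The original heat-budget software's internal formulations for Q, C, Res
and skin temperature are not published; the closures above are standard
documented forms and are this package's own choices. They reproduce the
signs, magnitudes and threshold behaviour of the published indicators
(e.g. a calm, humid 33 °C clear noon drives S > 15 W·m⁻², the overheating
threshold), not any undisclosed implementation bit for bit. S
conservation (S ≡ M+Q+E+C+Res) holds to machine precision and is asserted
on every synthetic June hour.

Daily budgets count hours with strict inequalities: UTCI > 26 (heat-stress
time), UTCI < 18 (heat-recovery time), S > 15 W·m⁻², HR > 90 beats·min⁻¹,
HSI > 30 %. Hours at exactly a threshold do not count, matching the
strict ">" of the indicator definitions. When S > 15 persists for ≥ 3
consecutive hours the day is annotated `sustained_overheating` (the
static "+2 °C core temperature after 3 h" interpretation); no dynamic
core-temperature simulation is attempted.

## Climatology

Threshold-day counts use strict inequalities (a 30.0 °C day is not "very
hot"). Heat waves are maximal runs of ≥ 3 consecutive days with
tmax > 30 °C; runs separated by a single cooler day are distinct waves.
Gaps in the date index are an error, not silently bridged. Anomalies use
the sample standard deviation (n − 1); with a constant reference the
SD-scaled anomaly is undefined (NaN) while the absolute anomaly is still
returned.

## Mortality

TMrel = 100·TMx/TMavg; reference means are taken over the years with
observed counts — missing years are excluded, never imputed.
SHRM = 2.595·PopRate·(SHS + VSHS) is adopted verbatim; since the time
basis of the 2.595 coefficient is not derivable from its published form,
SHRM is labelled "model-attributed deaths per month". Days hotter than
the very-strong band (above-scale) count as strong-heat days — the
operative definition is UTCI > 32 °C.

`estimate_heat_effect` recovers the relative risk as the ratio of stratum
means (strong-heat days vs all others) with a stratified percentile
bootstrap over days, so no resample loses a stratum. With the validation
conditions (baseline 30 deaths/day, 15 strong-heat days, injected RR 1.5)
the mean estimate over 500 replicates lies within [1.4, 1.6] and the 95 %
interval covers the null in ≥ 90 % of null replicates, as the acceptance
suite verifies.

## Synthetic data

The generator emulates a lowland Central European June:

- an hourly temperature cycle with minimum at 04 and maximum at 14 local
  solar time, built from two half-cosine branches (a single sinusoid
  cannot place both extremes correctly);
- a day-level AR(1) anomaly (φ = 0.85, innovation SD 1.5 °C → day-to-day
  SD ≈ 2.8 °C, interannual SD of monthly means ≈ 1.4 °C) added uniformly
  to all hours of a day, the simplest process consistent with
  advection-driven weather variability;
- heat-wave windows that add a constant offset to their days. The default
  severe-June scenario (base 20 °C, amplitude 6 °C, waves on days 10–16
  and 25–27 at +8 °C) has a monthly mean of ≈ 22.7 °C and ~12 days above
  30 °C — the regime of a record Central European June. The default
  reference scenario (base 16.5 °C, amplitude 5 °C, cloudier and windier,
  one 3-day +10 °C spell) represents the climatological June with roughly
  one strong-heat day;
- vapour pressure from a lognormal capped below saturation (physical
  humidity), wind from a lognormal, cloud from a Beta distribution;
- daily deaths as Poisson(baseline · RR^[strong-heat day]), baseline 30
  deaths/day for a city of 800 000 (≈ 1.1 % annual crude mortality).

Every variable draws from its own sub-stream of a single seeded
generator; identical scenario + seed is bitwise reproducible. What the
generator does **not** emulate: spatial correlation between stations,
urban heat-island structure, humidity–temperature covariance beyond the
saturation cap, pollution–weather coupling (pollutants are independent of
temperature by design, which is what makes the demo's near-100 % pollutant
columns informative), and harvesting dynamics in mortality. Passing tests
on synthetic data therefore validate the computational chain and its
statistical behaviour, not the epidemiological realism of any particular
city.

## Pipeline and reproducibility

A single `RunConfig` drives all stages; per-year seeds are derived
deterministically from the run seed. Each stage writes its intermediate
table to the output directory, and the report stage reads only those
files, so stages can be re-run in isolation and two runs with the same
config and seed produce byte-identical bundles (asserted in the tests).
Run metadata records the config hash (excluding the output location), the
seed, the UTCI coefficient checksum, and every radiation/strain constant
and threshold.

Problem sizes used by the shipped validation runs — 30-day months, ten
synthetic years, 1000-point random sweeps, 500/200 simulation replicates —
were chosen so every property is measured with comfortable statistical
margins while the whole suite completes in well under a minute.
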