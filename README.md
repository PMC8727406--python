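# heatstrain

Biometeorological analysis of severe heat waves for temperate (Central
European) station climates: from hourly synoptic weather to thermal-stress
exposure, physiological heat strain, climatological heat indicators, and
heat-attributable excess mortality.

The package is aimed at biometeorologists and environmental epidemiologists
who have hourly station observations (air temperature *ta*, vapour pressure
*vp*, 10-m wind *v*, total cloud cover *N*), monthly all-cause death counts,
and want the standard chain of heat-wave health diagnostics in one tested,
reproducible pipeline. A synthetic-data module generates June weather and
mortality with the statistical structure the analysis assumes, so the whole
chain can be exercised and validated without access to external archives.

## What it computes

**Thermal stress.** The Universal Thermal Climate Index (UTCI, °C) is
evaluated with the operational 6th-order polynomial approximation in
*ta*, *v*, vapour pressure and the mean radiant temperature excess
ΔT<sub>mrt</sub> = T<sub>mrt</sub> − *ta*. T<sub>mrt</sub> is estimated
from solar geometry, a clear-sky transmittance model with Kasten–Czeplak
cloud attenuation (1 − 0.75·N³·⁴), and Brunt-type sky emissivity. Daily and
midday (12 UTC) UTCI statistics are classified on the assessment scale:
no thermal stress (9–26 °C), moderate (26.1–32), strong (32.1–38, SHS) and
very strong (38.1–46, VSHS) heat stress.

**Climatological indicators.** Hot / very hot / extremely hot days
(tmax > 25/30/35 °C), warm and tropical nights (tmin > 18/20 °C), heat
waves (≥ 3 consecutive days with tmax > 30 °C), and anomalies of monthly
statistics against a multiannual reference in °C and in multiples of the
reference standard deviation.

**Heat strain.** The human heat balance S = M + Q + E + C + Res (W·m⁻²)
for a reference person walking 4 km·h⁻¹ (M = 135 W·m⁻²); heart rate
HR = 22.4 + 0.18·M + 0.25·(5·ta + 2.66·vp); the sultriness index
HSI = 100·E<sub>req</sub>/E<sub>max</sub> with
E<sub>max</sub> = k·v₁.₂·0.6·(56 − vp), k = 7.0 clothed / 11.7 naked; and
daily hour budgets: heat-stress time (UTCI > 26 °C), heat-recovery time
(UTCI < 18 °C), and hours with S > 15 W·m⁻², HR > 90 beats·min⁻¹,
HSI > 30 %.

**Mortality.** Relative monthly mortality TMrel = 100·TMx/TMavg against a
reference period; model-attributed strong-heat deaths
SHRM = 2.595·PopRate·(SHS + VSHS) with PopRate the population per 100 000;
SHRMrel against the reference-period mean; and, for validation, a
stratified-bootstrap estimator of the relative risk of death on
strong-heat days.

## Worked example

One command simulates ten synthetic Junes — nine climatological reference
years and one severe year with two embedded heat waves (days 10–16 and
25–27, +8 °C) and a relative death risk of 1.5 on strong-heat days — runs
the full chain and prints the report table:

```sh
heatstrain run-all --seed 1 --out run
```

```text
  period  tmrel_pct  shrmrel_pct  utci_mean  heat_stress_days  o3_ugm3  o3_pct  pm25_ugm3  pm25_pct
    2010       99.7        128.6       23.9               1.0     66.3   102.4       12.0     101.9
    2011      103.8          0.0       23.6               0.0     64.6    99.7       10.7      90.5
    2012       94.7          0.0       25.4               0.0     68.4   105.6       11.4      96.3
    2013      101.6          0.0       21.7               0.0     63.2    97.5       12.2     103.2
    2014       97.7          0.0       22.3               0.0     61.6    95.1       12.2     103.5
    2015       97.3          0.0       24.1               0.0     65.6   101.2       13.2     111.7
    2016      105.7        385.7       24.8               3.0     64.9   100.2       11.4      96.4
    2017       99.1          0.0       21.8               0.0     65.0   100.4       11.4      96.2
    2018      100.4        385.7       26.1               3.0     63.4    97.9       11.8     100.1
ref_mean      100.0        100.0       23.7               0.8     64.8   100.0       11.8     100.0
    2019      115.4       1285.7       31.3              10.0     65.8   101.5       11.6      98.6
```

Reading the table: the reference years' TMrel averages exactly 100 by
construction, and their SHRMrel fluctuates around 100 with most years at
zero strong-heat days. The severe year stands out on every column that
should respond to heat — deaths 15 % above the reference mean (the
injected risk on its 10 strong-heat days), midday UTCI 31.3 °C against the
23.7 °C reference, and a SHRM an order of magnitude above the reference
mean — while the pollutant columns, which were generated independently of
temperature, stay near 100 %. The run's `metadata.json` records the midday
UTCI anomaly of the severe year (+7.5 °C, 4.8 reference SDs) along with
the seed, config hash and every empirical constant used.

Per-stage verbs (`simulate`, `utci`, `strain`, `mortality`, `report`, …)
re-run any part of the chain from the cached intermediate files in the
output directory; `report` alone reproduces the final table byte for byte.

## Layout

- `src/heatstrain/station_io.py` — data model, readers/writers, daily aggregation
- `src/heatstrain/synthetic.py` — synthetic weather, pollution and mortality
- `src/heatstrain/radiation.py` — solar position, irradiance, mean radiant temperature
- `src/heatstrain/utci.py` — UTCI polynomial and stress categories
- `src/heatstrain/climatology.py` — threshold days, heat waves, anomalies
- `src/heatstrain/heat_strain.py` — heat balance, HR, HSI, daily budgets
- `src/heatstrain/mortality.py` — TMrel, SHRM, SHRMrel, effect recovery
- `src/heatstrain/pipeline.py`, `cli.py` — orchestration and the `heatstrain` command

See `docs/methods.md` for the model formulations, parameter defaults and
known limitations (including the fidelity envelope of the shipped UTCI
coefficient transcription).
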