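# radonrisk

Occupancy-conditioned indoor radon risk assessment: continuous
radon-concentration time series are aggregated against a building's
occupancy schedule into windowed effective-dose estimates, annualized, and
mapped to a four-level color-coded risk indicator (green / yellow / orange /
red at 1, 5 and 20 mSv·year⁻¹). Includes the reference abacus (annual dose
over a concentration × daily-occupation lattice), a seedable synthetic-data
generator for hermetic testing, and a survey margin-of-error helper.

## Layout

| module | what it does |
|---|---|
| `radonrisk.dose_model` | closed-form dose arithmetic: exposure integrals, effective dose, annual dose (IAED), four-level classification, relative-risk helpers, dose-coefficient conversions |
| `radonrisk.exposure_timeseries` | the monitoring pipeline: CSV ingestion, occupancy masks, windowed time-weighted means (RT/VST/ST/LT), window dose, annualization, per-window assessment |
| `radonrisk.abacus` | the reference grid with analytic level-boundary curves; CSV and figure export |
| `radonrisk.synthetic` | log-normal series generator with diurnal/seasonal modulation, schedule presets, named test scenarios |
| `radonrisk.cli` | `irrei` command-line front end, run configuration, margin-of-error helper |

Two dose-coefficient conventions are supported and carried in the type
system: an EEC-basis coefficient (e.g. 9 nSv per Bq·m⁻³·h, multiplied by
the equilibrium factor F) and a gas-basis coefficient with F already
embedded (e.g. 6.7×10⁻⁹ Sv per Bq·m⁻³·h). The default configuration is
EEC 9 nSv with F = 0.4. Because the basis is an enum on the coefficient,
F can never be applied twice.

## CLI

```sh
# generate a synthetic fixture (readings CSV + schedule JSON)
irrei simulate --gm 300 --gsd 1.3 --span-days 95 --schedule-kind dwelling \
    --seed 1 --outdir fixtures

# run the per-window assessment and write JSON + text reports
irrei assess --readings fixtures/readings.csv \
    --schedule fixtures/schedule.json --outdir reports

# export the reference abacus
irrei abacus --csv abacus.csv --figure abacus.png

# survey precision helper
irrei margin-of-error --n 873 --population 6000000
```

Schedules use a small JSON dialect:

```json
{"weekly": [{"day": "Mon", "start": "09:00", "end": "17:00"}],
 "exceptions": [{"date": "2021-12-25", "occupied": false}]}
```

Run configuration (YAML or JSON, all optional) covers the equilibrium
factor, coefficient value/basis, classification thresholds, long-term
window length, and the minimum data-coverage fraction below which a window
is flagged low-confidence.

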