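# insolekit

A toolkit for the software side of a pressure- and temperature-sensing
smart insole: the kind of low-cost wearable used to monitor plantar
loading and skin-temperature asymmetry, e.g. for early detection of
diabetic foot complications. The insole carries 16 force-sensitive
resistors (FSRs) and 8 NTC thermistors per foot, each read through a
pull-up voltage divider by a 12-bit ADC at 40 Hz and multiplexed into a
single text frame per sample.

`insolekit` implements everything downstream of the electronics, and a
synthetic insole simulator upstream of it, so the whole pipeline runs
and is tested without hardware:

- **calibration** — divider arithmetic `Vout = Vcc·Rext/(Rext+R)` and
  its inverse; thermistor conversion via the exponential calibration
  `R(T) = a·e^{bT}` (defaults `a = 24 710 Ω`, `b = −0.036 /°C`, so
  `T = (ln R − ln a)/b`); exponential curve fitting with R²; FSR
  resistance→force from a monotone anchor table (10 kΩ ↔ 100 g);
  pressure/force/mass conversions for the 126.68 mm² active area.
- **codec** — encode/decode of the 24-channel multiplexed frame line
  and trial log files (raw ADC counts, so calibration is re-runnable).
- **simulate** — walking and standing trials for a cohort sampled
  within the study's anthropometric ranges: two-peak body-weight-scaled
  vGRF stance template, phase-dependent heel→toe force sharing,
  12-bit quantization with voltage noise, per-site skin temperatures,
  optional sensor hysteresis, and a ground-truth sidecar per trial.
- **gait** — total vertical ground reaction force (vGRF), threshold
  heel-strike segmentation, 512-point cycle resampling, mean ± SD
  ensemble curves, stance-fraction estimation.
- **maps** — parametric foot template and piecewise-linear scattered
  interpolation of per-phase pressure maps and standing temperature
  maps from the sensor-site values.
- **power_budget** — battery arithmetic (mAh × V → Wh → runtime → days).
- **cli** — `insole simulate | convert | segment | map | power`.

## Worked example

Generate one subject's trials (a 10 m walk plus a quiet-standing
capture), segment the gait cycles and map the standing temperatures:

```sh
$ insole simulate --n-subjects 1 --n-trials 1 --standing --seed 7 -o trials
wrote 2 trial logs to trials

$ insole segment trials/S00_walk0.csv -o gait
7 cycles from 1 logs; mean stance fraction 0.609

$ insole map trials/S00_stand.csv --mode temperature -o tmap
wrote 1 map(s) to tmap

$ insole power
energy:  4.81 Wh
runtime: 12.02 h
days:    24.0 days at 0.5 h/day
```

The walk log holds one comma-separated frame per 40 Hz sample (16
pressure counts, 8 temperature counts, 0–4095 each). Segmentation found
7 complete heel-strike-to-heel-strike cycles and a mean stance fraction
of 0.609 — the fraction of each cycle with the foot loaded, which for
normal walking sits near 60%. `gait/cycles.csv` lists each stride:

```
trial_id,cycle,start,end,duration_s,stance_fraction
S00_walk0,0,9,49,1.000,0.6094
S00_walk0,1,49,96,1.175,0.6035
S00_walk0,2,96,136,1.000,0.6074
```

`gait/ensemble.csv` holds the 512-point mean ± SD vGRF curve over all
cycles, and `tmap/temperature_standing.csv` (plus a PNG) is the
interpolated plantar temperature field in °C on the foot-shaped grid.

The same operations are available as library calls
(`insolekit.simulate.simulate_walk`, `insolekit.gait.extract_cycles`,
`insolekit.maps.standing_temperature_map`, …), each returning arrays
and dataclasses rather than files.

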