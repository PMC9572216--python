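# Methods

## What the toolkit models

An instrumented insole reads 16 force-sensitive resistors (FSRs) and 8
NTC thermistors per foot at 40 Hz. Each sensor sits in a pull-up voltage
divider read by a 12-bit ADC (counts 0–4095 mapped linearly onto the
0–5 V supply), and all 24 channel values are multiplexed into a single
text line per sample. The toolkit implements the full software side of
that system — calibration, framing/logging, gait-cycle analysis and
plantar map generation — plus a synthetic generator that stands in for
the hardware so everything is testable end to end.

## Sensor calibration

**Divider.** `Vout = Vcc·Rext/(Rext + R)` with defaults `Vcc = 5 V`,
`Rext = 10 kΩ`. The inversion `R = Rext·(Vcc − Vout)/Vout` is exact;
`Vout = Vcc` reads 0 Ω and `Vout ≤ 0` is flagged as an open circuit
(unloaded FSR, R → ∞). The closed-form thermistor conversion
`R = Rext·(adc_max − A)/A` — `(40 950 000 − 10 000·A)/A` at the default
configuration — is algebraically identical to composing the ADC→voltage
and voltage→resistance steps; a test asserts agreement to 1e−9 °C across
the whole ADC range. ADC counts are accepted as real numbers in the
calibration layer; integer quantization belongs to the simulator.

**NTC thermistor.** Exponential calibration `R(T) = a·e^{bT}` with
defaults `a = 24 710 Ω`, `b = −0.036 /°C` (≈10 kΩ at 25 °C). The inverse
computes `ln a` directly rather than using a rounded constant.
`fit_exponential_calibration` is ordinary least squares on `ln R` vs `T`
(`scipy.stats.linregress`), returning the coefficients and R² of the log
fit; it recovers a generating curve exactly from noiseless samples. The
calibrated working range is 20–50 °C; conversions outside it warn but do
not fail, since the arithmetic remains well defined.

**FSR force curve.** No closed form exists for an FSR; the model is an
anchor table of (resistance, force) pairs interpolated log-log-linearly,
monotone by construction and exact at the anchors. The default table
follows the inverse power law `R·F = 9810 Ω·N`, chosen to pass exactly
through the one datasheet-fixed point (10 kΩ at 100 g = 0.981 N under
g = 9.81 m/s²); it is a plausible reconstruction of a typical FSR-402
response, not a measured curve, and users with a characterised sensor
should supply their own anchors. Above the largest-resistance anchor the
sensor is treated as unloaded (0 N); below the smallest, the terminal
log-log segment is extrapolated.

**Units.** Pressure→force is `F = p·A·10⁻⁶` (Pa × mm²), mass is `F/g`
with `g = 9.81 m/s²`, and the FSR-402 active area is `π·6.35² ≈
126.68 mm²`.

## Frame codec and logs

One line per 40 Hz sample: timestamp (s, 3 decimals), foot tag `L`/`R`,
16 pressure counts, 8 temperature counts, comma-separated. A stream
header (`# insole-log v1 server=… characteristic=… rate_hz=… …`)
carries per-stream metadata once, including stand-ins for the BLE
server/characteristic identifiers; the radio itself is not modelled —
files and pipes carry the frames. Logs store raw counts, not converted
values, so calibration is always re-runnable; decode validates the
24-channel count and the ADC range and reports the offending position.
A truncated final line (interrupted logger) is dropped with a warning;
corruption anywhere else is an error.

## Synthetic trial generator

The generator defines the study conditions for all quantitative tests:
a cohort of subjects sampled within the anthropometric bands age 20–59 y,
weight 52–125 kg, height 153–185 cm, BMI 18–36.5 kg/m², each walking a
10 m walkway at a self-selected speed drawn from 1.0–1.4 m/s, six trials
per subject by default, sampled at 40 Hz.

**vGRF template.** Stance occupies `stance_fraction` (default 0.60) of
each cycle. Within stance the total vertical ground reaction force is
two Gaussian bumps at 25% and 75% of stance (σ = 0.12 of stance
duration), the second scaled 1.25× the first, both scaled to body
weight; swing is zero. Cycle durations are mean 1.1 s with 5%
coefficient of variation, so no two strides are identical. The template
reproduces the canonical double-hump vGRF morphology qualitatively; it
is not a biomechanically validated model (no loading-rate asymmetry, no
mid-swing inertial content).

**Spatial sharing.** Each pressure site has a normalized heel→toe
coordinate `u`. At stance progress `s`, heel sites (`u < 0.3`) weigh
`(1−s)²`, forefoot sites (`0.55 ≤ u ≤ 0.85`) weigh `s²`, toe sites
(`u > 0.85`) activate only in the final 20% of stance, and midfoot
sites carry a small constant; weights are normalized to share the total
vGRF. The squared ramps sharpen the heel-strike/toe-off contrast so
phase maps show clearly posterior/anterior loading. Real per-sensor
force fractions were never measured; this scheme is a stand-in, and
passing tests demonstrate pipeline correctness, not biomechanical
fidelity of the sharing.

**Electronics.** Per-site force → resistance (inverse FSR table) →
divider voltage → additive Gaussian voltage noise (σ = 2 LSB) →
rounding to integer counts clipped to 0–4095. Temperature channels are
per-site baselines ~N(31.5, 1) °C with slow random drift
(σ = 0.005 °C/s) and 0.02 °C sample noise, pushed through the thermistor
divider the same way. When a test pins explicit site temperatures (a
controlled condition such as a planted hot spot) the drift is suppressed
so the pinned values are the true means. One `numpy` generator seeded per
trial makes every trial bit-reproducible.

**Hysteresis.** `apply_hysteresis` is a first-order lag with exact
exponential discretization (step release decays as `e^{−t/τ}`; τ = 0 is
the identity), modelling the slow mechanical recovery of resistive
polymer sensors. It defaults to *off* in walking trials: the FSRs were
selected for low hysteresis precisely because strong lag (the Velostat
behaviour) distorts dynamic gait signals — switching it on visibly
extends unloading tails, which a test demonstrates.

**Quantization accuracy.** At 12 bits over 20–50 °C the thermistor chain
resolves better than 0.03 °C, so time-averaged decoded temperatures
recover the generator's truth to under 0.1 °C. The FSR chain saturates
at high per-site force (the divider compresses large forces into a few
millivolts below the rail), so instantaneous per-frame force error grows
near the push-off peak; across a trial the mean absolute vGRF error
stays below 2% of the peak.

## Gait analysis

Total vGRF is the per-frame sum of the calibrated 16 pressure channels.
Heel strike is an upward crossing of `threshold × max(force)` (default
5%, relative so segmentation is invariant to uniform rescaling)
following at least one below-threshold sample; a cycle spans heel strike
to the next heel strike with half-open 0-based indices `[start, end)`.
Leading and trailing partial cycles are discarded rather than padded; a
standing or all-zero record yields zero cycles, not an error. Each cycle
is linearly resampled to 512 points and the ensemble is the pointwise
mean and *population* standard deviation (the sample/population
difference is immaterial at the cycle counts involved). The stance
fraction of a cycle is the fraction of resampled points above the
relative threshold. Force curves are reported in raw newtons by default,
with optional body-weight normalization.

The detection rule and threshold are design choices (no rule is fixed by
the hardware); both are configurable. With the generator's defaults the
pipeline recovers the configured 60% stance duty cycle to within 1
percentage point on 20-trial cohorts (~140 cycles), comfortably inside
the ±2-point acceptance band.

## Plantar maps

**Template.** The foot outline is the convex hull of a heel disc
(radius 0.40 × foot width, resting on the heel line) and a forefoot
ellipse (semi-axes 0.48 × width, 0.24 × length, centred at 75% of foot
length), built with `shapely` and rasterized at cell centres (default
1 mm). The x-grid is symmetric about the foot axis so mirroring a layout
mirrors the raster exactly. Any sensor outside the outline is rejected
by name. The default 260 mm × 95 mm dimensions and all sensor
coordinates ship in `data/default_layout.csv` — a labelled
reconstruction, since the original placements exist only as photographs.

**Interpolation.** Piecewise-linear scattered interpolation over the
sensor sites (`scipy.interpolate.LinearNDInterpolator`), chosen for node
exactness and min–max boundedness; cells inside the foot but outside the
sites' convex hull take the nearest site's value
(`NearestNDInterpolator`). Fewer than three or collinear sites are
rejected. Pressure maps are drawn at configurable stance phases (default
heel strike 0.0, foot-flat 0.15, midstance 0.30, heel-off 0.45, toe-off
0.60, mid-swing 0.80 as fractions of the cycle); the phase→frame mapping
floors rather than rounds so the toe-off phase lands on the last loaded
frame instead of the first swing frame. The temperature map time-averages
each channel over a window (default 10 s) of a quiet-standing capture.
Maps carry their mask and units (N or °C); per-area pressure display is
a presentation choice left to the caller.

## Power budget

Energy (Wh) = capacity (mAh) × nominal voltage / 1000; runtime =
energy / consumption rate; days = runtime / daily use. Defaults
(1300 mAh, 3.7 V, 0.4 Wh/h, 0.5 h/day) give 4.81 Wh, ≈12 h, ≈24 days.
Consumption is an input, not modelled — it depends on radio duty cycle
and hardware revision.

## Problem sizes and numerical choices

Simulation-backed tests use single trials (~8–10 s, 320–400 frames) or
20-trial cohorts, which segment in well under a second; map tests use a
2 mm raster. Tolerances: divider/thermistor identities at 1e−9;
calibration-fit recovery under 2% multiplicative noise (n = 31) is
bounded at 5% relative error on the exponential rate, a bound
established by Monte-Carlo before being frozen (observed maximum ≈3%
over 200 seeds); stance recovery at ±2 percentage points; temperature
recovery at 0.1 °C. Ties and degenerate inputs: zero-count pressure
channels are unloaded by definition; full-scale counts clip to the FSR
table's maximum force; zero-max cycles have undefined stance fraction
and raise.

## Known limitations

- The FSR anchor table, sensor coordinates, foot outline and spatial
  force-sharing are reconstructions; absolute newton values in maps and
  ensembles are internally consistent but not validated against a force
  plate.
- The vGRF template has no inter-subject morphology variation beyond
  amplitude, speed and timing jitter.
- Only the vertical force component is modelled (no shear), one foot at
  a time, and no IMU/kinematic channels.
- The BLE transport is represented by the text stream only.
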