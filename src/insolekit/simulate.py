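"""Synthetic insole trials: walking and standing, with ground truth.

No public dataset accompanies the hardware, so every downstream stage is
exercised against this generator.  A walking trial is built in four
steps per frame:

1. total vertical ground reaction force (vGRF) from a two-peak stance
   template (two Gaussian bumps at 25% and 75% of stance, second peak
   higher) scaled to the subject's body weight, zero in swing; cycle
   durations are jittered so no two strides are identical;
2. the total force is shared over the 16 pressure sites by a
   phase-dependent anterior-posterior weighting — heel-dominant at heel
   strike, forefoot/toe-dominant toward toe-off;
3. each site force is pushed through the inverse FSR curve, the pull-up
   divider and a 12-bit quantizer (with additive voltage noise) to give
   the ADC counts the hardware would report;
4. temperature channels carry a per-site skin-temperature baseline with
   slow drift and noise, converted through the thermistor divider.

Every trial comes with a :class:`GroundTruth` sidecar (true total vGRF,
true site temperatures, heel-strike frame indices) so recovery can be
tested quantitatively.  All randomness flows through one seeded
generator: the same seed reproduces a trial bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import calibration as cal
from .calibration import DividerConfig, FSRForceModel, ThermistorModel
from .codec import Frame, Trial
from .layout import SensorLayout, default_layout

__all__ = [
    "SubjectProfile",
    "GaitParams",
    "GroundTruth",
    "SimResult",
    "simulate_walk",
    "simulate_standing",
    "apply_hysteresis",
    "sample_subject",
]

# Table-2 cohort ranges the subject sampler draws from
AGE_RANGE = (20, 59)
WEIGHT_RANGE_KG = (52.0, 125.0)
HEIGHT_RANGE_CM = (153.0, 185.0)
BMI_RANGE = (18.0, 36.5)

SELF_SELECTED_SPEED_RANGE = (1.0, 1.4)  # m/s, documented default band


@dataclass(frozen=True)
class SubjectProfile:
    """Anthropometrics of one subject, within the study cohort ranges."""

    age: int
    weight_kg: float
    height_cm: float
    sex: str = "F"
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        if not AGE_RANGE[0] <= self.age <= AGE_RANGE[1]:
            raise ValueError(f"age {self.age} outside {AGE_RANGE}")
        if not WEIGHT_RANGE_KG[0] <= self.weight_kg <= WEIGHT_RANGE_KG[1]:
            raise ValueError(f"weight {self.weight_kg} outside {WEIGHT_RANGE_KG}")
        if not HEIGHT_RANGE_CM[0] <= self.height_cm <= HEIGHT_RANGE_CM[1]:
            raise ValueError(f"height {self.height_cm} outside {HEIGHT_RANGE_CM}")

    @property
    def bmi(self) -> float:
        return self.weight_kg / (self.height_cm / 100.0) ** 2

    @property
    def body_weight_n(self) -> float:
        return self.weight_kg * cal.STANDARD_GRAVITY


def sample_subject(rng: np.random.Generator, subject_id: str = "S00") -> SubjectProfile:
    """Draw a subject whose BMI also falls inside the cohort band."""
    for _ in range(1000):
        h = round(rng.uniform(*HEIGHT_RANGE_CM), 1)
        w = round(rng.uniform(*WEIGHT_RANGE_KG), 1)
        bmi = w / (h / 100.0) ** 2
        if BMI_RANGE[0] <= bmi <= BMI_RANGE[1]:
            return SubjectProfile(
                age=int(rng.integers(AGE_RANGE[0], AGE_RANGE[1] + 1)),
                weight_kg=w,
                height_cm=h,
                sex=str(rng.choice(["F", "M"])),
                subject_id=subject_id,
            )
    raise RuntimeError("could not sample a subject inside the BMI band")


@dataclass(frozen=True)
class GaitParams:
    """Tunable gait-generator parameters.

    stance_fraction
        fraction of the cycle the foot is loaded (default 0.60).
    cycle_duration_mean / cycle_duration_cv
        mean stride time (s) and its coefficient of variation.
    peak2_to_peak1_ratio
        push-off peak relative to the loading peak (> 1).
    walkway_length / speed
        trial kinematics; ``speed=None`` draws a self-selected speed
        from 1.0-1.4 m/s.
    """

    stance_fraction: float = 0.60
    cycle_duration_mean: float = 1.1
    cycle_duration_cv: float = 0.05
    peak2_to_peak1_ratio: float = 1.25
    walkway_length_m: float = 10.0
    speed_m_s: Optional[float] = None
    peak_width_frac: float = 0.12  # Gaussian sigma as a fraction of stance

    def __post_init__(self) -> None:
        if not 0.0 < self.stance_fraction < 1.0:
            raise ValueError("stance_fraction must be in (0, 1)")
        if self.peak2_to_peak1_ratio <= 1.0:
            raise ValueError("second peak must exceed the first (ratio > 1)")
        if self.cycle_duration_mean <= 0 or self.cycle_duration_cv < 0:
            raise ValueError("invalid cycle duration parameters")


@dataclass
class GroundTruth:
    """Generator-side truth for one trial, for quantitative recovery tests."""

    true_vgrf_n: np.ndarray  # per frame, pre-quantization total force
    heel_strike_frames: np.ndarray  # frame index of each heel strike
    site_temps_c: np.ndarray  # (n_frames, 8) true temperatures
    site_forces_n: np.ndarray  # (n_frames, 16) true per-site forces

    def save(self, path) -> None:
        payload = {
            "true_vgrf_n": self.true_vgrf_n.tolist(),
            "heel_strike_frames": self.heel_strike_frames.tolist(),
            "site_temps_c": self.site_temps_c.tolist(),
            "site_forces_n": self.site_forces_n.tolist(),
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            true_vgrf_n=np.asarray(d["true_vgrf_n"], dtype=float),
            heel_strike_frames=np.asarray(d["heel_strike_frames"], dtype=int),
            site_temps_c=np.asarray(d["site_temps_c"], dtype=float),
            site_forces_n=np.asarray(d["site_forces_n"], dtype=float),
        )


@dataclass
class SimResult:
    trial: Trial
    truth: GroundTruth
    subject: SubjectProfile


# ---------------------------------------------------------------------------
# building blocks


def stance_template(s: np.ndarray, ratio: float, width: float) -> np.ndarray:
    """Unit-peak two-bump vGRF shape on stance progress s in [0, 1].

    Loading-response bump at s=0.25, push-off bump at s=0.75 scaled by
    ``ratio``; zero outside [0, 1].
    """
    s = np.asarray(s, dtype=float)
    g1 = np.exp(-0.5 * ((s - 0.25) / width) ** 2)
    g2 = ratio * np.exp(-0.5 * ((s - 0.75) / width) ** 2)
    return np.where((s >= 0.0) & (s <= 1.0), g1 + g2, 0.0)


def phase_weights(anterior_frac: np.ndarray, s: float) -> np.ndarray:
    """Force-sharing weights over sensor sites at stance progress s.

    Sites are classed by their normalized heel->toe position: heel
    (< 0.3) weighted (1-s)^2, forefoot (0.55-0.85) weighted s^2, toes
    (> 0.85) active only in the final 20% of stance, midfoot a small
    constant.  Weights are normalized to sum to 1.  This sharing scheme
    is a qualitative stand-in: the real per-sensor fractions were never
    measured.
    """
    u = np.asarray(anterior_frac, dtype=float)
    w = np.full_like(u, 0.1)
    heel = u < 0.3
    fore = (u >= 0.55) & (u <= 0.85)
    toe = u > 0.85
    w[heel] = (1.0 - s) ** 2
    w[fore] = s**2
    w[toe] = s**2 if s >= 0.8 else 0.0
    total = w.sum()
    if total <= 0:  # pragma: no cover - guarded by the constant midfoot term
        return np.full_like(u, 1.0 / u.size)
    return w / total


def apply_hysteresis(series, relaxation_time_s: float, rate_hz: float):
    """First-order lag emulating slow polymer recovery of resistive sensors.

    Exact exponential discretization: y[n] = y[n-1] + (1 - e^(-dt/tau))
    (x[n] - y[n-1]); ``relaxation_time_s = 0`` is the identity.  On a
    step release from F to 0 the output after one relaxation time is
    F/e.
    """
    if relaxation_time_s < 0:
        raise ValueError("relaxation time must be >= 0")
    x = np.asarray(series, dtype=float)
    if relaxation_time_s == 0 or x.size == 0:
        return x.copy()
    alpha = 1.0 - np.exp(-1.0 / (relaxation_time_s * rate_hz))
    y = np.empty_like(x)
    y[0] = x[0]
    for n in range(1, x.size):
        y[n] = y[n - 1] + alpha * (x[n] - y[n - 1])
    return y


def _site_temperatures(
    rng: np.random.Generator,
    n_frames: int,
    n_sites: int,
    rate_hz: float,
    baseline_c: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-site skin temperature: baseline + slow linear drift + noise.

    An explicitly pinned baseline (a controlled condition, e.g. a planted
    hot spot) gets no drift so the pinned values are the true means.
    """
    if baseline_c is None:
        baseline_c = rng.normal(31.5, 1.0, size=n_sites).clip(25.0, 38.0)
        drift_rate = rng.normal(0.0, 0.005, size=n_sites)  # degC per second
    else:
        drift_rate = np.zeros(n_sites)
    t = np.arange(n_frames)[:, None] / rate_hz
    noise = rng.normal(0.0, 0.02, size=(n_frames, n_sites))
    return baseline_c[None, :] + drift_rate[None, :] * t + noise


def _quantize(voltage: np.ndarray, cfg: DividerConfig, rng, noise_lsb: float):
    lsb = cfg.vcc / cfg.adc_max
    v = voltage + rng.normal(0.0, noise_lsb * lsb, size=voltage.shape)
    counts = np.rint(v / lsb).astype(int)
    return np.clip(counts, 0, cfg.adc_max)


def _forces_to_counts(forces, cfg, fsr_model, rng, noise_lsb):
    r = cal.resistance_from_force(forces, fsr_model)
    v = cal.voltage_from_resistance(r, cfg)
    return _quantize(v, cfg, rng, noise_lsb)


def _temps_to_counts(temps, cfg, thermistor, rng, noise_lsb):
    r = thermistor.resistance_at(temps)
    v = cal.voltage_from_resistance(r, cfg)
    return _quantize(v, cfg, rng, noise_lsb)


def _assemble(
    timestamps, foot, p_counts, t_counts, rate, trial_id, subject_id
) -> Trial:
    frames = [
        Frame(
            timestamp=round(float(ts), 3),
            foot=foot,
            pressure_adc=tuple(int(c) for c in pc),
            temperature_adc=tuple(int(c) for c in tc),
        )
        for ts, pc, tc in zip(timestamps, p_counts, t_counts)
    ]
    return Trial(
        frames=frames, sampling_rate=rate, trial_id=trial_id, subject_id=subject_id
    )


# ---------------------------------------------------------------------------
# trial generators


def simulate_walk(
    subject: SubjectProfile,
    gait: GaitParams = GaitParams(),
    layout: Optional[SensorLayout] = None,
    cfg: DividerConfig = DividerConfig(),
    seed: int = 0,
    *,
    rate_hz: float = 40.0,
    fsr_model: FSRForceModel = FSRForceModel(),
    thermistor: ThermistorModel = ThermistorModel(),
    noise_lsb: float = 2.0,
    hysteresis_s: float = 0.0,
    foot: str = "L",
    trial_id: str = "walk",
) -> SimResult:
    """Generate one instrumented walking trial over the walkway.

    The trial length follows from walkway length and (self-selected)
    speed; strides are generated until the walkway is covered.  Set
    ``hysteresis_s`` > 0 to superimpose the slow-recovery lag of
    resistive sensors on the per-site forces (off by default: the FSRs
    were selected for low hysteresis).
    """
    if layout is None:
        layout = default_layout(foot)
    n_p = len(layout.pressure)
    n_t = len(layout.temperature)
    if n_p != 16 or n_t != 8:
        raise ValueError(
            f"layout must carry 16 pressure + 8 temperature channels, "
            f"got {n_p}+{n_t}"
        )
    rng = np.random.default_rng(seed)
    speed = (
        gait.speed_m_s
        if gait.speed_m_s is not None
        else rng.uniform(*SELF_SELECTED_SPEED_RANGE)
    )
    duration_s = gait.walkway_length_m / speed

    # stride boundaries with jittered durations; half a cycle of lead-in swing
    lead_in = 0.5 * gait.cycle_duration_mean * (1 - gait.stance_fraction)
    starts = [lead_in]
    durations = []
    while starts[-1] < lead_in + duration_s:
        d = gait.cycle_duration_mean * (
            1.0 + gait.cycle_duration_cv * rng.standard_normal()
        )
        d = max(d, 0.2 * gait.cycle_duration_mean)
        durations.append(d)
        starts.append(starts[-1] + d)
    total_s = starts[-1] + lead_in
    n_frames = int(np.ceil(total_s * rate_hz))
    t = np.arange(n_frames) / rate_hz

    anterior = layout.anterior_fraction("pressure")
    bw = subject.body_weight_n
    vgrf = np.zeros(n_frames)
    site_forces = np.zeros((n_frames, n_p))
    heel_strikes = []
    for start, dur in zip(starts[:-1], durations):
        stance_dur = gait.stance_fraction * dur
        in_cycle = (t >= start) & (t < start + dur)
        idx = np.nonzero(in_cycle)[0]
        if idx.size == 0:
            continue
        heel_strikes.append(int(idx[0]))
        s = (t[idx] - start) / stance_dur  # stance progress; > 1 in swing
        f = bw * stance_template(s, gait.peak2_to_peak1_ratio, gait.peak_width_frac)
        vgrf[idx] = f
        for pos, k in enumerate(idx):
            if 0.0 <= s[pos] <= 1.0 and f[pos] > 0:
                site_forces[k] = f[pos] * phase_weights(anterior, float(s[pos]))
    heel_strikes = np.asarray(heel_strikes, dtype=int)

    if hysteresis_s > 0:
        for j in range(n_p):
            site_forces[:, j] = apply_hysteresis(
                site_forces[:, j], hysteresis_s, rate_hz
            )

    temps = _site_temperatures(rng, n_frames, n_t, rate_hz)
    p_counts = _forces_to_counts(site_forces, cfg, fsr_model, rng, noise_lsb)
    t_counts = _temps_to_counts(temps, cfg, thermistor, rng, noise_lsb)

    trial = _assemble(
        t, foot, p_counts, t_counts, rate_hz, trial_id, subject.subject_id
    )
    truth = GroundTruth(
        true_vgrf_n=vgrf,
        heel_strike_frames=heel_strikes,
        site_temps_c=temps,
        site_forces_n=site_forces,
    )
    return SimResult(trial=trial, truth=truth, subject=subject)


def simulate_standing(
    subject: SubjectProfile,
    layout: Optional[SensorLayout] = None,
    cfg: DividerConfig = DividerConfig(),
    duration_s: float = 30.0,
    seed: int = 0,
    *,
    rate_hz: float = 40.0,
    fsr_model: FSRForceModel = FSRForceModel(),
    thermistor: ThermistorModel = ThermistorModel(),
    noise_lsb: float = 2.0,
    foot: str = "L",
    trial_id: str = "stand",
    site_temps_c: Optional[np.ndarray] = None,
) -> SimResult:
    """Generate a quiet-standing capture (static double support).

    Half the body weight rests on this foot, shared over the sites with
    the mid-stance weighting; temperatures as in walking.  Pass
    ``site_temps_c`` (8 values) to pin the per-site baselines, e.g. to
    plant a hot spot.
    """
    if layout is None:
        layout = default_layout(foot)
    n_p, n_t = len(layout.pressure), len(layout.temperature)
    if n_p != 16 or n_t != 8:
        raise ValueError("layout must carry 16 pressure + 8 temperature channels")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * rate_hz))
    t = np.arange(n_frames) / rate_hz

    anterior = layout.anterior_fraction("pressure")
    w = phase_weights(anterior, 0.5)  # flat-foot sharing
    load = 0.5 * subject.body_weight_n
    sway = 1.0 + 0.02 * np.sin(2 * np.pi * 0.3 * t)  # gentle postural sway
    site_forces = load * sway[:, None] * w[None, :]
    vgrf = site_forces.sum(axis=1)

    baseline = None if site_temps_c is None else np.asarray(site_temps_c, float)
    temps = _site_temperatures(rng, n_frames, n_t, rate_hz, baseline_c=baseline)
    p_counts = _forces_to_counts(site_forces, cfg, fsr_model, rng, noise_lsb)
    t_counts = _temps_to_counts(temps, cfg, thermistor, rng, noise_lsb)

    trial = _assemble(
        t, foot, p_counts, t_counts, rate_hz, trial_id, subject.subject_id
    )
    truth = GroundTruth(
        true_vgrf_n=vgrf,
        heel_strike_frames=np.asarray([], dtype=int),
        site_temps_c=temps,
        site_forces_n=site_forces,
    )
    return SimResult(trial=trial, truth=truth, subject=subject)
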