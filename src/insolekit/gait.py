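"""Gait-cycle extraction from the total vertical ground reaction force.

The per-frame vGRF is the sum, over the 16 pressure channels, of the
calibration chain ADC count -> divider voltage -> FSR resistance ->
force.  Heel strikes are detected as upward crossings of a relative
force threshold (default 5% of the trial maximum) preceded by at least
one unloaded (swing) sample; a gait cycle spans heel strike to the next
ipsilateral heel strike, half-open on frame indices.  Cycles are
resampled to a fixed length (default 512 points) and summarised as a
pointwise mean +/- standard deviation ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import calibration as cal
from .calibration import DividerConfig, FSRForceModel
from .codec import Trial

__all__ = [
    "GaitCycle",
    "EnsembleCurve",
    "total_vgrf",
    "segment_cycles",
    "resample_cycle",
    "ensemble_stats",
    "stance_fraction",
    "extract_cycles",
]

DEFAULT_N_POINTS = 512
DEFAULT_THRESHOLD_FRACTION = 0.05


@dataclass(frozen=True)
class GaitCycle:
    """One segmented stride: frame span, resampled force curve, labels."""

    start_index: int  # half-open [start, end) in trial frames
    end_index: int
    force_curve: np.ndarray  # resampled vGRF (N), length n_points
    stance_mask: np.ndarray  # per-point loaded/unloaded labels
    duration_s: float

    @property
    def stance_fraction(self) -> float:
        return float(self.stance_mask.mean())


@dataclass(frozen=True)
class EnsembleCurve:
    """Pointwise mean and population std over resampled cycles."""

    mean: np.ndarray
    std: np.ndarray
    n_cycles: int


def total_vgrf(
    trial: Trial,
    cfg: DividerConfig = DividerConfig(),
    fsr_model: FSRForceModel = FSRForceModel(),
) -> np.ndarray:
    """Per-frame total vGRF (N): calibrated sum over pressure channels.

    A zero count means no divider current, i.e. an open (unloaded) FSR,
    and contributes 0 N; a full-scale count means the FSR is at 0 Ohm
    and is clipped to the anchor table's maximum force.
    """
    counts = np.asarray([f.pressure_adc for f in trial.frames], dtype=float)
    if counts.size == 0:
        return np.zeros(0)
    forces = np.zeros_like(counts)
    loaded = counts > 0
    if np.any(loaded):
        v = cal.adc_to_voltage(counts[loaded], cfg)
        full = v >= cfg.vcc
        r = np.empty_like(v)
        if np.any(~full):
            r[~full] = cal.resistance_from_voltage(v[~full], cfg)
        f = np.empty_like(v)
        if np.any(~full):
            f[~full] = cal.force_from_resistance(r[~full], fsr_model)
        f[full] = fsr_model.max_force
        forces[loaded] = f
    return forces.sum(axis=1)


def segment_cycles(
    force: np.ndarray,
    rate_hz: float,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> list[tuple[int, int]]:
    """Heel-strike-to-heel-strike cycle boundaries, half-open [start, end).

    A heel strike is an upward crossing of ``threshold_fraction`` times
    the trial's maximum force, with the previous sample below threshold
    (i.e. after a swing).  Leading and trailing partial cycles are
    discarded; a series that never leaves/enters the threshold (standing
    still, or all zero) yields no cycles.
    """
    if rate_hz <= 0:
        raise ValueError("rate must be > 0")
    f = np.asarray(force, dtype=float)
    if f.size < 2:
        raise ValueError("force series must have at least 2 samples")
    peak = f.max()
    if peak <= 0:
        return []
    thr = threshold_fraction * peak
    above = f > thr
    strikes = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    return list(zip(strikes[:-1], strikes[1:]))


def resample_cycle(
    segment: np.ndarray, n_points: int = DEFAULT_N_POINTS
) -> np.ndarray:
    """Linearly resample one cycle's force segment onto n uniform points."""
    seg = np.asarray(segment, dtype=float)
    if seg.size < 2:
        raise ValueError("cycle segment must have at least 2 samples")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    x_old = np.linspace(0.0, 1.0, seg.size)
    x_new = np.linspace(0.0, 1.0, n_points)
    return np.interp(x_new, x_old, seg)


def ensemble_stats(cycles) -> EnsembleCurve:
    """Pointwise mean and population standard deviation over cycles."""
    curves = [np.asarray(c, dtype=float) for c in cycles]
    if not curves:
        raise ValueError("need at least one cycle")
    n = curves[0].size
    if any(c.size != n for c in curves):
        raise ValueError("all cycles must have equal length")
    stacked = np.vstack(curves)
    return EnsembleCurve(
        mean=stacked.mean(axis=0), std=stacked.std(axis=0, ddof=0),
        n_cycles=len(curves),
    )


def stance_fraction(
    force_curve: np.ndarray,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> float:
    """Fraction of a cycle spent loaded (force above the relative threshold)."""
    f = np.asarray(force_curve, dtype=float)
    peak = f.max()
    if peak <= 0:
        raise ValueError("stance fraction undefined for an unloaded cycle")
    return float(np.mean(f > threshold_fraction * peak))


def extract_cycles(
    trial: Trial,
    cfg: DividerConfig = DividerConfig(),
    fsr_model: FSRForceModel = FSRForceModel(),
    *,
    n_points: int = DEFAULT_N_POINTS,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    normalize_body_weight_n: float | None = None,
) -> list[GaitCycle]:
    """Full chain: calibrate, segment, resample; one GaitCycle per stride.

    ``normalize_body_weight_n`` divides the force curves by a body
    weight to give dimensionless %BW curves (off by default — the
    ensemble is reported in raw newtons).
    """
    force = total_vgrf(trial, cfg, fsr_model)
    bounds = segment_cycles(force, trial.sampling_rate, threshold_fraction)
    cycles = []
    for start, end in bounds:
        seg = force[start:end]
        curve = resample_cycle(seg, n_points)
        thr = threshold_fraction * curve.max()
        if normalize_body_weight_n:
            curve = curve / normalize_body_weight_n
            thr = thr / normalize_body_weight_n
        cycles.append(
            GaitCycle(
                start_index=int(start),
                end_index=int(end),
                force_curve=curve,
                stance_mask=curve > thr,
                duration_s=(end - start) / trial.sampling_rate,
            )
        )
    return cycles
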