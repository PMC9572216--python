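"""Plantar pressure and temperature maps on a foot-shaped template.

The template is a parametric foot outline — the convex hull of a heel
disc and a forefoot ellipse sized from foot length and width —
rasterized onto a regular grid (default 1 mm).  Per-channel scalars at
the sensor sites are spread over the template by piecewise-linear
scattered interpolation (exact at the sensor nodes, bounded by the
input range); cells inside the outline but outside the sites' convex
hull take the nearest site's value.  Pressure maps are produced at
chosen stance phases of a gait cycle; the temperature map comes from a
time-averaged quiet-standing capture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import QhullError
from shapely.affinity import scale as shp_scale
from shapely.geometry import Point
from shapely.ops import unary_union
import shapely

from . import calibration as cal
from .calibration import DividerConfig, FSRForceModel, ThermistorModel
from .codec import Trial
from .gait import GaitCycle
from .layout import SensorLayout

__all__ = [
    "FootTemplate",
    "PlantarMap",
    "foot_outline",
    "build_template",
    "interpolate_map",
    "phase_pressure_maps",
    "standing_temperature_map",
    "DEFAULT_PHASES",
]

# default stance phases mapped (label -> fraction of the gait cycle);
# stance occupies the first ~60% of the cycle
DEFAULT_PHASES: dict[str, float] = {
    "heel_strike": 0.0,
    "foot_flat": 0.15,
    "midstance": 0.30,
    "heel_off": 0.45,
    "toe_off": 0.60,
    "mid_swing": 0.80,
}


def foot_outline(foot_length_mm: float = 260.0, foot_width_mm: float = 95.0):
    """Parametric foot outline polygon in the foot-local frame.

    Convex hull of a heel disc (radius 0.40 x width, resting on y=0)
    and a forefoot ellipse (semi-axes 0.48 x width, 0.24 x length,
    centred at 75% of foot length); deterministic for given dimensions.
    """
    if foot_length_mm <= 0 or foot_width_mm <= 0:
        raise ValueError("foot dimensions must be positive")
    r_heel = 0.40 * foot_width_mm
    heel = Point(0.0, r_heel).buffer(r_heel, quad_segs=64)
    fore = shp_scale(
        Point(0.0, 0.75 * foot_length_mm).buffer(1.0, quad_segs=64),
        xfact=0.48 * foot_width_mm,
        yfact=0.24 * foot_length_mm,
    )
    return unary_union([heel, fore]).convex_hull


@dataclass(frozen=True)
class FootTemplate:
    """Rasterized foot mask: grid cell centres + inside-outline indicator."""

    mask: np.ndarray  # (ny, nx) bool; row 0 = heel end
    x_mm: np.ndarray  # (nx,) cell-centre x coordinates
    y_mm: np.ndarray  # (ny,) cell-centre y coordinates
    resolution_mm: float
    foot_length_mm: float
    foot_width_mm: float

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())

    def nearest_cell(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the grid cell whose centre is closest to (x, y)."""
        return (
            int(np.argmin(np.abs(self.y_mm - y))),
            int(np.argmin(np.abs(self.x_mm - x))),
        )


@dataclass(frozen=True)
class PlantarMap:
    """Gridded, foot-masked scalar field (pressure in N or temperature degC)."""

    grid: np.ndarray  # (ny, nx) float, NaN outside the mask
    template: FootTemplate
    units: str
    phase: Optional[str] = None

    @property
    def mask(self) -> np.ndarray:
        return self.template.mask

    def max_location(self) -> tuple[int, int]:
        """(row, col) of the maximum value inside the mask."""
        g = np.where(self.mask, self.grid, -np.inf)
        return tuple(np.unravel_index(int(np.argmax(g)), g.shape))

    def centroid_y_fraction(self) -> float:
        """Heel->toe position (0..1) of the map's centre of mass."""
        g = np.where(self.mask & np.isfinite(self.grid), self.grid, 0.0)
        total = g.sum()
        if total <= 0:
            raise ValueError("centroid undefined for a zero map")
        wy = (g.sum(axis=1) * self.template.y_mm).sum() / total
        return float(wy / self.template.foot_length_mm)


def build_template(
    layout: SensorLayout,
    foot_length_mm: Optional[float] = None,
    foot_width_mm: Optional[float] = None,
    resolution_mm: float = 1.0,
) -> FootTemplate:
    """Rasterize the foot outline and check every sensor sits inside it."""
    if resolution_mm <= 0:
        raise ValueError("resolution must be positive")
    length = foot_length_mm or layout.foot_length_mm
    width = foot_width_mm or layout.foot_width_mm
    outline = foot_outline(length, width)
    if (layout.table["foot"] == "R").all():
        # right foot: outline mirrored in x (the default shape is symmetric,
        # but a custom asymmetric outline would need this too)
        outline = shp_scale(outline, xfact=-1.0, origin=(0, 0))
    for _, row in layout.table.iterrows():
        if not outline.covers(Point(row["x_mm"], row["y_mm"])):
            raise ValueError(
                f"sensor {row['id']!r} at ({row['x_mm']}, {row['y_mm']}) "
                "lies outside the foot outline"
            )
    minx, miny, maxx, maxy = outline.bounds
    # x grid symmetric about the foot axis, so mirroring a layout mirrors
    # the raster exactly
    half_span = max(abs(minx), abs(maxx))
    half = np.arange(resolution_mm / 2, half_span, resolution_mm)
    x = np.concatenate([-half[::-1], half])
    y = np.arange(miny + resolution_mm / 2, maxy, resolution_mm)
    xx, yy = np.meshgrid(x, y)
    mask = shapely.contains_xy(outline, xx.ravel(), yy.ravel()).reshape(xx.shape)
    return FootTemplate(
        mask=mask,
        x_mm=x,
        y_mm=y,
        resolution_mm=resolution_mm,
        foot_length_mm=length,
        foot_width_mm=width,
    )


def _scattered_interpolator(points: np.ndarray, values: np.ndarray):
    """Linear scattered interpolation with nearest-site fill outside the hull."""
    if points.shape[0] < 3:
        raise ValueError("need at least 3 sensor sites to interpolate")
    try:
        lin = LinearNDInterpolator(points, values)
    except QhullError as exc:
        raise ValueError("sensor sites are collinear; cannot triangulate") from exc
    near = NearestNDInterpolator(points, values)

    def interp(x, y):
        z = lin(x, y)
        hole = np.isnan(z)
        if np.any(hole):
            z = np.where(hole, near(x, y), z)
        return z

    return interp


def interpolate_map(
    values,
    layout: SensorLayout,
    template: FootTemplate,
    kind: str = "pressure",
    units: str = "N",
    phase: Optional[str] = None,
) -> PlantarMap:
    """Spread one scalar per sensor site of a kind over the foot template."""
    points = layout.xy(kind)
    vals = np.asarray(values, dtype=float)
    if vals.shape != (points.shape[0],):
        raise ValueError(
            f"expected {points.shape[0]} values for kind {kind!r}, "
            f"got shape {vals.shape}"
        )
    interp = _scattered_interpolator(points, vals)
    xx, yy = np.meshgrid(template.x_mm, template.y_mm)
    grid = interp(xx, yy)
    grid = np.where(template.mask, grid, np.nan)
    return PlantarMap(grid=grid, template=template, units=units, phase=phase)


def _frame_forces(
    trial: Trial, index: int, cfg: DividerConfig, fsr_model: FSRForceModel
) -> np.ndarray:
    counts = np.asarray(trial.frames[index].pressure_adc, dtype=float)
    forces = np.zeros_like(counts)
    loaded = counts > 0
    if np.any(loaded):
        v = cal.adc_to_voltage(counts[loaded], cfg)
        full = v >= cfg.vcc
        f = np.empty_like(v)
        if np.any(~full):
            r = cal.resistance_from_voltage(v[~full], cfg)
            f[~full] = cal.force_from_resistance(r, fsr_model)
        f[full] = fsr_model.max_force
        forces[loaded] = f
    return forces


def phase_pressure_maps(
    trial: Trial,
    cycle: GaitCycle,
    layout: SensorLayout,
    template: FootTemplate,
    phases: Optional[dict[str, float] | Sequence[float]] = None,
    cfg: DividerConfig = DividerConfig(),
    fsr_model: FSRForceModel = FSRForceModel(),
) -> list[PlantarMap]:
    """One pressure map per gait phase (fractions of the cycle, 0..1).

    For each phase the frame nearest to start + phase x cycle span is
    calibrated to per-channel forces and interpolated over the template.
    """
    if phases is None:
        phases = DEFAULT_PHASES
    if not isinstance(phases, dict):
        phases = {f"phase_{p:g}": float(p) for p in phases}
    span = cycle.end_index - cycle.start_index
    out = []
    for label, p in phases.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"phase {label}={p} outside [0, 1]")
        # floor, not round: keeps a phase at the stance/swing boundary
        # (toe-off) on the last loaded frame rather than the first swing one
        idx = cycle.start_index + int(p * (span - 1))
        if idx >= len(trial.frames):
            raise ValueError(f"phase {label} falls outside the trial")
        forces = _frame_forces(trial, idx, cfg, fsr_model)
        out.append(
            interpolate_map(
                forces, layout, template, kind="pressure", units="N", phase=label
            )
        )
    return out


def standing_temperature_map(
    trial: Trial,
    layout: SensorLayout,
    template: FootTemplate,
    window_s: float = 10.0,
    cfg: DividerConfig = DividerConfig(),
    thermistor: ThermistorModel = ThermistorModel(),
) -> PlantarMap:
    """Temperature map from a quiet-standing capture.

    Counts are converted per frame through the thermistor calibration
    and averaged over the first ``window_s`` seconds per channel.
    """
    n_window = int(round(window_s * trial.sampling_rate))
    if n_window < 1 or n_window > len(trial.frames):
        raise ValueError(
            f"window of {window_s} s needs {n_window} frames, "
            f"trial has {len(trial.frames)}"
        )
    counts = np.asarray(
        [f.temperature_adc for f in trial.frames[:n_window]], dtype=float
    )
    temps = cal.temperature_from_adc(counts, cfg, thermistor)
    mean_temp = temps.mean(axis=0)
    return interpolate_map(
        mean_temp, layout, template, kind="temperature", units="degC"
    )
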