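"""Battery-life arithmetic for the wearable unit.

A single Li-ion/LiPo cell powers the insole electronics.  With the
default 1300 mAh cell at 3.7 V nominal, the energy rating is about
4.81 Wh; at the measured consumption of roughly 0.4 Wh per hour the
unit runs for about 12 h, i.e. about 24 days of half-hour daily use.
Consumption is a user input (it depends on the radio duty cycle and
hardware revision), not something this module models.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PowerBudget", "energy_wh", "runtime_h", "days_of_use"]


@dataclass(frozen=True)
class PowerBudget:
    capacity_mah: float = 1300.0
    nominal_voltage: float = 3.7
    consumption_wh_per_h: float = 0.4
    daily_use_h: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "capacity_mah",
            "nominal_voltage",
            "consumption_wh_per_h",
            "daily_use_h",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def energy_wh(budget: PowerBudget = PowerBudget()) -> float:
    """Battery energy (Wh) = capacity (mAh) x nominal voltage / 1000."""
    return budget.capacity_mah * budget.nominal_voltage / 1000.0


def runtime_h(budget: PowerBudget = PowerBudget()) -> float:
    """Continuous runtime (h) = energy / consumption rate."""
    return energy_wh(budget) / budget.consumption_wh_per_h


def days_of_use(budget: PowerBudget = PowerBudget()) -> float:
    """Days until depletion at the given daily usage."""
    return runtime_h(budget) / budget.daily_use_h
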