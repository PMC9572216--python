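"""Sensor layout: per-channel anatomical coordinates in the foot frame.

Coordinates are expressed in a foot-local frame: origin at the heel
centre, +y toward the toes, +x toward the lateral side, millimetres.
The channel order declared here IS the canonical multiplexing order of
the codec — nothing downstream reorders channels.

The original hardware's sensor placements are not published as
coordinates, so the layout shipped with the package (``default_layout``
and ``data/default_layout.csv``) is a reconstruction on a 260 mm
template: 16 pressure sites (3 toe,
5 metatarsal, 2 lateral midfoot, 2 medial arch, 4 heel) and 8
temperature sites (1 hallux, 3 metatarsal, 1 midfoot, 3 heel).  All map
and simulator code is driven by the layout object, never by these
particular numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SensorLayout", "default_layout", "load_layout", "save_layout"]

_COLUMNS = ["id", "kind", "foot", "x_mm", "y_mm"]

# (id, kind, x_mm, y_mm) for a LEFT foot on a 260 mm template
_DEFAULT_SITES = [
    # pressure: heel (4)
    ("p_heel_m", "pressure", -15.0, 25.0),
    ("p_heel_l", "pressure", 15.0, 25.0),
    ("p_heel_m2", "pressure", -18.0, 48.0),
    ("p_heel_l2", "pressure", 18.0, 48.0),
    # pressure: medial arch (2)
    ("p_arch_1", "pressure", -20.0, 100.0),
    ("p_arch_2", "pressure", -15.0, 125.0),
    # pressure: lateral midfoot (2)
    ("p_mid_l1", "pressure", 25.0, 105.0),
    ("p_mid_l2", "pressure", 28.0, 130.0),
    # pressure: metatarsal heads (5)
    ("p_met_1", "pressure", -30.0, 180.0),
    ("p_met_2", "pressure", -15.0, 186.0),
    ("p_met_3", "pressure", 0.0, 188.0),
    ("p_met_4", "pressure", 16.0, 184.0),
    ("p_met_5", "pressure", 30.0, 176.0),
    # pressure: toes (3)
    ("p_toe_hallux", "pressure", -22.0, 232.0),
    ("p_toe_2", "pressure", 0.0, 238.0),
    ("p_toe_3", "pressure", 20.0, 228.0),
    # temperature: hallux (1), metatarsal (3), midfoot (1), heel (3)
    ("t_hallux", "temperature", -18.0, 230.0),
    ("t_met_1", "temperature", -20.0, 178.0),
    ("t_met_2", "temperature", 0.0, 182.0),
    ("t_met_3", "temperature", 22.0, 175.0),
    ("t_mid", "temperature", 5.0, 115.0),
    ("t_heel_1", "temperature", 0.0, 30.0),
    ("t_heel_2", "temperature", -14.0, 45.0),
    ("t_heel_3", "temperature", 14.0, 45.0),
]


@dataclass(frozen=True)
class SensorLayout:
    """Per-channel ids, kinds and foot-frame coordinates (one foot).

    Wraps a DataFrame with columns id, kind (pressure|temperature),
    foot (L|R), x_mm, y_mm; row order is the canonical channel order.
    """

    table: pd.DataFrame
    foot_length_mm: float = 260.0
    foot_width_mm: float = 95.0

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in _COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"layout table missing columns {missing}")
        if t["id"].duplicated().any():
            dup = t.loc[t["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate channel ids {dup}")
        bad = set(t["kind"]) - {"pressure", "temperature"}
        if bad:
            raise ValueError(f"unknown channel kinds {bad}")

    def _of_kind(self, kind: str) -> pd.DataFrame:
        return self.table[self.table["kind"] == kind]

    @property
    def pressure(self) -> pd.DataFrame:
        return self._of_kind("pressure")

    @property
    def temperature(self) -> pd.DataFrame:
        return self._of_kind("temperature")

    def xy(self, kind: str) -> np.ndarray:
        """(n, 2) array of site coordinates for one channel kind."""
        sub = self._of_kind(kind)
        return sub[["x_mm", "y_mm"]].to_numpy(dtype=float)

    def anterior_fraction(self, kind: str = "pressure") -> np.ndarray:
        """Normalized heel->toe position (0..1) of each site of a kind."""
        return self.xy(kind)[:, 1] / self.foot_length_mm

    def mirrored(self) -> "SensorLayout":
        """Layout for the contralateral foot (x negated, foot tag flipped)."""
        t = self.table.copy()
        t["x_mm"] = -t["x_mm"]
        t["foot"] = t["foot"].map({"L": "R", "R": "L"})
        return SensorLayout(t, self.foot_length_mm, self.foot_width_mm)


def default_layout(foot: str = "L") -> SensorLayout:
    """The packaged reconstructed 24-channel layout for one foot."""
    rows = [
        {"id": i, "kind": k, "foot": "L", "x_mm": x, "y_mm": y}
        for i, k, x, y in _DEFAULT_SITES
    ]
    layout = SensorLayout(pd.DataFrame(rows, columns=_COLUMNS))
    return layout if foot == "L" else layout.mirrored()


def load_layout(path=None) -> SensorLayout:
    """Read a layout CSV; with no path, the packaged default layout file."""
    if path is None:
        ref = resources.files("insolekit").joinpath("data/default_layout.csv")
        with resources.as_file(ref) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(Path(path))
    return SensorLayout(table)


def save_layout(layout: SensorLayout, path) -> None:
    layout.table.to_csv(Path(path), index=False)
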