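"""Frame encoding and trial log I/O.

Each 40 Hz sample from one insole is multiplexed into a single
comma-delimited line: timestamp (s, 3 decimals), foot tag (L/R), the 16
pressure-channel ADC counts in canonical layout order, then the 8
temperature-channel counts.  A stream carries one ``#``-prefixed header
line with the schema version and the server/characteristic identifiers
of the wireless link (stand-ins for the BLE UUIDs), followed by a CSV
column header; the radio itself is out of scope — files and pipes stand
in for it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .calibration import DividerConfig

__all__ = [
    "Frame",
    "Trial",
    "MalformedFrameError",
    "N_PRESSURE",
    "N_TEMPERATURE",
    "encode_frame",
    "decode_frame",
    "write_log",
    "read_log",
]

N_PRESSURE = 16
N_TEMPERATURE = 8
N_CHANNELS = N_PRESSURE + N_TEMPERATURE

SCHEMA_VERSION = "1"
DEFAULT_SERVER_ID = "insole-server-0001"
DEFAULT_CHARACTERISTIC_ID = "frame-stream-0001"

_FOOT_TAGS = ("L", "R")


class MalformedFrameError(ValueError):
    """A serialized frame line that cannot be parsed into a valid Frame."""


@dataclass(frozen=True)
class Frame:
    """One multiplexed insole sample: 16 pressure + 8 temperature counts."""

    timestamp: float
    foot: str
    pressure_adc: tuple[int, ...]
    temperature_adc: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.foot not in _FOOT_TAGS:
            raise ValueError(f"foot must be one of {_FOOT_TAGS}, got {self.foot!r}")
        if len(self.pressure_adc) != N_PRESSURE:
            raise ValueError(
                f"expected {N_PRESSURE} pressure channels, got {len(self.pressure_adc)}"
            )
        if len(self.temperature_adc) != N_TEMPERATURE:
            raise ValueError(
                f"expected {N_TEMPERATURE} temperature channels, "
                f"got {len(self.temperature_adc)}"
            )


@dataclass
class Trial:
    """A time-ordered sequence of frames from one walk or standing capture."""

    frames: list[Frame] = field(default_factory=list)
    sampling_rate: float = 40.0
    trial_id: str = "trial"
    subject_id: Optional[str] = None

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        return len(self.frames) / self.sampling_rate


def encode_frame(frame: Frame) -> str:
    """Serialize one frame to its single-line wire/log format."""
    counts = ",".join(
        str(int(c)) for c in (*frame.pressure_adc, *frame.temperature_adc)
    )
    return f"{frame.timestamp:.3f},{frame.foot},{counts}"


def decode_frame(line: str, cfg: DividerConfig = DividerConfig()) -> Frame:
    """Parse a frame line, validating field count and ADC ranges."""
    fields = line.strip().split(",")
    if len(fields) != 2 + N_CHANNELS:
        raise MalformedFrameError(
            f"expected {N_CHANNELS} channel fields, got {len(fields) - 2}"
        )
    try:
        ts = float(fields[0])
    except ValueError as exc:
        raise MalformedFrameError(f"non-numeric timestamp {fields[0]!r}") from exc
    foot = fields[1]
    if foot not in _FOOT_TAGS:
        raise MalformedFrameError(f"unknown foot tag {foot!r}")
    counts = []
    for pos, tok in enumerate(fields[2:], start=1):
        try:
            c = int(tok)
        except ValueError as exc:
            raise MalformedFrameError(
                f"non-numeric count {tok!r} at channel position {pos}"
            ) from exc
        if not 0 <= c <= cfg.adc_max:
            raise MalformedFrameError(
                f"count {c} at channel position {pos} outside [0, {cfg.adc_max}]"
            )
        counts.append(c)
    return Frame(
        timestamp=ts,
        foot=foot,
        pressure_adc=tuple(counts[:N_PRESSURE]),
        temperature_adc=tuple(counts[N_PRESSURE:]),
    )


def _header_lines(trial: Trial) -> list[str]:
    meta = (
        f"# insole-log v{SCHEMA_VERSION}"
        f" server={DEFAULT_SERVER_ID}"
        f" characteristic={DEFAULT_CHARACTERISTIC_ID}"
        f" rate_hz={trial.sampling_rate:g}"
        f" trial={trial.trial_id}"
        f" subject={trial.subject_id or '-'}"
    )
    cols = ["timestamp_s", "foot"]
    cols += [f"p{i:02d}" for i in range(N_PRESSURE)]
    cols += [f"t{i}" for i in range(N_TEMPERATURE)]
    return [meta, ",".join(cols)]


def write_log(trial: Trial, path) -> None:
    """Write a trial to a UTF-8 log file (header + one line per frame)."""
    path = Path(path)
    lines = _header_lines(trial)
    lines.extend(encode_frame(f) for f in trial.frames)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _parse_meta(line: str) -> dict:
    meta = {}
    for tok in line.lstrip("# ").split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            meta[k] = v
    return meta


def read_log(path, cfg: DividerConfig = DividerConfig()) -> Trial:
    """Read a trial log; a truncated final line is dropped with a warning."""
    path = Path(path)
    raw = path.read_text(encoding="utf-8")
    lines = raw.split("\n")
    if not lines or not lines[0].startswith("#"):
        raise MalformedFrameError(f"{path}: missing '# insole-log' header")
    meta = _parse_meta(lines[0])
    ended_clean = raw.endswith("\n")
    body = [ln for ln in lines[1:] if ln.strip()]
    if body and body[0].startswith("timestamp"):
        body = body[1:]
    frames: list[Frame] = []
    for i, ln in enumerate(body):
        is_last = i == len(body) - 1
        try:
            frames.append(decode_frame(ln, cfg))
        except MalformedFrameError:
            if is_last and not ended_clean:
                warnings.warn(
                    f"{path}: dropping truncated final frame line", stacklevel=2
                )
                break
            raise
    return Trial(
        frames=frames,
        sampling_rate=float(meta.get("rate_hz", 40.0)),
        trial_id=meta.get("trial", path.stem),
        subject_id=None if meta.get("subject") in (None, "-") else meta["subject"],
    )


def read_frames(lines: Iterable[str], cfg: DividerConfig = DividerConfig()):
    """Decode an iterable of frame lines, skipping headers (streaming use)."""
    for ln in lines:
        ln = ln.strip()
        if not ln or ln.startswith("#") or ln.startswith("timestamp"):
            continue
        yield decode_frame(ln, cfg)
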