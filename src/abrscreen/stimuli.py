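"""Stimulus battery for the ABR screen.

The screen presents a broadband click plus five pure tones (6, 12, 18, 24
and 30 kHz).  Sound levels run on a 5-dB grid; each stimulus has its own
default level window, extended to the 95 dB SPL system maximum when a line
is suspected of hearing impairment.
"""
from __future__ import annotations

from dataclasses import dataclass

LEVEL_STEP_DB: float = 5.0
MAX_LEVEL_DB: float = 95.0
TONE_FREQUENCIES_KHZ: tuple[float, ...] = (6.0, 12.0, 18.0, 24.0, 30.0)


@dataclass(frozen=True)
class StimulusSpec:
    """A click or pure-tone stimulus.

    ``frequency_khz`` is present iff ``kind == "tone"``.  Durations are in
    milliseconds; the click is a 0.01-ms transient, tones are 5-ms pips with
    1-ms rise/fall ramps.
    """

    kind: str  # "click" | "tone"
    frequency_khz: float | None = None
    duration_ms: float = 5.0
    rise_fall_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("click", "tone"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if (self.frequency_khz is None) != (self.kind == "click"):
            raise ValueError("frequency_khz must be present iff kind is 'tone'")
        if self.frequency_khz is not None and self.frequency_khz <= 0:
            raise ValueError("frequency_khz must be positive")
        if self.duration_ms <= 0 or self.rise_fall_ms < 0:
            raise ValueError("invalid stimulus timing parameters")

    @property
    def label(self) -> str:
        """Serialized form: ``"click"`` or ``"tone:<kHz>"``."""
        if self.kind == "click":
            return "click"
        freq = self.frequency_khz
        if freq == int(freq):
            return f"tone:{int(freq)}"
        return f"tone:{freq}"


CLICK = StimulusSpec("click", None, duration_ms=0.01, rise_fall_ms=0.0)


def tone(frequency_khz: float) -> StimulusSpec:
    return StimulusSpec("tone", float(frequency_khz))


def parse_stimulus(label: str) -> StimulusSpec:
    """Inverse of :attr:`StimulusSpec.label`."""
    if label == "click":
        return CLICK
    if label.startswith("tone:"):
        return tone(float(label.split(":", 1)[1]))
    raise ValueError(f"unparseable stimulus label {label!r}")


DEFAULT_BATTERY: tuple[StimulusSpec, ...] = (CLICK,) + tuple(
    tone(f) for f in TONE_FREQUENCIES_KHZ
)

# Per-stimulus level windows (dB SPL) used for time efficiency during the
# screen; the upper limit is raised to MAX_LEVEL_DB for suspected
# hearing-impaired lines.
DEFAULT_LEVEL_WINDOWS: dict[str, tuple[float, float]] = {
    "click": (0.0, 85.0),
    "tone:6": (20.0, 85.0),
    "tone:12": (0.0, 70.0),
    "tone:18": (0.0, 70.0),
    "tone:24": (10.0, 70.0),
    "tone:30": (20.0, 85.0),
}

BATTERY_LABELS: tuple[str, ...] = tuple(s.label for s in DEFAULT_BATTERY)
TONE_LABELS: tuple[str, ...] = tuple(s.label for s in DEFAULT_BATTERY if s.kind == "tone")


def on_grid(level_db: float, step: float = LEVEL_STEP_DB) -> bool:
    """True when a level sits on the 5-dB presentation grid."""
    return abs(level_db / step - round(level_db / step)) < 1e-9


def snap_to_grid(level_db: float, step: float = LEVEL_STEP_DB) -> float:
    """Round to the nearest grid level and clip to [0, MAX_LEVEL_DB]."""
    snapped = round(level_db / step) * step
    return float(min(max(snapped, 0.0), MAX_LEVEL_DB))
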