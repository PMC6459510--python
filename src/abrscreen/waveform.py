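"""Generative model of averaged ABR waveforms.

An averaged ABR to a suprathreshold stimulus is modelled as four
positive-negative wave pairs (P1-N1 ... P4-N4).  Each positive peak is a
Gaussian bump; its trough is an equal-magnitude negative bump offset by a
fixed multiple of the bump width.  Peak amplitude grows linearly with
sensation level (SL, dB above the individual's threshold) and peak latency
shortens linearly with SL, floored at half the base latency — the
characteristic latency lengthening as threshold is approached.  Below
threshold the trace is pure Gaussian recording noise.

The model is deliberately simple: bump centres are analytic, so the peak
picker and threshold detector can be validated against exact oracles.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stimuli import LEVEL_STEP_DB, StimulusSpec, on_grid


@dataclass(frozen=True)
class WaveParams:
    """Level-dependence of one ABR component wave."""

    base_latency_ms: float
    latency_slope_ms_per_db: float
    base_amplitude_uv: float
    amplitude_gain_uv_per_db: float
    width_ms: float  # Gaussian sigma of the bump

    def __post_init__(self) -> None:
        if self.base_latency_ms <= 0 or self.base_amplitude_uv <= 0 or self.width_ms <= 0:
            raise ValueError("latency, amplitude and width must be positive")
        if self.latency_slope_ms_per_db < 0 or self.amplitude_gain_uv_per_db < 0:
            raise ValueError("slopes must be non-negative")

    def latency_ms(self, sl_db: float) -> float:
        lat = self.base_latency_ms - self.latency_slope_ms_per_db * sl_db
        return max(lat, 0.5 * self.base_latency_ms)

    def amplitude_uv(self, sl_db: float) -> float:
        return self.base_amplitude_uv + self.amplitude_gain_uv_per_db * sl_db


@dataclass(frozen=True)
class WaveModel:
    """Four-wave ABR morphology plus recording parameters.

    ``trough_offset_sigmas`` places Nk at the Pk latency plus that many bump
    widths.  ``wave2_split`` emulates the empirical splitting of wave 2 into
    a double bump at high levels (>= ``wave2_split_sl_db`` dB SL), which is
    why downstream analysis never quantifies wave-2 amplitude.
    """

    waves: tuple[WaveParams, WaveParams, WaveParams, WaveParams] = (
        WaveParams(1.4, 0.005, 0.55, 0.020, 0.12),
        WaveParams(2.2, 0.005, 0.45, 0.015, 0.12),
        WaveParams(3.1, 0.005, 0.50, 0.018, 0.13),
        WaveParams(4.1, 0.005, 0.35, 0.012, 0.14),
    )
    noise_sd_uv: float = 0.12
    sample_rate_hz: float = 100_000.0
    window_ms: float = 8.0
    trough_offset_sigmas: float = 3.0
    wave2_split: bool = False
    wave2_split_sl_db: float = 40.0

    def __post_init__(self) -> None:
        if len(self.waves) != 4:
            raise ValueError("exactly four component waves required")
        lats = [w.base_latency_ms for w in self.waves]
        if not all(a < b for a, b in zip(lats, lats[1:])):
            raise ValueError("base latencies must be strictly increasing wave 1 -> 4")
        if self.noise_sd_uv < 0:
            raise ValueError("noise sd must be non-negative")
        if self.sample_rate_hz <= 0 or self.window_ms <= 0:
            raise ValueError("sample rate and window must be positive")
        last = self.waves[-1]
        n4 = last.base_latency_ms + self.trough_offset_sigmas * last.width_ms
        if n4 + 2 * last.width_ms > self.window_ms:
            raise ValueError("window too short to contain all four waves at SL 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.window_ms * 1e-3 * self.sample_rate_hz))

    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz * 1e3


DEFAULT_WAVE_MODEL = WaveModel()


def clean_trace(sl_db: float, model: WaveModel) -> np.ndarray:
    """Noise-free ABR waveform at sensation level ``sl_db`` (>= 0)."""
    t = model.times_ms()
    out = np.zeros_like(t)
    for k, w in enumerate(model.waves):
        amp = w.amplitude_uv(sl_db)
        lat = w.latency_ms(sl_db)
        sig = w.width_ms
        if k == 1 and model.wave2_split and sl_db >= model.wave2_split_sl_db:
            # double bump: two sub-peaks within 20% of each other's amplitude
            for sub_lat in (lat - 1.5 * sig, lat + 1.5 * sig):
                out += amp * np.exp(-0.5 * ((t - sub_lat) / sig) ** 2)
        else:
            out += amp * np.exp(-0.5 * ((t - lat) / sig) ** 2)
        trough = lat + model.trough_offset_sigmas * sig
        out -= amp * np.exp(-0.5 * ((t - trough) / sig) ** 2)
    return out


def synth_trace(
    stimulus: StimulusSpec,
    level_db: float,
    true_threshold_db: float,
    model: WaveModel = DEFAULT_WAVE_MODEL,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate one averaged trace (µV per sample).

    Below threshold the trace is pure Gaussian noise with sd
    ``model.noise_sd_uv``; at or above threshold the four-wave morphology is
    added at SL = ``level_db - true_threshold_db``.
    """
    if not on_grid(level_db):
        raise ValueError(f"level {level_db} dB is off the {LEVEL_STEP_DB}-dB grid")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = (
        rng.normal(0.0, model.noise_sd_uv, model.n_samples)
        if model.noise_sd_uv > 0
        else np.zeros(model.n_samples)
    )
    if level_db < true_threshold_db:
        return noise
    return clean_trace(level_db - true_threshold_db, model) + noise


@dataclass
class LevelSeries:
    """Averaged traces for one stimulus over an ascending level ladder."""

    stimulus: str  # serialized label
    levels_db: np.ndarray  # (L,), ascending, on the 5-dB grid
    traces_uv: np.ndarray  # (L, T)
    sample_rate_hz: float
    window_ms: float

    def __post_init__(self) -> None:
        self.levels_db = np.asarray(self.levels_db, dtype=float)
        self.traces_uv = np.asarray(self.traces_uv, dtype=float)
        if self.traces_uv.shape[0] != self.levels_db.shape[0]:
            raise ValueError("one trace per level required")
        if np.any(np.diff(self.levels_db) <= 0):
            raise ValueError("levels must be strictly ascending")

    def times_ms(self) -> np.ndarray:
        return np.arange(self.traces_uv.shape[1]) / self.sample_rate_hz * 1e3

    @property
    def max_level_db(self) -> float:
        return float(self.levels_db[-1])


def generate_level_series(
    stimulus: StimulusSpec,
    true_threshold_db: float,
    model: WaveModel = DEFAULT_WAVE_MODEL,
    level_min: float = 0.0,
    level_max: float = 85.0,
    step_db: float = LEVEL_STEP_DB,
    seed: int | np.random.Generator = 0,
) -> LevelSeries:
    """Simulate the ascending level ladder for one stimulus."""
    if level_min > level_max:
        raise ValueError("empty level range")
    span = level_max - level_min
    if abs(span / step_db - round(span / step_db)) > 1e-9:
        raise ValueError("step must divide the level range")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    levels = level_min + step_db * np.arange(int(round(span / step_db)) + 1)
    traces = np.empty((levels.size, model.n_samples))
    for i, lvl in enumerate(levels):
        traces[i] = synth_trace(stimulus, float(lvl), true_threshold_db, model, rng)
    return LevelSeries(stimulus.label, levels, traces, model.sample_rate_hz, model.window_ms)
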