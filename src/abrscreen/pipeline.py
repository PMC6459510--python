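"""End-to-end orchestration: simulate -> measure -> reference -> call -> summarise."""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as abr_io
from .calling import (
    LineCall,
    ReferenceRange,
    bonferroni,
    build_reference_range,
    call_line,
    fraction_pct,
    hit_rate_and_extrapolate,
    screen_fdr,
)
from .config import PipelineConfig
from .metrics import DetectorParams, estimate_threshold
from .simulate import DEFAULT_POP_PARAMS, attach_waveforms, generate_screen
from .types import MouseRecord, ScreenDataset, ThresholdProfile
from .waveform import DEFAULT_WAVE_MODEL, WaveModel

__all__ = [
    "build_reference",
    "measure_thresholds",
    "ScreenSummary",
    "summarize_screen",
    "run_screen_pipeline",
]


def build_reference(
    controls: Sequence[MouseRecord], convention: str = "linear"
) -> dict[str, ReferenceRange]:
    """Per-stimulus reference ranges from the control cohort's thresholds."""
    if not controls:
        raise ValueError("no control mice")
    stimuli = controls[0].thresholds.stimuli
    return {
        s: build_reference_range([m.thresholds.level(s) for m in controls], convention)
        for s in stimuli
    }


def measure_thresholds(
    mice: Sequence[MouseRecord], detector: DetectorParams = DetectorParams()
) -> None:
    """Re-estimate each mouse's thresholds from its waveform series, in place."""
    for mouse in mice:
        if not mouse.series:
            raise ValueError(f"mouse {mouse.mouse_id} has no waveform series")
        entries = {}
        for s, series in mouse.series.items():
            est = estimate_threshold(series, detector)
            entries[s] = est.threshold
        mouse.thresholds = ThresholdProfile(entries)


@dataclass
class ScreenSummary:
    n_genes_screened: int
    n_hits: int
    hit_rate_pct: float
    n_false_positive_rule60: int
    n_false_positive_rule20: int
    fdr_rule60_pct: float
    fdr_rule20_pct: float
    genome_size: int
    estimated_remaining: int
    bonferroni_alpha: float

    def __post_init__(self) -> None:
        if not (0 <= self.n_hits <= self.n_genes_screened):
            raise ValueError("n_hits must be within [0, n_genes_screened]")

    def as_mapping(self) -> dict[str, object]:
        return dict(vars(self))


def summarize_screen(
    calls: Sequence[LineCall],
    genome_size: int,
    alpha: float = 0.05,
    truth: Mapping[str, str] | None = None,
) -> ScreenSummary:
    """Screen arithmetic from the per-line calls.

    With ground truth available (simulation), false positives per rule are
    calls on lines whose true class is Normal; otherwise the review flags
    stand in for the human false-positive assessment.
    """
    n = len(calls)
    hits = [c for c in calls if c.called]
    if truth is not None:
        fp60 = sum(1 for c in calls if c.rule60 and truth.get(c.line_id) == "Normal")
        fp20 = sum(1 for c in calls if c.rule20 and truth.get(c.line_id) == "Normal")
    else:
        fp60 = sum(1 for c in hits if c.rule60 and c.review_flags)
        fp20 = sum(1 for c in hits if c.rule20 and c.review_flags)
    rate, remaining = hit_rate_and_extrapolate(len(hits), n, genome_size)
    return ScreenSummary(
        n_genes_screened=n,
        n_hits=len(hits),
        hit_rate_pct=rate,
        n_false_positive_rule60=fp60,
        n_false_positive_rule20=fp20,
        fdr_rule60_pct=screen_fdr(fp60, n),
        fdr_rule20_pct=screen_fdr(fp20, n),
        genome_size=genome_size,
        estimated_remaining=remaining,
        bonferroni_alpha=bonferroni(alpha, max(n, 1)),
    )


def run_screen_pipeline(
    config: PipelineConfig,
    outdir: str | Path | None = None,
    model: WaveModel = DEFAULT_WAVE_MODEL,
) -> tuple[ScreenSummary, list[LineCall], ScreenDataset]:
    """Simulate and analyse a full screen under one configuration.

    Deterministic given ``config.seed``.  When ``simulate_waveforms`` is on,
    thresholds are re-estimated from simulated traces (controls on default
    level windows, mutant lines extended to 95 dB SPL); otherwise the
    generated thresholds are used directly.  Writes every stage's tables
    when ``outdir`` is given.
    """
    dataset = generate_screen(
        n_lines=config.n_lines,
        class_mixture=config.class_mixture,
        n_per_line=config.n_per_line,
        n_controls=config.n_controls,
        pop=DEFAULT_POP_PARAMS,
        seed=config.seed,
        inter_mouse_sd_db=config.inter_mouse_sd_db,
        outlier_prob=config.outlier_prob,
    )
    if config.simulate_waveforms:
        det = DetectorParams(
            corr_threshold=config.detector.corr_threshold,
            rms_ratio_threshold=config.detector.rms_ratio_threshold,
            max_lag_ms=config.detector.max_lag_ms,
        )
        rng = np.random.default_rng(config.seed + 1)
        attach_waveforms(dataset.controls, model, seed=int(rng.integers(2**31)))
        measure_thresholds(dataset.controls, det)
        for line in dataset.lines:
            impaired = line.spec.class_label != "Normal"
            attach_waveforms(
                line.mice, model, seed=int(rng.integers(2**31)), extend_to_max=impaired
            )
            measure_thresholds(line.mice, det)
            for m in line.mice:  # raw traces are bulky; keep the measurements
                m.series = None

    ref = build_reference(dataset.controls, config.percentile_convention)
    alpha_corrected = bonferroni(config.alpha, max(config.n_lines, 1))
    control_profiles = [m.thresholds for m in dataset.controls]
    calls = [
        call_line(
            line.line_id,
            [m.thresholds for m in line.mice],
            control_profiles,
            ref,
            alpha_corrected,
            denominator=config.rule60_denominator,
            pooling=config.fisher_pooling,
            ceiling_mode=config.ceiling_mode,
            low_frequency_as_printed=config.low_frequency_as_printed,
        )
        for line in dataset.lines
    ]
    truth = {line.line_id: line.spec.class_label for line in dataset.lines}
    summary = summarize_screen(calls, config.genome_size, config.alpha, truth)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        abr_io.write_screen_dataset(dataset, outdir)
        abr_io._write(abr_io.reference_table(ref), outdir / "reference_ranges.tsv")
        abr_io._write(abr_io.calls_table(calls), outdir / "calls.tsv")
        abr_io._write(abr_io.heatmap_table(calls), outdir / "heatmap.tsv")
        abr_io._write(abr_io.summary_table(summary.as_mapping()), outdir / "summary.tsv")
        config.to_yaml(outdir / "config.yaml")
    return summary, calls, dataset
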