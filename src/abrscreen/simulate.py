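"""Synthetic cohorts with the statistical structure the screen assumes.

Control thresholds per stimulus are drawn from a contaminated normal (95%
N(median, sd), 5% N(median, 3 sd)) — screens of this kind find control
threshold distributions significantly non-normal — then rounded to the 5-dB
presentation grid and clipped at the 95 dB SPL ceiling.  Mutant lines add a
per-stimulus threshold shift encoding one of five audiogram classes (or
none); the shift pattern is validated against the downstream classification
rules, so a line labelled e.g. HighFrequency is guaranteed to classify as
such in the noise-free limit.

Sex is generated but carries no effect: large wild-type cohorts show no sex
difference in ABR thresholds.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import calling
from .stimuli import (
    BATTERY_LABELS,
    DEFAULT_BATTERY,
    DEFAULT_LEVEL_WINDOWS,
    MAX_LEVEL_DB,
    on_grid,
    parse_stimulus,
)
from .types import (
    AssocCohort,
    MouseRecord,
    ScreenDataset,
    ScreenLine,
    SyntheticLineSpec,
    Threshold,
    ThresholdProfile,
)
from .waveform import DEFAULT_WAVE_MODEL, WaveModel, generate_level_series

__all__ = [
    "PopulationParams",
    "DEFAULT_POP_PARAMS",
    "CLASS_SHIFT_TEMPLATES",
    "default_line_spec",
    "sample_control_values",
    "generate_control_cohort",
    "generate_mutant_line",
    "generate_screen",
    "attach_waveforms",
    "generate_assoc_cohort",
]


@dataclass(frozen=True)
class PopulationParams:
    """Control threshold distribution per stimulus.

    ``heavy_tail_frac`` of draws come from a ``heavy_tail_scale``-times
    wider normal, reproducing the heavy tails of real control data; set the
    fraction to 0 for a pure normal.
    """

    medians: Mapping[str, float]
    sds: Mapping[str, float]
    heavy_tail_frac: float = 0.05
    heavy_tail_scale: float = 3.0

    def __post_init__(self) -> None:
        for s, m in self.medians.items():
            if not on_grid(m):
                raise ValueError(f"population median for {s} must sit on the 5-dB grid")
        if any(sd < 0 for sd in self.sds.values()):
            raise ValueError("negative population sd")
        if not (0.0 <= self.heavy_tail_frac <= 1.0):
            raise ValueError("heavy_tail_frac must be in [0, 1]")

    @property
    def stimuli(self) -> tuple[str, ...]:
        return tuple(self.medians)


# Typical 14-week C57BL/6N-background sensitivities: best in the 12-24 kHz
# region, poorer at the band edges.
DEFAULT_POP_PARAMS = PopulationParams(
    medians={
        "click": 20.0,
        "tone:6": 35.0,
        "tone:12": 20.0,
        "tone:18": 15.0,
        "tone:24": 25.0,
        "tone:30": 35.0,
    },
    sds={s: 5.0 for s in BATTERY_LABELS},
)

# Per-class threshold-shift templates (dB added to the control median).
# Effects are well separated from the class decision boundaries so that the
# classifier recovers the label despite inter-mouse scatter.
CLASS_SHIFT_TEMPLATES: dict[str, dict[str, float]] = {
    "SevereProfound": {s: 100.0 for s in BATTERY_LABELS},
    "HighFrequency": {"tone:30": 45.0},
    "LowFrequency": {"tone:6": 35.0, "tone:12": 35.0},
    "Moderate": {s: 30.0 for s in BATTERY_LABELS},
    "Mild": {"click": 20.0, "tone:12": 20.0},
    "Normal": {},
}


_IDEAL_REF_CACHE: dict[tuple, dict[str, calling.ReferenceRange]] = {}


def _idealized_reference(pop: PopulationParams) -> dict[str, calling.ReferenceRange]:
    """Analytic large-n reference ranges of the control mixture (used for
    the noise-free class-consistency check)."""
    from scipy import stats as ss

    key = (
        tuple(sorted(pop.medians.items())),
        tuple(sorted(pop.sds.items())),
        pop.heavy_tail_frac,
        pop.heavy_tail_scale,
    )
    if key in _IDEAL_REF_CACHE:
        return _IDEAL_REF_CACHE[key]
    refs = {}
    for s in pop.stimuli:
        sd = pop.sds[s]
        # 97.5th quantile of the contaminated normal, by bisection
        def tail(x: float) -> float:
            return (1 - pop.heavy_tail_frac) * ss.norm.sf(x, 0, sd) + (
                pop.heavy_tail_frac * ss.norm.sf(x, 0, pop.heavy_tail_scale * sd)
                if pop.heavy_tail_frac > 0
                else 0.0
            )

        lo, hi = 0.0, 10.0 * sd * pop.heavy_tail_scale + 1.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if tail(mid) > 0.025:
                lo = mid
            else:
                hi = mid
        q = 0.5 * (lo + hi)
        med = pop.medians[s]
        refs[s] = calling.ReferenceRange(med - q, med, med + q, n=10**6)
    _IDEAL_REF_CACHE[key] = refs
    return refs


def validate_line_spec(
    spec: SyntheticLineSpec,
    pop: PopulationParams,
    low_frequency_as_printed: bool = False,
) -> None:
    """Reject a spec whose shift pattern is inconsistent with its class.

    The check classifies the noise-free shifted audiogram against analytic
    control ranges and requires the downstream category to match.
    """
    refs = _idealized_reference(pop)
    levels, ceilings = {}, {}
    for s in pop.stimuli:
        raw = pop.medians[s] + spec.shift_db.get(s, 0.0)
        levels[s] = min(round(raw / 5.0) * 5.0, MAX_LEVEL_DB)
        ceilings[s] = raw > MAX_LEVEL_DB
    profile = ThresholdProfile.from_values(levels, ceilings)
    got = calling.classify_audiogram(
        [profile] * max(spec.n_mutants, 2), refs, low_frequency_as_printed
    )
    if got != spec.class_label:
        raise ValueError(
            f"shift pattern classifies as {got!r}, inconsistent with declared "
            f"class {spec.class_label!r}"
        )


def default_line_spec(
    class_label: str,
    inter_mouse_sd_db: float = 5.0,
    outlier_prob: float = 0.0,
    n_mutants: int = 4,
) -> SyntheticLineSpec:
    """Canonical line spec for one audiogram class."""
    return SyntheticLineSpec(
        class_label=class_label,
        shift_db=dict(CLASS_SHIFT_TEMPLATES[class_label]),
        inter_mouse_sd_db=inter_mouse_sd_db,
        outlier_prob=outlier_prob,
        n_mutants=n_mutants,
    )


def _draw_raw(
    rng: np.random.Generator,
    n: int,
    median: float,
    sd: float,
    heavy_tail_frac: float,
    heavy_tail_scale: float,
) -> np.ndarray:
    """Continuous threshold draws from the contaminated normal."""
    sds = np.full(n, sd)
    if heavy_tail_frac > 0:
        heavy = rng.random(n) < heavy_tail_frac
        sds[heavy] = sd * heavy_tail_scale
    return median + rng.normal(0.0, 1.0, n) * sds


def sample_control_values(
    pop: PopulationParams, n: int, seed: int
) -> pd.DataFrame:
    """Continuous (pre-quantisation) control threshold draws, one column per
    stimulus — the latent scale on which reference-range coverage is exact."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            s: _draw_raw(rng, n, pop.medians[s], pop.sds[s], pop.heavy_tail_frac, pop.heavy_tail_scale)
            for s in pop.stimuli
        }
    )


def _quantize(raw: float) -> Threshold:
    level = min(max(round(raw / 5.0) * 5.0, 0.0), MAX_LEVEL_DB)
    return Threshold(level, ceiling=raw > MAX_LEVEL_DB)


def _profile_from_raw(raw: Mapping[str, float]) -> ThresholdProfile:
    return ThresholdProfile({s: _quantize(v) for s, v in raw.items()})


def generate_control_cohort(
    pop: PopulationParams = DEFAULT_POP_PARAMS,
    n: int = 100,
    seed: int = 0,
    id_prefix: str = "C",
) -> list[MouseRecord]:
    """Wild-type control cohort with no sex effect on thresholds."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    raw = {
        s: _draw_raw(rng, n, pop.medians[s], pop.sds[s], pop.heavy_tail_frac, pop.heavy_tail_scale)
        for s in pop.stimuli
    }
    sexes = rng.choice(["M", "F"], size=n)
    mice = []
    for i in range(n):
        profile = _profile_from_raw({s: raw[s][i] for s in pop.stimuli})
        mice.append(
            MouseRecord(
                mouse_id=f"{id_prefix}{i + 1:05d}",
                genotype="wt",
                sex=str(sexes[i]),
                line_id="control",
                thresholds=profile,
                true_threshold=profile,
            )
        )
    return mice


def generate_mutant_line(
    spec: SyntheticLineSpec,
    pop: PopulationParams = DEFAULT_POP_PARAMS,
    seed: int = 0,
    line_id: str = "L0001",
    genotype: str = "hom",
    low_frequency_as_printed: bool = False,
) -> list[MouseRecord]:
    """Mutant cohort: control-like draws plus the class shift pattern.

    With probability ``outlier_prob`` one mouse receives no shift, emulating
    a segregating independent mutation / clear-outlier artefact.
    """
    validate_line_spec(spec, pop, low_frequency_as_printed)
    rng = np.random.default_rng(seed)
    outlier_idx = -1
    if spec.outlier_prob > 0 and rng.random() < spec.outlier_prob:
        outlier_idx = int(rng.integers(spec.n_mutants))
    sexes = rng.choice(["M", "F"], size=spec.n_mutants)
    mice = []
    for i in range(spec.n_mutants):
        raw = {}
        for s in pop.stimuli:
            base = _draw_raw(
                rng, 1, pop.medians[s], spec.inter_mouse_sd_db, pop.heavy_tail_frac, pop.heavy_tail_scale
            )[0]
            shift = 0.0 if i == outlier_idx else spec.shift_db.get(s, 0.0)
            raw[s] = base + shift
        profile = _profile_from_raw(raw)
        mice.append(
            MouseRecord(
                mouse_id=f"{line_id}-M{i + 1:02d}",
                genotype=genotype,
                sex=str(sexes[i]),
                line_id=line_id,
                thresholds=profile,
                true_threshold=profile,
            )
        )
    return mice


def generate_screen(
    n_lines: int,
    class_mixture: Mapping[str, float],
    n_per_line: int = 4,
    n_controls: int = 200,
    pop: PopulationParams = DEFAULT_POP_PARAMS,
    seed: int = 0,
    inter_mouse_sd_db: float = 5.0,
    outlier_prob: float = 0.0,
) -> ScreenDataset:
    """Simulate a full screen: shared controls plus ``n_lines`` cohorts with
    ground-truth class labels drawn from ``class_mixture``."""
    total = sum(class_mixture.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class mixture sums to {total}, not 1")
    if n_per_line < 4:
        raise ValueError("screen protocol requires >= 4 mutant mice per line")
    unknown = set(class_mixture) - set(calling.AUDIOGRAM_CLASSES)
    if unknown:
        raise ValueError(f"unknown audiogram classes {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    controls = generate_control_cohort(pop, n_controls, seed=int(rng.integers(2**31)))
    classes = list(class_mixture)
    probs = np.array([class_mixture[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    lines = []
    for i in range(n_lines):
        label = classes[int(rng.choice(len(classes), p=probs))]
        spec = default_line_spec(
            label, inter_mouse_sd_db, outlier_prob, n_mutants=n_per_line
        )
        line_id = f"L{i + 1:04d}"
        mice = generate_mutant_line(
            spec, pop, seed=int(rng.integers(2**31)), line_id=line_id
        )
        lines.append(ScreenLine(line_id, spec, mice))
    return ScreenDataset(controls=controls, lines=lines, seed=seed)


def attach_waveforms(
    mice: Sequence[MouseRecord],
    model: WaveModel = DEFAULT_WAVE_MODEL,
    seed: int = 0,
    extend_to_max: bool = False,
    battery=DEFAULT_BATTERY,
) -> None:
    """Simulate per-stimulus level ladders for each mouse, in place.

    ``extend_to_max`` raises every ladder's upper limit to 95 dB SPL, as the
    protocol does for suspected hearing-impaired lines.  The mouse's
    ``true_threshold`` drives the generative model; measured thresholds are
    then re-estimated downstream from these traces.
    """
    rng = np.random.default_rng(seed)
    for mouse in mice:
        if mouse.true_threshold is None:
            raise ValueError("waveform simulation needs ground-truth thresholds")
        series = {}
        for stim in battery:
            lo, hi = DEFAULT_LEVEL_WINDOWS[stim.label]
            if extend_to_max:
                hi = MAX_LEVEL_DB
            true = mouse.true_threshold.level(stim.label)
            if mouse.true_threshold.is_ceiling(stim.label):
                true = MAX_LEVEL_DB + 5.0  # no response anywhere in the ladder
            series[stim.label] = generate_level_series(
                stim, true, model, lo, hi, seed=rng
            )
        mouse.series = series


def generate_assoc_cohort(
    n: int,
    n_markers: int = 25,
    maf: float = 0.3,
    beta_per_allele: float = 0.0,
    causal_index: int | None = None,
    gene_interval_bp: tuple[int, int] = (1_000_000, 1_050_000),
    flank_bp: int = 100_000,
    seed: int = 0,
    trait_names: tuple[str, str] = ("1kHz", "4kHz"),
    causal_trait: str = "4kHz",
    intercept_log: float = 3.0,
    sex_effect_log: float = 0.10,
    n_nuisance_levels: int = 3,
    nuisance_sd_log: float = 0.05,
    noise_sd_log: float = 0.35,
) -> AssocCohort:
    """Simulate a candidate-gene association cohort.

    Allele counts are Binomial(2, maf) independently per marker; the raw
    trait is exp(intercept + beta x count + covariate effects + noise), so
    the log-scale model is exactly linear.  Marker positions span the gene
    interval plus ``flank_bp`` on each side.
    """
    if n < 10:
        raise ValueError("degenerate fit: need n >= 10 individuals")
    if not (0.0 < maf <= 0.5):
        raise ValueError("maf must be in (0, 0.5]")
    if causal_index is None:
        causal_index = n_markers // 2
    if not (0 <= causal_index < n_markers):
        raise ValueError("causal_index out of range")
    g_start, g_end = gene_interval_bp
    if g_start > g_end:
        raise ValueError("invalid gene interval")
    rng = np.random.default_rng(seed)
    genotypes = rng.binomial(2, maf, size=(n, n_markers))
    lo = max(g_start - flank_bp, 1)
    hi = g_end + flank_bp
    positions = np.unique(np.linspace(lo, hi, n_markers).round().astype(int))
    while positions.size < n_markers:  # collisions only in pathological spans
        positions = np.append(positions, positions[-1] + 1)
    sex = rng.integers(0, 2, n)
    nuisance = rng.integers(0, n_nuisance_levels, n)
    nuisance_effects = rng.normal(0.0, nuisance_sd_log, n_nuisance_levels)
    covariates = pd.DataFrame({"sex": sex, "nuisance": nuisance})
    traits = {}
    for name in trait_names:
        log_y = (
            intercept_log
            + sex_effect_log * sex
            + nuisance_effects[nuisance]
            + rng.normal(0.0, noise_sd_log, n)
        )
        if name == causal_trait and beta_per_allele != 0.0:
            log_y = log_y + beta_per_allele * genotypes[:, causal_index]
        traits[name] = np.exp(log_y)
    return AssocCohort(
        genotypes=genotypes,
        positions_bp=positions,
        marker_ids=[f"m{i + 1:04d}" for i in range(n_markers)],
        trait_raw=traits,
        covariates=covariates,
        true_beta={causal_index: beta_per_allele} if beta_per_allele else {},
        maf=maf,
    )
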