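"""Reference ranges, calling rules and screen-level arithmetic.

A mutant line is called hearing-impaired when either

* rule 60: for some stimulus, >= 60% of its mice have thresholds strictly
  outside the control 95% reference range (2.5th-97.5th percentile), or
* rule 20: for some stimulus, the line mean threshold deviates from the
  control median by >= 20 dB.

A two-sided Fisher exact test on the pooled inside/outside counts provides
an accompanying significance annotation, Bonferroni-corrected for the
number of lines screened.  Called lines are classified into audiogram
categories and reviewed for false-positive signatures (excess within-line
variability, single outliers).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .metrics import IOFCurve
from .stimuli import BATTERY_LABELS, TONE_LABELS
from .types import ThresholdProfile

__all__ = [
    "ReferenceRange",
    "build_reference_range",
    "is_outside",
    "rule_outside_fraction",
    "rule_mean_deviation",
    "ContingencyTable",
    "fisher_two_sided",
    "fisher_exact_line",
    "bonferroni",
    "IOFFlag",
    "min_sls_to_flag",
    "iof_flag",
    "waveform_triage",
    "classify_audiogram",
    "AUDIOGRAM_CLASSES",
    "review_false_positive",
    "fraction_pct",
    "screen_fdr",
    "hit_rate_and_extrapolate",
    "LineCall",
    "call_line",
]

MIN_REFERENCE_N = 20

_QUANTILE_METHODS = {"linear": "linear", "hazen": "hazen"}


@dataclass(frozen=True)
class ReferenceRange:
    """95% control range (2.5th / 97.5th percentile) plus the median."""

    p2_5: float
    median: float
    p97_5: float
    n: int

    def __post_init__(self) -> None:
        if not (self.p2_5 <= self.median <= self.p97_5):
            raise ValueError("percentiles out of order")


def build_reference_range(
    values: Iterable[float], convention: str = "linear", min_n: int = MIN_REFERENCE_N
) -> ReferenceRange:
    """Percentile reference range from control values.

    ``convention`` selects the order-statistic interpolation ("linear" is
    Hyndman-Fan type 7, the numpy default; "hazen" is type 5).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < min_n:
        raise ValueError(f"reference range underpowered: n={arr.size} < {min_n}")
    method = _QUANTILE_METHODS[convention]
    p2_5, med, p97_5 = np.quantile(arr, [0.025, 0.5, 0.975], method=method)
    return ReferenceRange(float(p2_5), float(med), float(p97_5), int(arr.size))


def is_outside(value: float, ref: ReferenceRange) -> int:
    """-1 below, +1 above, 0 inside.  Values exactly at a bound count inside
    (strict inequalities keep control self-coverage at >= 95%)."""
    if value > ref.p97_5:
        return 1
    if value < ref.p2_5:
        return -1
    return 0


def _direction(n_above: int, n_below: int) -> str:
    if n_above and n_below:
        return "mixed"
    if n_above:
        return "elevated"
    if n_below:
        return "reduced"
    return "none"


def rule_outside_fraction(
    line_thresholds: Sequence[ThresholdProfile],
    ref: Mapping[str, ReferenceRange],
    frac_threshold: float = 0.6,
    denominator: str = "per_stimulus",
) -> tuple[dict[str, float], bool, str]:
    """Fraction of mice outside the reference range and the 60% rule.

    Default reading: the fraction is computed stimulus by stimulus and the
    rule fires when any single stimulus reaches ``frac_threshold``.  The
    alternative ``denominator="any_stimulus"`` counts mice with at least one
    outside stimulus.
    """
    if not line_thresholds:
        raise ValueError("empty line")
    stimuli = line_thresholds[0].stimuli
    for s in stimuli:
        if s not in ref:
            raise ValueError(f"reference range missing for stimulus {s!r}")
    fractions: dict[str, float] = {}
    n_above = n_below = 0
    for s in stimuli:
        sides = [is_outside(tp.level(s), ref[s]) for tp in line_thresholds]
        n_above += sum(x == 1 for x in sides)
        n_below += sum(x == -1 for x in sides)
        fractions[s] = sum(x != 0 for x in sides) / len(sides)
    if denominator == "per_stimulus":
        fired = any(f >= frac_threshold for f in fractions.values())
    elif denominator == "any_stimulus":
        per_mouse = [
            any(is_outside(tp.level(s), ref[s]) for s in stimuli) for tp in line_thresholds
        ]
        fired = sum(per_mouse) / len(per_mouse) >= frac_threshold
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    return fractions, fired, _direction(n_above, n_below)


def _line_mean(
    values: Sequence[float], ceilings: Sequence[bool], ceiling_mode: str
) -> float:
    """Ceiling thresholds enter at face value by default; the "censored"
    sensitivity mode drops them unless every mouse is at ceiling."""
    if ceiling_mode == "face_value":
        return float(np.mean(values))
    if ceiling_mode == "censored":
        kept = [v for v, c in zip(values, ceilings) if not c]
        return float(np.mean(kept)) if kept else float(np.mean(values))
    raise ValueError(f"unknown ceiling mode {ceiling_mode!r}")


def rule_mean_deviation(
    line_thresholds: Sequence[ThresholdProfile],
    ref: Mapping[str, ReferenceRange],
    deviation_db: float = 20.0,
    ceiling_mode: str = "face_value",
) -> tuple[dict[str, float], bool]:
    """|line mean - control median| per stimulus; the 20-dB rule is
    inclusive ("at least 20 dB different")."""
    if not line_thresholds:
        raise ValueError("empty line")
    deviations: dict[str, float] = {}
    for s in line_thresholds[0].stimuli:
        if s not in ref:
            raise ValueError(f"reference range missing for stimulus {s!r}")
        mean = _line_mean(
            [tp.level(s) for tp in line_thresholds],
            [tp.is_ceiling(s) for tp in line_thresholds],
            ceiling_mode,
        )
        deviations[s] = abs(mean - ref[s].median)
    return deviations, any(d >= deviation_db for d in deviations.values())


@dataclass(frozen=True)
class ContingencyTable:
    mutant_outside: int
    mutant_inside: int
    control_outside: int
    control_inside: int

    def __post_init__(self) -> None:
        cells = (self.mutant_outside, self.mutant_inside, self.control_outside, self.control_inside)
        if any(c < 0 for c in cells):
            raise ValueError("negative cell count")
        if self.mutant_outside + self.mutant_inside == 0:
            raise ValueError("empty mutant row")
        if self.control_outside + self.control_inside == 0:
            raise ValueError("empty control row")


def fisher_two_sided_by_margin(n: int, r1: int, c1: int) -> dict[int, float]:
    """Two-sided Fisher exact p for every admissible first cell given fixed
    margins (total ``n``, first row sum ``r1``, first column sum ``c1``).

    The two-sided p of an observed table is the sum of probabilities of all
    tables with the same margins whose hypergeometric probability does not
    exceed the observed table's (standard 1e-7 relative tie tolerance).
    """
    support = np.arange(max(0, c1 - (n - r1)), min(r1, c1) + 1)
    if c1 == 0 or c1 == n:
        # degenerate margins: all observations in one column
        return {int(x): 1.0 for x in support}
    pmf = stats.hypergeom(n, c1, r1).pmf(support)
    ps = {}
    for x, p_obs in zip(support, pmf):
        ps[int(x)] = float(min(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum(), 1.0))
    return ps


def fisher_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p of one contingency table."""
    r1 = table.mutant_outside + table.mutant_inside
    n = r1 + table.control_outside + table.control_inside
    c1 = table.mutant_outside + table.control_outside
    return fisher_two_sided_by_margin(n, r1, c1)[table.mutant_outside]


def _count_outside(
    profiles: Sequence[ThresholdProfile], ref: Mapping[str, ReferenceRange], stimuli: Sequence[str]
) -> tuple[int, int]:
    outside = inside = 0
    for tp in profiles:
        for s in stimuli:
            if is_outside(tp.level(s), ref[s]):
                outside += 1
            else:
                inside += 1
    return outside, inside


def fisher_exact_line(
    line_thresholds: Sequence[ThresholdProfile],
    control_thresholds: Sequence[ThresholdProfile],
    ref: Mapping[str, ReferenceRange],
    alpha_corrected: float,
    pooling: str = "pooled",
) -> tuple[ContingencyTable, float, bool]:
    """Fisher exact comparison of inside/outside threshold counts.

    Observations are one per mouse per stimulus, pooled across the battery
    by default; ``pooling="per_stimulus"`` runs the test per stimulus and
    returns the smallest p with its table.
    """
    if not line_thresholds or not control_thresholds:
        raise ValueError("both cohorts must be non-empty")
    stimuli = line_thresholds[0].stimuli
    if pooling == "pooled":
        groups = [tuple(stimuli)]
    elif pooling == "per_stimulus":
        groups = [(s,) for s in stimuli]
    else:
        raise ValueError(f"unknown pooling mode {pooling!r}")
    best: tuple[ContingencyTable, float] | None = None
    for grp in groups:
        mo, mi = _count_outside(line_thresholds, ref, grp)
        co, ci = _count_outside(control_thresholds, ref, grp)
        tab = ContingencyTable(mo, mi, co, ci)
        p = fisher_two_sided(tab)
        if best is None or p < best[1]:
            best = (tab, p)
    assert best is not None
    return best[0], best[1], best[1] <= alpha_corrected


def bonferroni(alpha: float, m: int) -> float:
    """Family-wise corrected per-test threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def min_sls_to_flag(n_sls: int, fraction: float = 0.4) -> int:
    """Minimum number of abnormal SLs required to flag an IOF parameter
    (>= 40% of available SLs; 5 when the full 12-SL grid was recorded)."""
    if n_sls < 1:
        raise ValueError("need at least one SL")
    return math.ceil(fraction * n_sls)


@dataclass(frozen=True)
class IOFFlag:
    flag: bool
    direction: str  # "up" | "down" | "none"
    fraction_of_sls: float
    n_outside: int
    n_sls: int


def iof_flag(
    line_mean_iof: IOFCurve,
    ref: Mapping[tuple[str, float], ReferenceRange],
    fraction: float = 0.4,
) -> IOFFlag:
    """Flag an IOF parameter abnormal when the line mean is outside the
    per-SL reference range at >= 40% of the SLs available in both."""
    sides = []
    for sl, val in zip(line_mean_iof.sl_db, line_mean_iof.values):
        key = (line_mean_iof.parameter, float(sl))
        if key in ref:
            sides.append(is_outside(val, ref[key]))
    if not sides:
        raise ValueError("no overlapping SLs between line and reference")
    n_out = sum(s != 0 for s in sides)
    n_up = sum(s == 1 for s in sides)
    n_down = sum(s == -1 for s in sides)
    flag = n_out >= min_sls_to_flag(len(sides), fraction)
    direction = "none"
    if n_out:
        direction = "up" if n_up >= n_down else "down"
    return IOFFlag(flag, direction, n_out / len(sides), n_out, len(sides))


def waveform_triage(
    line_mean_waveform: np.ndarray,
    envelope_low: np.ndarray,
    envelope_high: np.ndarray,
    times_ms: np.ndarray,
    window_ms: tuple[float, float],
    min_fraction: float = 0.10,
) -> bool:
    """Quantitative stand-in for the two-observer waveform triage: positive
    when the line mean leaves the control 95% envelope for >= 10% of the
    timepoints within the P1-N4 window."""
    arrs = (line_mean_waveform, envelope_low, envelope_high)
    if not all(a.shape == times_ms.shape for a in arrs):
        raise ValueError("time-base mismatch between waveform and envelope")
    mask = (times_ms >= window_ms[0]) & (times_ms <= window_ms[1])
    if not mask.any():
        raise ValueError("triage window outside the recorded epoch")
    out = (line_mean_waveform[mask] > envelope_high[mask]) | (
        line_mean_waveform[mask] < envelope_low[mask]
    )
    return float(out.mean()) >= min_fraction


AUDIOGRAM_CLASSES = (
    "SevereProfound",
    "HighFrequency",
    "LowFrequency",
    "Moderate",
    "Mild",
    "Normal",
)


def classify_audiogram(
    line_thresholds: Sequence[ThresholdProfile],
    ref: Mapping[str, ReferenceRange],
    low_frequency_as_printed: bool = False,
    ceiling_mode: str = "face_value",
) -> str:
    """Rule-based audiogram classification of a mutant line.

    Rules are evaluated in severity order; "elevated" means the line mean
    lies strictly above the stimulus's 97.5th control percentile, and
    "elevation" is the line mean minus the control median (dB).

    * SevereProfound — every mouse at ceiling (no response at the maximum
      level) for at least two adjacent tone frequencies.
    * HighFrequency — elevation at 30 kHz > 30 dB and at least one
      lower-frequency tone not elevated.
    * LowFrequency — 6 and 12 kHz elevated while at least one
      higher-frequency tone stays normal.  By default "normal" is an
      elevation below 15 dB; ``low_frequency_as_printed=True`` instead
      requires the smallest elevation among elevated stimuli to be < 15 dB.
    * Moderate — at least 4 of the 6 stimuli elevated, each elevated
      stimulus by more than 15 dB.
    * Mild — at most 3 stimuli elevated, none by more than 30 dB.
    * Normal — no stimulus altered.

    Patterns matching no rule fall back to Mild (<= 3 elevated stimuli) or
    Moderate (otherwise).
    """
    if not line_thresholds:
        raise ValueError("empty line")
    for s in BATTERY_LABELS:
        if s not in line_thresholds[0]:
            raise ValueError(f"missing stimulus {s!r}: full battery required")
        if s not in ref:
            raise ValueError(f"reference range missing for stimulus {s!r}")

    elev: dict[str, float] = {}
    elevated: dict[str, bool] = {}
    for s in BATTERY_LABELS:
        mean = _line_mean(
            [tp.level(s) for tp in line_thresholds],
            [tp.is_ceiling(s) for tp in line_thresholds],
            ceiling_mode,
        )
        elev[s] = mean - ref[s].median
        elevated[s] = mean > ref[s].p97_5

    # SevereProfound: all mice ceiling-flagged at >= 2 adjacent tones
    all_ceiling = [all(tp.is_ceiling(s) for tp in line_thresholds) for s in TONE_LABELS]
    if any(a and b for a, b in zip(all_ceiling, all_ceiling[1:])):
        return "SevereProfound"

    lower_tones = list(TONE_LABELS[:-1])
    high_tone = TONE_LABELS[-1]  # 30 kHz
    if elev[high_tone] > 30.0 and any(not elevated[s] for s in lower_tones):
        return "HighFrequency"

    higher_tones = list(TONE_LABELS[2:])  # 18, 24, 30 kHz
    if elevated["tone:6"] and elevated["tone:12"]:
        if low_frequency_as_printed:
            mins = min(e for s, e in elev.items() if elevated[s])
            if any(not elevated[s] for s in higher_tones) and mins < 15.0:
                return "LowFrequency"
        elif any(elev[s] < 15.0 for s in higher_tones):
            return "LowFrequency"

    n_elev = sum(elevated.values())
    elevations = [elev[s] for s in BATTERY_LABELS if elevated[s]]
    if n_elev >= 4 and elevations and min(elevations) > 15.0:
        return "Moderate"
    if 1 <= n_elev <= 3 and max(elevations) <= 30.0:
        return "Mild"
    if n_elev == 0:
        return "Normal"
    return "Mild" if n_elev <= 3 else "Moderate"


def review_false_positive(
    line_thresholds: Sequence[ThresholdProfile],
    calling_stimulus: str,
    ref: Mapping[str, ReferenceRange],
    variability_sd_db: float = 20.0,
    outlier_gap_db: float = 30.0,
    frac_threshold: float = 0.6,
    deviation_db: float = 20.0,
) -> set[str]:
    """Advisory review flags for a called line (never auto-rejecting).

    ``excess_variability``: within-line SD at the calling stimulus exceeds
    ``variability_sd_db``.  ``single_outlier``: the most extreme mouse sits
    >= ``outlier_gap_db`` from the nearest other mouse and removing it
    cancels both calling rules.
    """
    if len(line_thresholds) < 2:
        raise ValueError("review undefined for a line of one mouse")
    flags: set[str] = set()
    vals = np.asarray([tp.level(calling_stimulus) for tp in line_thresholds])
    if float(np.std(vals, ddof=1)) > variability_sd_db:
        flags.add("excess_variability")
    med = float(np.median(vals))
    idx = int(np.argmax(np.abs(vals - med)))
    rest = np.delete(vals, idx)
    gap = float(np.min(np.abs(rest - vals[idx])))
    if gap >= outlier_gap_db:
        remaining = [tp for i, tp in enumerate(line_thresholds) if i != idx]
        _, r60, _ = rule_outside_fraction(remaining, ref, frac_threshold)
        _, r20 = rule_mean_deviation(remaining, ref, deviation_db)
        if not r60 and not r20:
            flags.add("single_outlier")
    return flags


def fraction_pct(numerator: int, denominator: int, decimals: int = 2) -> float:
    """Percentage numerator/denominator, reported to ``decimals`` places."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, decimals)


def screen_fdr(n_false_calls: int, n_genes: int) -> float:
    """Screen-level false discovery rate (%) from reviewed false calls."""
    if not (0 <= n_false_calls <= n_genes):
        raise ValueError("n_false_calls must be in [0, n_genes]")
    return fraction_pct(n_false_calls, n_genes)


def hit_rate_and_extrapolate(
    n_hits: int, n_screened: int, genome_size: int
) -> tuple[float, int]:
    """Hit rate (%) and the extrapolated count of further genes expected in
    the unscreened remainder of the genome."""
    if n_screened < 1:
        raise ValueError("n_screened must be >= 1")
    if genome_size < n_screened:
        raise ValueError("genome_size must be >= n_screened")
    rate = n_hits / n_screened
    remaining = round(rate * (genome_size - n_screened))
    return fraction_pct(n_hits, n_screened), int(remaining)


@dataclass
class LineCall:
    """Full calling record for one mutant line."""

    line_id: str
    outside_fraction: dict[str, float]
    mean_deviation_db: dict[str, float]
    rule60: bool
    rule20: bool
    fisher_p: float
    fisher_significant: bool
    direction: str
    category: str
    review_flags: set[str] = field(default_factory=set)
    iof_flags: dict[str, IOFFlag] = field(default_factory=dict)
    waveform_triage: bool = False

    @property
    def called(self) -> bool:
        return self.rule60 or self.rule20


def call_line(
    line_id: str,
    line_thresholds: Sequence[ThresholdProfile],
    control_thresholds: Sequence[ThresholdProfile],
    ref: Mapping[str, ReferenceRange],
    alpha_corrected: float,
    frac_threshold: float = 0.6,
    deviation_db: float = 20.0,
    denominator: str = "per_stimulus",
    pooling: str = "pooled",
    ceiling_mode: str = "face_value",
    low_frequency_as_printed: bool = False,
    variability_sd_db: float = 20.0,
    outlier_gap_db: float = 30.0,
) -> LineCall:
    """Run the full calling cascade for one line."""
    fractions, rule60, direction = rule_outside_fraction(
        line_thresholds, ref, frac_threshold, denominator
    )
    deviations, rule20 = rule_mean_deviation(line_thresholds, ref, deviation_db, ceiling_mode)
    _, fisher_p, significant = fisher_exact_line(
        line_thresholds, control_thresholds, ref, alpha_corrected, pooling
    )
    if rule60 or rule20:
        category = classify_audiogram(
            line_thresholds, ref, low_frequency_as_printed, ceiling_mode
        )
        if category == "Normal":
            # keep the invariant category == Normal <=> no rule fired
            category = "Mild"
        if rule60:
            calling = max(fractions, key=lambda s: fractions[s])
        else:
            calling = max(deviations, key=lambda s: deviations[s])
        review = (
            review_false_positive(
                line_thresholds,
                calling,
                ref,
                variability_sd_db,
                outlier_gap_db,
                frac_threshold,
                deviation_db,
            )
            if len(line_thresholds) >= 2
            else set()
        )
    else:
        category = "Normal"
        review = set()
    return LineCall(
        line_id=line_id,
        outside_fraction=fractions,
        mean_deviation_db=deviations,
        rule60=rule60,
        rule20=rule20,
        fisher_p=fisher_p,
        fisher_significant=significant,
        direction=direction,
        category=category,
        review_flags=review,
    )
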