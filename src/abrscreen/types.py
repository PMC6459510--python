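"""Shared record types for the screen pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

from .stimuli import MAX_LEVEL_DB, on_grid
from .waveform import LevelSeries


@dataclass(frozen=True)
class Threshold:
    """One stimulus threshold (dB SPL, on the 5-dB grid).

    ``ceiling`` marks the no-response convention: no detectable response up
    to the maximum level presented, which is then recorded as the threshold.
    """

    level_db: float
    ceiling: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.level_db <= MAX_LEVEL_DB):
            raise ValueError(f"threshold {self.level_db} outside [0, {MAX_LEVEL_DB}]")
        if not on_grid(self.level_db):
            raise ValueError(f"threshold {self.level_db} off the 5-dB grid")


class ThresholdProfile:
    """Per-mouse mapping stimulus label -> :class:`Threshold`."""

    def __init__(self, entries: Mapping[str, Threshold]):
        self._entries = dict(entries)

    @classmethod
    def from_values(
        cls,
        levels: Mapping[str, float],
        ceiling: Mapping[str, bool] | None = None,
    ) -> "ThresholdProfile":
        ceiling = ceiling or {}
        return cls({s: Threshold(float(v), bool(ceiling.get(s, False))) for s, v in levels.items()})

    def __getitem__(self, stimulus: str) -> Threshold:
        return self._entries[stimulus]

    def __contains__(self, stimulus: str) -> bool:
        return stimulus in self._entries

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ThresholdProfile) and self._entries == other._entries

    def __repr__(self) -> str:
        vals = ", ".join(f"{s}={t.level_db:g}{'^' if t.ceiling else ''}" for s, t in self._entries.items())
        return f"ThresholdProfile({vals})"

    @property
    def stimuli(self) -> tuple[str, ...]:
        return tuple(self._entries)

    def level(self, stimulus: str) -> float:
        return self._entries[stimulus].level_db

    def is_ceiling(self, stimulus: str) -> bool:
        return self._entries[stimulus].ceiling

    def items(self):
        return self._entries.items()


@dataclass
class MouseRecord:
    """One mouse in the screen: identity, genotype and its ABR results.

    ``true_threshold`` carries the simulation ground truth and is absent for
    real data.  ``series`` (raw waveform ladders) is optional; ``thresholds``
    is always present once the mouse has been analysed.
    """

    mouse_id: str
    genotype: str  # "wt" | "het" | "hom"
    sex: str  # "M" | "F"
    line_id: str  # mutant line or "control"
    thresholds: ThresholdProfile
    true_threshold: ThresholdProfile | None = None
    series: dict[str, LevelSeries] | None = None

    def __post_init__(self) -> None:
        if self.genotype not in ("wt", "het", "hom"):
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"unknown sex {self.sex!r}")


@dataclass(frozen=True)
class SyntheticLineSpec:
    """Ground-truth description of one simulated mutant line."""

    class_label: str  # audiogram class the shifts encode
    shift_db: Mapping[str, float]  # stimulus -> threshold elevation
    inter_mouse_sd_db: float = 5.0
    outlier_prob: float = 0.0
    n_mutants: int = 4

    def __post_init__(self) -> None:
        if self.n_mutants < 1:
            raise ValueError("n_mutants must be >= 1")
        if self.inter_mouse_sd_db < 0:
            raise ValueError("inter_mouse_sd_db must be non-negative")
        if not (0.0 <= self.outlier_prob <= 1.0):
            raise ValueError("outlier_prob must be in [0, 1]")
        if any(v < 0 for v in self.shift_db.values()):
            raise ValueError("threshold shifts must be non-negative")


@dataclass
class ScreenLine:
    line_id: str
    spec: SyntheticLineSpec
    mice: list[MouseRecord]


@dataclass
class ScreenDataset:
    """A full simulated screen: shared controls plus per-line cohorts."""

    controls: list[MouseRecord]
    lines: list[ScreenLine]
    seed: int

    def __post_init__(self) -> None:
        ids = [m.mouse_id for m in self.controls] + [
            m.mouse_id for line in self.lines for m in line.mice
        ]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate mouse_id across cohorts")

    def all_mice(self) -> list[MouseRecord]:
        return list(self.controls) + [m for line in self.lines for m in line.mice]


@dataclass
class AssocCohort:
    """Simulated candidate-gene association cohort.

    ``genotypes`` holds minor-allele counts (0/1/2) per individual x marker;
    traits are raw (dB-scale, positive) hearing thresholds whose log is
    exactly linear in the causal allele count and covariates.
    """

    genotypes: np.ndarray  # (n, m) int
    positions_bp: np.ndarray  # (m,), strictly increasing
    marker_ids: list[str]
    trait_raw: dict[str, np.ndarray]  # trait name -> (n,)
    covariates: "object"  # pandas.DataFrame: sex + nuisance codes
    true_beta: dict[int, float]  # causal marker index -> per-allele log effect
    maf: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.positions_bp) <= 0):
            raise ValueError("marker positions must be strictly increasing")
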