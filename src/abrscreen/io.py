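"""Frozen file formats: UTF-8, tab-delimited, mandatory header, '.' missing.

Tables:
  mouse table      mouse_id line_id genotype sex
  threshold table  mouse_id stimulus threshold_db ceiling   (long format)
  waveform store   mouse_id stimulus level_db time_ms voltage_uv
  ground truth     line_id class <one column per stimulus shift>
  reference ranges key p2_5 median p97_5 n
  calls report     one row per line with all call fields
  summary          key value pairs
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import LineCall, ReferenceRange
from .stimuli import on_grid
from .types import MouseRecord, ScreenDataset, ThresholdProfile

_TSV = dict(sep="\t", na_rep=".", index=False)
_READ = dict(sep="\t", na_values=["."], keep_default_na=False)


def _write(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, **_TSV)


def mouse_table(mice: Sequence[MouseRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"mouse_id": m.mouse_id, "line_id": m.line_id, "genotype": m.genotype, "sex": m.sex}
            for m in mice
        ]
    )


def threshold_table(mice: Sequence[MouseRecord]) -> pd.DataFrame:
    rows = []
    for m in mice:
        for s, t in m.thresholds.items():
            rows.append(
                {
                    "mouse_id": m.mouse_id,
                    "stimulus": s,
                    "threshold_db": t.level_db,
                    "ceiling": int(t.ceiling),
                }
            )
    return pd.DataFrame(rows)


def ground_truth_table(dataset: ScreenDataset) -> pd.DataFrame:
    stimuli = dataset.controls[0].thresholds.stimuli if dataset.controls else ()
    rows = []
    for line in dataset.lines:
        row: dict = {"line_id": line.line_id, "class": line.spec.class_label}
        for s in stimuli:
            row[f"shift:{s}"] = line.spec.shift_db.get(s, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def waveform_table(mice: Sequence[MouseRecord]) -> pd.DataFrame:
    rows = []
    for m in mice:
        if not m.series:
            continue
        for s, series in m.series.items():
            t = series.times_ms()
            for lvl, trace in zip(series.levels_db, series.traces_uv):
                rows.append(
                    pd.DataFrame(
                        {
                            "mouse_id": m.mouse_id,
                            "stimulus": s,
                            "level_db": lvl,
                            "time_ms": t,
                            "voltage_uv": trace,
                        }
                    )
                )
    if not rows:
        return pd.DataFrame(
            columns=["mouse_id", "stimulus", "level_db", "time_ms", "voltage_uv"]
        )
    return pd.concat(rows, ignore_index=True)


def write_screen_dataset(dataset: ScreenDataset, outdir: str | Path) -> dict[str, Path]:
    """Write mouse, threshold and ground-truth tables; returns the paths."""
    outdir = Path(outdir)
    paths = {
        "mice": outdir / "mice.tsv",
        "thresholds": outdir / "thresholds.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
    }
    _write(mouse_table(dataset.all_mice()), paths["mice"])
    _write(threshold_table(dataset.all_mice()), paths["thresholds"])
    _write(ground_truth_table(dataset), paths["ground_truth"])
    return paths


def read_threshold_profiles(
    mouse_path: str | Path, threshold_path: str | Path
) -> dict[str, tuple[str, ThresholdProfile]]:
    """Read mouse + threshold tables -> {mouse_id: (line_id, profile)}."""
    mice = pd.read_csv(mouse_path, **_READ)
    thr = pd.read_csv(threshold_path, **_READ)
    lines = dict(zip(mice["mouse_id"], mice["line_id"]))
    out: dict[str, tuple[str, ThresholdProfile]] = {}
    for mouse_id, grp in thr.groupby("mouse_id", sort=False):
        profile = ThresholdProfile.from_values(
            dict(zip(grp["stimulus"], grp["threshold_db"])),
            dict(zip(grp["stimulus"], grp["ceiling"].astype(bool))),
        )
        out[str(mouse_id)] = (str(lines.get(mouse_id, "?")), profile)
    return out


def reference_table(ref: Mapping[str, ReferenceRange]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"key": k, "p2_5": r.p2_5, "median": r.median, "p97_5": r.p97_5, "n": r.n}
            for k, r in ref.items()
        ]
    )


def read_reference_table(path: str | Path) -> dict[str, ReferenceRange]:
    df = pd.read_csv(path, **_READ)
    return {
        str(row.key): ReferenceRange(row.p2_5, row.median, row.p97_5, int(row.n))
        for row in df.itertuples()
    }


def calls_table(calls: Sequence[LineCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row: dict = {
            "line_id": c.line_id,
            "called": int(c.called),
            "rule60": int(c.rule60),
            "rule20": int(c.rule20),
            "fisher_p": c.fisher_p,
            "fisher_significant": int(c.fisher_significant),
            "direction": c.direction,
            "category": c.category,
            "review_flags": ",".join(sorted(c.review_flags)) or None,
        }
        for s, f in c.outside_fraction.items():
            row[f"outside_frac:{s}"] = f
        for s, d in c.mean_deviation_db.items():
            row[f"mean_dev:{s}"] = d
        rows.append(row)
    return pd.DataFrame(rows)


def heatmap_table(calls: Sequence[LineCall]) -> pd.DataFrame:
    """Categorical in/out-of-range summary per line x stimulus, mirroring a
    blue/red heat-map: 'out' when either threshold rule fires there."""
    rows = []
    for c in calls:
        row: dict = {"line_id": c.line_id}
        for s, f in c.outside_fraction.items():
            out = f >= 0.6 or c.mean_deviation_db.get(s, 0.0) >= 20.0
            row[s] = "out" if out else "in"
        rows.append(row)
    return pd.DataFrame(rows)


def summary_table(summary: Mapping[str, object]) -> pd.DataFrame:
    return pd.DataFrame({"key": list(summary), "value": [summary[k] for k in summary]})


@dataclass
class ValidationReport:
    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_tables(mouse_path: str | Path, threshold_path: str | Path) -> ValidationReport:
    """Structural double-entry checks between mouse and threshold tables."""
    violations: list[str] = []
    try:
        mice = pd.read_csv(mouse_path, **_READ)
        thr = pd.read_csv(threshold_path, **_READ)
    except Exception as exc:  # unreadable file is itself the finding
        return ValidationReport([f"unreadable input: {exc}"])

    for col in ("mouse_id", "line_id", "genotype", "sex"):
        if col not in mice.columns:
            violations.append(f"{mouse_path}: missing column {col!r}")
    for col in ("mouse_id", "stimulus", "threshold_db", "ceiling"):
        if col not in thr.columns:
            violations.append(f"{threshold_path}: missing column {col!r}")
    if violations:
        return ValidationReport(violations)

    dup = mice[mice.duplicated("mouse_id", keep=False)]["mouse_id"].unique()
    for d in dup:
        violations.append(f"duplicate mouse_id {d!r} in mouse table")
    known = set(mice["mouse_id"])
    for i, row in enumerate(thr.itertuples(), start=2):
        if row.mouse_id not in known:
            violations.append(
                f"{threshold_path}:{i}: mouse {row.mouse_id!r} absent from mouse table"
            )
        lvl = float(row.threshold_db)
        if not on_grid(lvl) or not (0.0 <= lvl <= 95.0):
            violations.append(
                f"{threshold_path}:{i}: threshold {lvl} off the 5-dB grid in [0, 95]"
            )
        if int(row.ceiling) == 1 and lvl != 95.0:
            violations.append(
                f"{threshold_path}:{i}: ceiling flag with threshold {lvl} != 95"
            )
    return ValidationReport(violations)
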