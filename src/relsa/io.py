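"""Tabular readers/writers and the study configuration.

Input tables are delimited text (comma or tab, auto-detected), either
long — columns ``animal_id, group, time, variable, value`` — or wide —
``animal_id, group, time`` plus one column per variable.  Empty cells or
``NA`` mean missing; times are plain numerics with the intervention at 0
by convention, so negative times are baseline candidates.  Outputs are
tidy CSVs with a JSON metadata sidecar so every table is machine-
re-readable with full provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import AnimalSeries, ReferenceSet, RelsaResult, VariableSpec

__all__ = [
    "StudyConfig",
    "read_table",
    "write_scores",
    "write_weights",
    "write_summary",
    "read_reference",
    "write_reference",
]

_LONG_COLS = ["animal_id", "group", "time", "variable", "value"]
_NA_VALUES = ["", "NA", "NaN", "nan"]


@dataclass
class StudyConfig:
    """Everything a full pipeline run needs, serializable to YAML/JSON.

    ``variables`` maps each name to its severity direction and (optionally)
    an already-normalized flag; ``baseline`` is either the string
    ``"negative-times"`` or an explicit list of baseline times;
    ``reference_group`` selects the reference cohort by its group label.
    """

    variables: list[dict] = field(default_factory=list)
    layout: str = "long"
    baseline: object = "negative-times"
    reference_group: str = "reference"
    time_unit: str = "day"
    severity_context_label: str = "moderate"
    k: object = "auto"
    level_mode: str = "lloyd"
    threshold_mode: str = "max"
    restarts: int = 25
    bootstrap_B: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layout not in ("long", "wide"):
            raise ValueError("layout must be 'long' or 'wide'")
        if not isinstance(self.baseline, str):
            self.baseline = [float(t) for t in self.baseline]
        elif self.baseline != "negative-times":
            raise ValueError("baseline must be 'negative-times' or a list of times")
        for v in self.variables:
            if "name" not in v or "direction" not in v:
                raise ValueError("each variable needs 'name' and 'direction'")

    def variable_specs(self) -> list[VariableSpec]:
        return [
            VariableSpec(
                v["name"], v["direction"], bool(v.get("already_normalized", False))
            )
            for v in self.variables
        ]

    def baseline_window_for(self, times: np.ndarray) -> tuple[float, ...] | None:
        if self.baseline == "negative-times":
            return None  # AnimalSeries defaults to negative times
        return tuple(t for t in self.baseline if t in set(times))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} is not a mapping")
        return cls(**raw)


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    first = path.open().readline()
    sep = "\t" if "\t" in first else ","
    return pd.read_csv(
        path, sep=sep, na_values=_NA_VALUES, keep_default_na=False, skipinitialspace=True
    )


def read_table(
    path: str | Path,
    layout: str = "long",
    config: StudyConfig | None = None,
) -> list[AnimalSeries]:
    """Read a long- or wide-format study table into per-animal series.

    Duplicate (animal, time, variable) records and unparseable numerics are
    hard errors with row-level diagnostics; missing values ("NA" or empty)
    are preserved as NaN.
    """
    df = _read_delimited(path)
    if layout == "long":
        missing = [c for c in _LONG_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        df = df[_LONG_COLS].copy()
    elif layout == "wide":
        required = ["animal_id", "group", "time"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        value_cols = [c for c in df.columns if c not in required]
        if not value_cols:
            raise ValueError(f"{path}: wide table has no variable columns")
        df = df.melt(
            id_vars=required, value_vars=value_cols,
            var_name="variable", value_name="value",
        )
    else:
        raise ValueError("layout must be 'long' or 'wide'")

    for col in ("time", "value"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: column {col!r} is not numeric: {exc}") from None

    dup = df.duplicated(subset=["animal_id", "time", "variable"], keep=False)
    if dup.any():
        rows = df.index[dup].tolist()[:10]
        keys = df.loc[rows[:3], ["animal_id", "time", "variable"]].to_dict("records")
        raise ValueError(
            f"{path}: duplicate (animal, time, variable) records at rows {rows} "
            f"(e.g. {keys})"
        )

    known = None
    if config is not None and config.variables:
        known = {v["name"] for v in config.variables}
        unknown = sorted(set(df["variable"]) - known)
        if unknown:
            raise ValueError(f"{path}: variables {unknown} not declared in the config")

    out: list[AnimalSeries] = []
    for (animal, group), sub in df.groupby(["animal_id", "group"], sort=True):
        wide = sub.pivot(index="time", columns="variable", values="value").sort_index()
        wide.columns.name = None
        if known is not None:
            ordered = [v["name"] for v in config.variables if v["name"] in wide.columns]
            wide = wide[ordered]
        times = np.asarray(wide.index, dtype=float)
        bl = config.baseline_window_for(times) if config is not None else None
        out.append(
            AnimalSeries(
                animal_id=str(animal), group=str(group), data=wide, baseline_window=bl
            )
        )
    return out


def _write_with_meta(df: pd.DataFrame, path: Path, meta: dict) -> None:
    df.to_csv(path, index=False)
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n"
    )


def write_scores(results: Sequence[RelsaResult], path: str | Path, meta: dict | None = None) -> pd.DataFrame:
    """Tidy per-time scores: (animal_id, group, time, n_contributing, relsa)."""
    rows = []
    for r in results:
        for t in r.times:
            rows.append(
                {
                    "animal_id": r.animal_id,
                    "group": r.group,
                    "time": float(t),
                    "n_contributing": int(r.n_contributing.loc[t]),
                    "relsa": float(r.score.loc[t]),
                }
            )
    df = pd.DataFrame(rows)
    _write_with_meta(df, Path(path), {"table": "scores", **(meta or {})})
    return df


def write_weights(results: Sequence[RelsaResult], path: str | Path, meta: dict | None = None) -> pd.DataFrame:
    """Tidy per-time weights: (animal_id, group, time, variable, RW)."""
    rows = []
    for r in results:
        for v in r.variables:
            for t in r.times:
                rows.append(
                    {
                        "animal_id": r.animal_id,
                        "group": r.group,
                        "time": float(t),
                        "variable": v,
                        "RW": float(r.weights.loc[t, v]),
                    }
                )
    df = pd.DataFrame(rows)
    _write_with_meta(df, Path(path), {"table": "weights", **(meta or {})})
    return df


def write_summary(results: Sequence[RelsaResult], path: str | Path, meta: dict | None = None) -> pd.DataFrame:
    """Per-animal summary with the maximum score."""
    df = pd.DataFrame(
        [
            {"animal_id": r.animal_id, "group": r.group, "relsa_max": r.relsa_max}
            for r in results
        ]
    )
    _write_with_meta(df, Path(path), {"table": "relsa_max", **(meta or {})})
    return df


def write_reference(ref: ReferenceSet, path: str | Path) -> None:
    Path(path).write_text(json.dumps(ref.to_dict(), indent=2, sort_keys=True) + "\n")


def read_reference(path: str | Path) -> ReferenceSet:
    return ReferenceSet.from_dict(json.loads(Path(path).read_text()))
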