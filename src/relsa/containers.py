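"""Domain containers for severity scoring.

The pipeline moves raw per-animal time series through baseline
normalization, reference-anchored weighting and composite scoring.  Each
stage has a small dataclass carrying its result plus enough provenance to
make downstream outputs reproducible.  Measurements live in pandas
DataFrames indexed by numeric time (days or hours — the unit is carried as
a label only), one column per outcome measure, with ``NaN`` marking a
missing observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Direction",
    "VariableSpec",
    "AnimalSeries",
    "NormalizedSeries",
    "ReferenceSet",
    "RelsaResult",
    "SeverityLevels",
    "BootstrapResult",
]


class Direction(str, Enum):
    """Direction in which severity unfolds relative to baseline.

    Impaired welfare lowers body weight, burrowing, activity and heart-rate
    variability (``DECREASE``) but raises heart rate (``INCREASE``).
    """

    DECREASE = "decrease"
    INCREASE = "increase"

    @classmethod
    def coerce(cls, value: "Direction | str") -> "Direction":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValueError(
                f"direction must be 'decrease' or 'increase', got {value!r}"
            ) from None


@dataclass(frozen=True)
class VariableSpec:
    """One outcome measure and how to interpret its deviations.

    Parameters
    ----------
    name
        Column name of the variable in the input tables.
    direction
        Whether severity manifests below (``decrease``) or above
        (``increase``) baseline.
    already_normalized
        True when the input is already a percentage of baseline (e.g.
        overnight burrowing performance recorded as % of baseline nights);
        such variables bypass baseline normalization.
    """

    name: str
    direction: Direction = Direction.DECREASE
    already_normalized: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", Direction.coerce(self.direction))
        if not self.name:
            raise ValueError("variable name must be non-empty")


def _check_specs(specs: Sequence[VariableSpec]) -> dict[str, VariableSpec]:
    by_name = {s.name: s for s in specs}
    if len(by_name) != len(specs):
        raise ValueError("variable names must be unique within a study")
    return by_name


@dataclass
class AnimalSeries:
    """Raw time-indexed measurements for one animal.

    ``data`` is indexed by strictly increasing numeric time with one column
    per declared variable; ``NaN`` means not measured.  ``baseline_window``
    lists the pre-intervention times used to anchor normalization; by the
    package's convention the intervention happens at time 0, so it defaults
    to all negative times.
    """

    animal_id: str
    group: str
    data: pd.DataFrame
    baseline_window: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame indexed by time")
        times = np.asarray(self.data.index, dtype=float)
        if times.size == 0:
            raise ValueError(f"animal {self.animal_id!r}: empty time series")
        if not np.all(np.diff(times) > 0):
            raise ValueError(
                f"animal {self.animal_id!r}: times must be strictly increasing"
            )
        self.data = self.data.copy()
        self.data.index = times
        if self.baseline_window is None:
            self.baseline_window = tuple(times[times < 0])
        else:
            self.baseline_window = tuple(float(t) for t in self.baseline_window)
            missing = set(self.baseline_window) - set(times)
            if missing:
                raise ValueError(
                    f"animal {self.animal_id!r}: baseline times {sorted(missing)} "
                    "not present in the series"
                )

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.data.index, dtype=float)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def post_baseline_times(self) -> np.ndarray:
        bl = set(self.baseline_window)
        return np.array([t for t in self.times if t not in bl], dtype=float)


@dataclass
class NormalizedSeries:
    """Per-variable values on the percent-of-baseline scale (baseline = 100)."""

    animal_id: str
    group: str
    data: pd.DataFrame
    baseline_window: tuple[float, ...] = ()

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.data.index, dtype=float)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def post_baseline_times(self) -> np.ndarray:
        bl = set(self.baseline_window)
        return np.array([t for t in self.times if t not in bl], dtype=float)


@dataclass
class ReferenceSet:
    """Per-variable maximum baseline deviations observed in a reference cohort.

    ``max_delta[v]`` is the largest percent-point deviation from baseline in
    the severity direction seen anywhere (any animal, any post-baseline
    time) in the reference cohort; it is the denominator anchoring every
    weight.  The variable set is fixed at construction: test animals may
    supply any non-empty subset, but never new variables.
    """

    variable_specs: tuple[VariableSpec, ...]
    max_delta: dict[str, float]
    cohort_id: str = "reference"
    n_animals: int = 0
    time_span: tuple[float, float] = (0.0, 0.0)
    severity_context_label: str = ""

    def __post_init__(self) -> None:
        self.variable_specs = tuple(self.variable_specs)
        by_name = _check_specs(self.variable_specs)
        if set(self.max_delta) != set(by_name):
            raise ValueError("max_delta keys must match the variable specs")
        bad = [v for v, d in self.max_delta.items() if not (d > 0)]
        if bad:
            raise ValueError(
                f"reference deviations must be positive; unusable variables: {sorted(bad)}"
            )

    @property
    def variables(self) -> list[str]:
        return [s.name for s in self.variable_specs]

    def spec(self, name: str) -> VariableSpec:
        for s in self.variable_specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "variables": [
                {
                    "name": s.name,
                    "direction": s.direction.value,
                    "already_normalized": s.already_normalized,
                    "max_delta": float(self.max_delta[s.name]),
                }
                for s in self.variable_specs
            ],
            "cohort_id": self.cohort_id,
            "n_animals": int(self.n_animals),
            "time_span": [float(self.time_span[0]), float(self.time_span[1])],
            "severity_context_label": self.severity_context_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceSet":
        specs = tuple(
            VariableSpec(v["name"], v["direction"], v.get("already_normalized", False))
            for v in d["variables"]
        )
        return cls(
            variable_specs=specs,
            max_delta={v["name"]: float(v["max_delta"]) for v in d["variables"]},
            cohort_id=d.get("cohort_id", "reference"),
            n_animals=int(d.get("n_animals", 0)),
            time_span=tuple(d.get("time_span", (0.0, 0.0))),
            severity_context_label=d.get("severity_context_label", ""),
        )


@dataclass
class RelsaResult:
    """Scored time course for one animal.

    ``weights`` holds the per-variable, per-time reference-anchored weights
    (NaN where the input was missing), ``n_contributing`` the per-time count
    of non-missing variables, ``score`` the composite severity value (NaN
    where no variable was observed) and ``relsa_max`` its maximum over the
    defined time points.
    """

    animal_id: str
    group: str
    weights: pd.DataFrame
    n_contributing: pd.Series
    score: pd.Series
    relsa_max: float

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.score.index, dtype=float)

    @property
    def variables(self) -> list[str]:
        return list(self.weights.columns)


@dataclass
class SeverityLevels:
    """Ordered severity levels derived from maximum-score values.

    Level ``j`` (1-based) covers values up to ``thresholds[j-1]``; values
    beyond the top threshold still grade into the top level but lie outside
    the range spanned by the fitted data.
    """

    k: int
    centroids: np.ndarray
    thresholds: np.ndarray
    assignments: np.ndarray
    wss_by_k: dict[int, float] = field(default_factory=dict)
    mode: str = "lloyd"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.assignments = np.asarray(self.assignments, dtype=int)
        if len(self.centroids) != self.k or len(self.thresholds) != self.k:
            raise ValueError("need exactly k centroids and k thresholds")
        if np.any(np.diff(self.centroids) <= 0):
            raise ValueError("centroids must be strictly increasing")
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if np.any(self.thresholds < self.centroids):
            raise ValueError("each threshold must be >= its centroid")


@dataclass
class BootstrapResult:
    """Point estimate with a bias-corrected and accelerated bootstrap interval."""

    statistic_label: str
    point_estimate: float
    B: int
    ci_low: float
    ci_high: float
    level: float
    seed: int
    z0: float
    acceleration: float
    fallback_percentile: bool = False

    def as_row(self) -> dict:
        return {
            "statistic": self.statistic_label,
            "estimate": self.point_estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
            "B": self.B,
            "seed": self.seed,
            "z0": self.z0,
            "acceleration": self.acceleration,
            "fallback_percentile": self.fallback_percentile,
        }
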