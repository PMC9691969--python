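"""Synthetic cohorts with the structure the scoring model assumes.

Each simulated variable follows a baseline plateau, an abrupt deflection
at the intervention (time 0) and an exponential (half-life) recovery:

    mean(t) = baseline * (1 -/+ deflection * 2^(-t / half_life) / 100),  t >= 0

with the sign set by the severity direction, additive Gaussian noise on
the percent scale, a per-variable sampling period (daily body weight vs.
sub-daily telemetry), optional i.i.d. missingness and an optional humane
endpoint that truncates an animal's record when a variable crosses a
cut-off.  The default parameters qualitatively mimic a transmitter-
implantation cohort: ~11% body-weight drop recovering over ~10 days, a
collapse of burrowing to ~26% of baseline with fast recovery, a transient
heart-rate rise, and deep, slowly recovering drops in heart-rate
variability and activity.

`engineer_known_severity` builds noise-free animals whose composite score
is known exactly, for end-to-end recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import AnimalSeries, Direction, ReferenceSet, VariableSpec

__all__ = ["VariableSim", "SimSpec", "simulate_cohort", "engineer_known_severity"]


@dataclass(frozen=True)
class VariableSim:
    """Generator settings for one simulated outcome measure.

    deflection: % of baseline displaced at time 0 (in the severity
    direction); half_life: recovery half-life in time units; noise_sd:
    additive Gaussian sd in % points; period: sampling interval in time
    units; baseline: raw-scale baseline level (already-normalized
    variables use 100).
    """

    name: str
    direction: Direction = Direction.DECREASE
    deflection: float = 10.0
    half_life: float = 2.0
    noise_sd: float = 1.0
    period: float = 1.0
    baseline: float = 100.0
    already_normalized: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", Direction.coerce(self.direction))
        if self.deflection < 0:
            raise ValueError(f"{self.name}: deflection must be >= 0")
        if self.half_life <= 0:
            raise ValueError(f"{self.name}: half_life must be > 0")
        if self.noise_sd < 0:
            raise ValueError(f"{self.name}: noise_sd must be >= 0")
        if self.period <= 0:
            raise ValueError(f"{self.name}: period must be > 0")

    def spec(self) -> VariableSpec:
        return VariableSpec(self.name, self.direction, self.already_normalized)


def default_variables() -> tuple[VariableSim, ...]:
    """Transmitter-implantation-like defaults for a six-variable cohort."""
    return (
        VariableSim("bwc", Direction.DECREASE, deflection=11.0, half_life=3.0,
                    noise_sd=2.0, period=1.0, baseline=22.0),
        VariableSim("burON", Direction.DECREASE, deflection=74.0, half_life=0.7,
                    noise_sd=12.0, period=2.0, baseline=100.0,
                    already_normalized=True),
        VariableSim("hr", Direction.INCREASE, deflection=11.0, half_life=2.0,
                    noise_sd=2.5, period=0.5, baseline=580.0),
        VariableSim("hrv", Direction.DECREASE, deflection=76.0, half_life=4.0,
                    noise_sd=8.0, period=0.5, baseline=14.0),
        VariableSim("temp", Direction.DECREASE, deflection=0.7, half_life=1.0,
                    noise_sd=0.3, period=0.5, baseline=36.6),
        VariableSim("act", Direction.DECREASE, deflection=86.0, half_life=4.0,
                    noise_sd=9.0, period=0.5, baseline=1000.0),
    )


@dataclass
class SimSpec:
    """Study-level simulation settings.

    ``between_animal_cv`` scales each animal's deflections by a common
    multiplicative factor (coefficient of variation), producing the spread
    of per-animal severity needed for level clustering; it is reported in
    the truth table so noise-free recovery remains exact.
    """

    n_animals: int = 13
    variables: tuple[VariableSim, ...] = field(default_factory=default_variables)
    study_length: float = 14.0
    baseline_days: float = 2.0
    missing_rate: float = 0.0
    between_animal_cv: float = 0.1
    endpoint_variable: str | None = None
    endpoint_drop: float | None = None  # e.g. 20.0 for a 20% body-weight loss
    group: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.between_animal_cv < 0:
            raise ValueError("between_animal_cv must be >= 0")
        if self.study_length <= 0 or self.baseline_days <= 0:
            raise ValueError("study_length and baseline_days must be > 0")
        if (self.endpoint_variable is None) != (self.endpoint_drop is None):
            raise ValueError("endpoint_variable and endpoint_drop go together")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("simulated variable names must be unique")
        if self.endpoint_variable is not None and self.endpoint_variable not in names:
            raise ValueError(f"endpoint variable {self.endpoint_variable!r} not simulated")

    def variable_specs(self) -> list[VariableSpec]:
        return [v.spec() for v in self.variables]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["variables"] = [
            {**asdict(v), "direction": v.direction.value} for v in self.variables
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimSpec":
        d = dict(d)
        d["variables"] = tuple(VariableSim(**v) for v in d.get("variables", []))
        if not d["variables"]:
            d.pop("variables")
        return cls(**d)


def _mean_curve(v: VariableSim, t: np.ndarray, deflection: float) -> np.ndarray:
    rel = np.where(t < 0, 0.0, deflection * 2.0 ** (-t / v.half_life))
    sign = -1.0 if v.direction is Direction.DECREASE else 1.0
    return v.baseline * (1.0 + sign * rel / 100.0)


def simulate_cohort(
    spec: SimSpec, return_truth: bool = False
) -> list[AnimalSeries] | tuple[list[AnimalSeries], pd.DataFrame]:
    """Draw a cohort of raw-scale animal time series.

    Deterministic under ``spec.seed``.  With ``return_truth=True`` also
    returns a tidy table of each animal's realized per-variable deflection
    (% of baseline at time 0), from which the noise-free composite scores
    are computable in closed form.
    """
    rng = np.random.default_rng(spec.seed)
    cohort: list[AnimalSeries] = []
    truth_rows: list[dict] = []
    for a in range(spec.n_animals):
        animal_id = f"{spec.group}_{a + 1:02d}"
        scale = max(0.0, 1.0 + rng.normal(0.0, spec.between_animal_cv))
        frames = []
        for v in spec.variables:
            n_bl = int(np.ceil(spec.baseline_days / v.period))
            times = np.arange(-n_bl, np.floor(spec.study_length / v.period) + 1) * v.period
            defl = v.deflection * scale
            if v.direction is Direction.DECREASE:
                # a decrease-type variable cannot lose more than 100% of baseline
                defl = min(defl, 100.0)
            vals = _mean_curve(v, times, defl)
            if v.noise_sd > 0:
                vals = vals + v.baseline * rng.normal(0.0, v.noise_sd, times.size) / 100.0
            if spec.missing_rate > 0:
                post = times >= 0
                drop = post & (rng.random(times.size) < spec.missing_rate)
                vals = np.where(drop, np.nan, vals)
            frames.append(pd.Series(vals, index=times, name=v.name))
            truth_rows.append(
                {"animal_id": animal_id, "variable": v.name, "deflection": defl}
            )
        data = pd.concat(frames, axis=1).sort_index()
        series = AnimalSeries(animal_id=animal_id, group=spec.group, data=data)
        if spec.endpoint_variable is not None:
            series = _apply_endpoint(series, spec)
        cohort.append(series)
    if return_truth:
        return cohort, pd.DataFrame(truth_rows)
    return cohort


def _apply_endpoint(series: AnimalSeries, spec: SimSpec) -> AnimalSeries:
    """Truncate the record after a humane-endpoint crossing.

    The endpoint variable is monitored on the percent-of-baseline scale
    (baseline mean over the baseline window); the first post-baseline time
    at which it has dropped by at least ``endpoint_drop`` percent ends the
    record — no observation of any variable is kept afterwards.
    """
    vsim = next(v for v in spec.variables if v.name == spec.endpoint_variable)
    col = series.data[vsim.name]
    bl = [t for t in series.baseline_window if t in col.index]
    base = 100.0 if vsim.already_normalized else float(col.loc[bl].mean())
    norm = 100.0 * col / base
    post = norm.loc[norm.index >= 0]
    crossed = post[post <= 100.0 - spec.endpoint_drop]
    if crossed.empty:
        return series
    t_end = float(crossed.index[0])
    return AnimalSeries(
        animal_id=series.animal_id,
        group=series.group,
        data=series.data.loc[series.data.index <= t_end],
        baseline_window=series.baseline_window,
    )


def engineer_known_severity(
    ref: ReferenceSet,
    target_profile: Sequence[tuple[float, float]] | dict,
    variables: Sequence[str] | None = None,
    animal_id: str = "engineered",
    group: str = "engineered",
) -> AnimalSeries:
    """Construct a noise-free animal with a prescribed composite score.

    All chosen variables carry the same weight at every time, and the RMS
    of equal weights equals the weight itself, so setting each variable's
    normalized value to ``100 -/+ target * max_delta`` makes the scored
    time course reproduce ``target_profile`` exactly.  A target of 1 places
    every variable at the reference maximum.  Targets must be >= 0.

    ``target_profile`` maps post-baseline times (>= 0) to intended scores.
    """
    if isinstance(target_profile, dict):
        profile = sorted((float(t), float(r)) for t, r in target_profile.items())
    else:
        profile = sorted((float(t), float(r)) for t, r in target_profile)
    if not profile:
        raise ValueError("target profile is empty")
    if any(t < 0 for t, _ in profile):
        raise ValueError("target times must be post-baseline (>= 0)")
    if any(r < 0 for _, r in profile):
        raise ValueError("target scores below 0 are unreachable (weights are >= 0)")
    names = list(variables) if variables is not None else list(ref.variables)
    bad = [v for v in names if v not in ref.max_delta]
    if bad:
        raise ValueError(f"variables {bad} not in the reference set")
    times = [-1.0] + [t for t, _ in profile]
    data = pd.DataFrame(index=np.asarray(times, float))
    for v in names:
        spec = ref.spec(v)
        sign = -1.0 if spec.direction is Direction.DECREASE else 1.0
        vals = [100.0] + [100.0 + sign * r * ref.max_delta[v] for _, r in profile]
        data[v] = vals
    return AnimalSeries(
        animal_id=animal_id, group=group, data=data, baseline_window=(-1.0,)
    )
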