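"""Reference-anchored composite severity scoring.

The model: each outcome measure ``i`` is expressed as a percentage of its
pre-intervention baseline (baseline = 100).  Its deviation from baseline in
the severity direction, ``|100 - i|`` (zero at or beyond baseline in the
benign direction), is divided by the maximum such deviation observed for
that variable anywhere in a designated reference cohort, giving a
dimensionless weight

    RW_i(t) = delta_i(t) / max_delta_i,ref

that reads as "fraction of the worst deviation the reference ever showed".
At each time the available weights are combined by their root mean square,

    score(t) = sqrt( sum_i RW_i(t)^2 / N(t) ),

where ``N(t)`` counts the variables actually measured at ``t``: a missing
variable does not contribute, while a measured variable sitting at or
beyond baseline contributes zero and still counts toward ``N``.  A score of
1 means every contributing variable matches the largest deviation seen in
the reference cohort; weights and scores above 1 are possible and flag
severity beyond the reference context.

`RelsaScorer` packages reference building (``fit``) and test-animal scoring
(``transform``) as a scikit-learn style estimator; the module-level
functions expose the individual steps.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import (
    AnimalSeries,
    Direction,
    NormalizedSeries,
    ReferenceSet,
    RelsaResult,
    VariableSpec,
)

__all__ = [
    "normalize_to_baseline",
    "severity_delta",
    "build_reference_set",
    "relsa_weight",
    "relsa_score",
    "relsa_timecourse",
    "contribution_profile",
    "radar_area_fraction",
    "RelsaScorer",
]


def normalize_to_baseline(
    series: AnimalSeries, specs: Sequence[VariableSpec]
) -> NormalizedSeries:
    """Rescale each variable to percent of its baseline mean.

    The baseline aggregate is the mean of the non-missing values inside the
    animal's ``baseline_window``.  Variables flagged ``already_normalized``
    pass through unchanged.  Values above 100 are retained; directional
    clipping happens later in :func:`severity_delta`.

    Raises
    ------
    ValueError
        If a variable is not declared in ``specs``, or its baseline
        aggregate is missing, zero or negative.
    """
    by_name = {s.name: s for s in specs}
    unknown = [v for v in series.variables if v not in by_name]
    if unknown:
        raise ValueError(
            f"animal {series.animal_id!r}: variables {sorted(unknown)} not in the "
            "study configuration"
        )
    out = pd.DataFrame(index=series.data.index, dtype=float)
    bl_times = [t for t in series.baseline_window if t in series.data.index]
    for name in series.variables:
        col = series.data[name].astype(float)
        if by_name[name].already_normalized:
            out[name] = col
            continue
        base = col.loc[bl_times].mean() if bl_times else np.nan
        if not np.isfinite(base) or base <= 0:
            raise ValueError(
                f"animal {series.animal_id!r}, variable {name!r}: baseline "
                f"aggregate {base!r} is not a positive finite number"
            )
        out[name] = 100.0 * col / base
    return NormalizedSeries(
        animal_id=series.animal_id,
        group=series.group,
        data=out,
        baseline_window=tuple(series.baseline_window),
    )


def severity_delta(norm_value, direction: Direction | str):
    """Deviation from baseline in the severity direction, in percent points.

    ``decrease`` variables: ``max(0, 100 - value)``; ``increase`` variables:
    ``max(0, value - 100)``.  Values at or beyond baseline in the benign
    direction contribute zero; missing stays missing.  Accepts scalars or
    array-likes.
    """
    direction = Direction.coerce(direction)
    v = np.asarray(norm_value, dtype=float)
    if direction is Direction.DECREASE:
        out = np.maximum(0.0, 100.0 - v)
    else:
        out = np.maximum(0.0, v - 100.0)
    out = np.where(np.isnan(v), np.nan, out)
    return float(out) if np.isscalar(norm_value) or out.ndim == 0 else out


def build_reference_set(
    cohort: Iterable[NormalizedSeries],
    specs: Sequence[VariableSpec],
    label: str = "",
    cohort_id: str = "reference",
) -> ReferenceSet:
    """Derive per-variable maximum deviations from a normalized reference cohort.

    For each declared variable the maximum :func:`severity_delta` over every
    reference animal and every post-baseline time is taken (pooled over
    time, not per time point).  Variables never observed post-baseline, or
    whose maximum deviation is zero, make the build fail: silently dropping
    them would change the contributing-variable count for every downstream
    score.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("reference cohort is empty")
    by_name = {s.name: s for s in specs}
    if len(by_name) != len(specs):
        raise ValueError("variable names must be unique")
    max_delta: dict[str, float] = {}
    t_lo, t_hi = np.inf, -np.inf
    for name, spec in by_name.items():
        best = np.nan
        for animal in cohort:
            if name not in animal.data.columns:
                continue
            post = animal.post_baseline_times()
            if post.size == 0:
                continue
            t_lo = min(t_lo, post.min())
            t_hi = max(t_hi, post.max())
            deltas = severity_delta(animal.data.loc[post, name].to_numpy(), spec.direction)
            if np.any(~np.isnan(deltas)):
                best = np.nanmax([best, np.nanmax(deltas)])
        max_delta[name] = float(best)
    unusable = [v for v, d in max_delta.items() if not (d > 0)]
    if unusable:
        raise ValueError(
            "reference build failed: variables with no post-baseline deviation "
            f"(max delta zero or unobserved): {sorted(unusable)}"
        )
    return ReferenceSet(
        variable_specs=tuple(by_name.values()),
        max_delta=max_delta,
        cohort_id=cohort_id,
        n_animals=len(cohort),
        time_span=(float(t_lo), float(t_hi)),
        severity_context_label=label,
    )


def relsa_weight(norm_value, direction: Direction | str, max_delta: float):
    """Reference-anchored weight: severity deviation / reference maximum.

    Dimensionless and non-negative; unbounded above, since test animals may
    deviate further than the reference cohort ever did.  Missing in,
    missing out.
    """
    if not (max_delta > 0):
        raise ValueError(f"reference max_delta must be positive, got {max_delta!r}")
    delta = severity_delta(norm_value, direction)
    return delta / max_delta


def relsa_score(weights_at_t) -> float:
    """Root-mean-square of the available weights at one time point.

    ``N`` counts the non-missing weights; present-but-zero weights count
    toward ``N``, missing ones do not.  Returns NaN when nothing was
    measured.
    """
    w = np.asarray(weights_at_t, dtype=float)
    mask = ~np.isnan(w)
    n = int(mask.sum())
    if n == 0:
        return float("nan")
    return float(np.sqrt(np.sum(w[mask] ** 2) / n))


def relsa_timecourse(series: AnimalSeries, ref: ReferenceSet) -> RelsaResult:
    """Score one animal's full time course against a reference set.

    Any non-empty subset of the reference variables may be present; times
    where every variable is missing carry a missing score and are ignored
    by the maximum.
    """
    used = [v for v in series.variables if v in ref.max_delta]
    if not used:
        raise ValueError(
            f"animal {series.animal_id!r} shares no variables with the reference "
            f"set {sorted(ref.max_delta)}"
        )
    norm = normalize_to_baseline(
        AnimalSeries(
            animal_id=series.animal_id,
            group=series.group,
            data=series.data[used],
            baseline_window=series.baseline_window,
        ),
        [ref.spec(v) for v in used],
    )
    weights = pd.DataFrame(index=norm.data.index, dtype=float)
    for v in used:
        spec = ref.spec(v)
        weights[v] = relsa_weight(
            norm.data[v].to_numpy(), spec.direction, ref.max_delta[v]
        )
    n_contrib = weights.notna().sum(axis=1)
    with np.errstate(invalid="ignore"):
        sq = weights.pow(2).sum(axis=1, min_count=1)
    score = np.sqrt(sq / n_contrib.where(n_contrib > 0))
    score = pd.Series(score, index=weights.index, name="relsa")
    relsa_max = float(score.max()) if score.notna().any() else float("nan")
    return RelsaResult(
        animal_id=series.animal_id,
        group=series.group,
        weights=weights,
        n_contributing=n_contrib,
        score=score,
        relsa_max=relsa_max,
    )


def radar_area_fraction(radii: Sequence[float]) -> float:
    """Area of the radar polygon over the area of the unit polygon.

    Vertices sit at equal angles in the given order with radius = weight
    (missing treated as 0).  With fewer than 3 vertices the polygon has no
    area and NaN is returned.  The value depends on the variable order and
    is advisory only.
    """
    r = np.nan_to_num(np.asarray(radii, dtype=float), nan=0.0)
    n = r.size
    if n < 3:
        return float("nan")
    # polygon area = 1/2 sin(2pi/n) * sum r_j r_{j+1}; the unit polygon's
    # area is 1/2 sin(2pi/n) * n, so the sine factor cancels.
    return float(np.sum(r * np.roll(r, -1)) / n)


def contribution_profile(
    result: RelsaResult | Sequence[RelsaResult],
    at_times: Sequence[float],
    var_order: Sequence[str],
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-time weight vectors in a fixed variable order, plus radar areas.

    Passing several results averages the per-animal weights at each time
    first (a group-level profile).  Returns ``(vectors, area_fraction)``
    where ``vectors`` is indexed by the requested times with columns in
    ``var_order``.
    """
    results = [result] if isinstance(result, RelsaResult) else list(result)
    if not results:
        raise ValueError("no results given")
    ref_vars = set(results[0].variables)
    if set(var_order) != ref_vars:
        raise ValueError(
            f"var_order must be a permutation of {sorted(ref_vars)}, got {list(var_order)}"
        )
    stacked = pd.concat([r.weights for r in results], axis=0)
    mean_w = stacked.groupby(level=0).mean()
    missing_t = [t for t in at_times if t not in mean_w.index]
    if missing_t:
        raise ValueError(f"times {missing_t} not present in the scored time course")
    vectors = mean_w.loc[list(at_times), list(var_order)]
    areas = pd.Series(
        [radar_area_fraction(row) for row in vectors.to_numpy()],
        index=vectors.index,
        name="area_fraction",
    )
    return vectors, areas


class RelsaScorer(BaseEstimator, TransformerMixin):
    """Reference-anchored severity scorer in scikit-learn estimator form.

    ``fit`` normalizes a reference cohort and records each variable's
    maximum baseline deviation; ``transform`` scores test animals against
    that reference and returns a tidy per-animal/per-time table.

    Parameters
    ----------
    variables : sequence of VariableSpec
        The fixed variable set of the reference.
    severity_context_label : str
        Free-text qualitative severity of the reference procedure (e.g.
        ``"moderate"`` for transmitter implantation).

    Attributes
    ----------
    reference_ : ReferenceSet
        The fitted reference (per-variable maximum deviations).
    max_delta_ : dict
        Convenience view of ``reference_.max_delta``.
    """

    def __init__(
        self,
        variables: Sequence[VariableSpec] | None = None,
        severity_context_label: str = "",
    ):
        self.variables = variables
        self.severity_context_label = severity_context_label

    def _specs(self, cohort: Sequence[AnimalSeries]) -> list[VariableSpec]:
        if self.variables is not None:
            return list(self.variables)
        names: list[str] = []
        for a in cohort:
            for v in a.variables:
                if v not in names:
                    names.append(v)
        return [VariableSpec(n) for n in names]

    def fit(self, X: Sequence[AnimalSeries], y=None) -> "RelsaScorer":
        cohort = list(X)
        if not cohort:
            raise ValueError("reference cohort is empty")
        specs = self._specs(cohort)
        normed = [normalize_to_baseline(a, specs) for a in cohort]
        self.reference_ = build_reference_set(
            normed,
            specs,
            label=self.severity_context_label,
            cohort_id=cohort[0].group if cohort else "reference",
        )
        self.max_delta_ = dict(self.reference_.max_delta)
        return self

    def score_animal(self, series: AnimalSeries) -> RelsaResult:
        self._check_fitted()
        return relsa_timecourse(series, self.reference_)

    def transform(self, X: Sequence[AnimalSeries]) -> pd.DataFrame:
        """Score animals; returns tidy rows (animal_id, group, time, n, relsa)."""
        self._check_fitted()
        rows = []
        for series in X:
            res = relsa_timecourse(series, self.reference_)
            for t in res.times:
                rows.append(
                    {
                        "animal_id": res.animal_id,
                        "group": res.group,
                        "time": float(t),
                        "n_contributing": int(res.n_contributing.loc[t]),
                        "relsa": float(res.score.loc[t]),
                    }
                )
        return pd.DataFrame(rows)

    def relsa_max(self, X: Sequence[AnimalSeries]) -> pd.DataFrame:
        """Per-animal maximum severity summary."""
        self._check_fitted()
        rows = []
        for series in X:
            res = relsa_timecourse(series, self.reference_)
            rows.append(
                {
                    "animal_id": res.animal_id,
                    "group": res.group,
                    "relsa_max": res.relsa_max,
                }
            )
        return pd.DataFrame(rows)

    def _check_fitted(self) -> None:
        if not hasattr(self, "reference_"):
            raise ValueError("RelsaScorer is not fitted; call fit() first")
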