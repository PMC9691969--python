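"""Unit and property tests for normalization, weighting and scoring."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_animal, raw_cohort_to_series
from oracles import brute_reference_max, brute_timecourse

from relsa import (
    AnimalSeries,
    ReferenceSet,
    RelsaScorer,
    VariableSpec,
    build_reference_set,
    contribution_profile,
    engineer_known_severity,
    normalize_to_baseline,
    radar_area_fraction,
    relsa_score,
    relsa_timecourse,
    relsa_weight,
    severity_delta,
)


# ---------------------------------------------------------------- normalization

def test_normalize_to_baseline_basic(two_var_specs):
    """Baseline mean maps to 100; above-baseline values are kept unclipped."""
    animal = make_animal(
        "a1",
        {
            "bwc": {-2.0: 20.0, -1.0: 20.0, 0.0: 18.0},
            "hr": {-2.0: 600.0, -1.0: 600.0, 0.0: 642.0},
        },
        baseline_window=(-2.0, -1.0),
    )
    norm = normalize_to_baseline(animal, two_var_specs)
    assert norm.data.loc[0.0, "bwc"] == pytest.approx(90.0, abs=1e-12)
    assert norm.data.loc[0.0, "hr"] == pytest.approx(107.0, abs=1e-12)
    assert norm.data.loc[-1.0, "bwc"] == pytest.approx(100.0, abs=1e-12)


def test_normalize_passes_through_prenormalized_values():
    """Variables already on the %-of-baseline scale are left untouched."""
    spec = [VariableSpec("burON", "decrease", already_normalized=True)]
    animal = make_animal("a1", {"burON": {-1.0: 100.0, 0.0: 25.64}})
    norm = normalize_to_baseline(animal, spec)
    assert norm.data.loc[0.0, "burON"] == 25.64


def test_normalize_keeps_missing_and_aggregates_window(two_var_specs):
    animal = make_animal(
        "a1",
        {"bwc": {-2.0: 19.0, -1.0: 21.0, 0.0: None, 1.0: 10.0},
         "hr": {-2.0: 600.0, -1.0: 600.0, 0.0: 630.0, 1.0: 600.0}},
        baseline_window=(-2.0, -1.0),
    )
    norm = normalize_to_baseline(animal, two_var_specs)
    assert np.isnan(norm.data.loc[0.0, "bwc"])
    assert norm.data.loc[1.0, "bwc"] == pytest.approx(50.0, abs=1e-12)


@pytest.mark.parametrize("bad_baseline", [0.0, -5.0, None])
def test_normalize_rejects_nonpositive_baseline(bad_baseline):
    animal = make_animal("a1", {"bwc": {-1.0: bad_baseline, 0.0: 18.0}})
    with pytest.raises(ValueError, match="bwc"):
        normalize_to_baseline(animal, [VariableSpec("bwc", "decrease")])


def test_normalize_rejects_undeclared_variable(two_var_specs):
    animal = make_animal("a1", {"mystery": {-1.0: 1.0, 0.0: 1.0}})
    with pytest.raises(ValueError, match="mystery"):
        normalize_to_baseline(animal, two_var_specs)


# ------------------------------------------------------------- severity deltas

@pytest.mark.parametrize(
    "value,direction,expected",
    [
        (90.0, "decrease", 10.0),
        (110.0, "decrease", 0.0),   # at/above baseline contributes zero
        (100.0, "decrease", 0.0),
        (120.0, "increase", 20.0),
        (95.0, "increase", 0.0),    # mirrored zero rule for "up" variables
        (100.0, "increase", 0.0),
    ],
)
def test_severity_delta_directional_zero_rule(value, direction, expected):
    assert severity_delta(value, direction) == expected


def test_severity_delta_propagates_missing():
    assert math.isnan(severity_delta(float("nan"), "decrease"))
    out = severity_delta(np.array([90.0, np.nan]), "decrease")
    assert out[0] == 10.0 and np.isnan(out[1])


# ------------------------------------------------------------- reference build

def test_reference_max_pooled_over_animals():
    """The denominator is the worst deviation seen anywhere in the cohort."""
    specs = [VariableSpec("bwc", "decrease"), VariableSpec("hr", "increase")]
    a1 = make_animal("a1", {"bwc": {-1.0: 100.0, 0.0: 70.0, 1.0: 80.0},
                            "hr": {-1.0: 100.0, 0.0: 140.0}})
    a2 = make_animal("a2", {"bwc": {-1.0: 100.0, 0.0: 75.0},
                            "hr": {-1.0: 100.0, 0.0: 120.0}})
    normed = [normalize_to_baseline(a, specs) for a in (a1, a2)]
    ref = build_reference_set(normed, specs, label="moderate")
    assert ref.max_delta["bwc"] == pytest.approx(30.0, abs=1e-12)
    assert ref.max_delta["hr"] == pytest.approx(40.0, abs=1e-12)


def test_reference_rejects_flat_variable():
    specs = [VariableSpec("bwc", "decrease"), VariableSpec("flat", "decrease")]
    a = make_animal("a1", {"bwc": {-1.0: 100.0, 0.0: 70.0},
                           "flat": {-1.0: 100.0, 0.0: 100.0}})
    with pytest.raises(ValueError, match="flat"):
        build_reference_set([normalize_to_baseline(a, specs)], specs)


# --------------------------------------------------------------------- weights

@pytest.mark.parametrize(
    "norm_value,direction,max_delta,expected",
    [
        (75.0, "decrease", 30.0, 25.0 / 30.0),
        (100.0, "decrease", 30.0, 0.0),
        (100.0, "increase", 30.0, 0.0),
        (55.0, "decrease", 30.0, 1.5),  # weights may exceed 1
    ],
)
def test_relsa_weight_ratio(norm_value, direction, max_delta, expected):
    assert relsa_weight(norm_value, direction, max_delta) == pytest.approx(
        expected, abs=1e-12
    )


def test_relsa_weight_requires_positive_reference():
    with pytest.raises(ValueError):
        relsa_weight(90.0, "decrease", 0.0)


# ---------------------------------------------------------------------- scores

@pytest.mark.parametrize(
    "weights,expected",
    [
        ((1.0, 1.0, 1.0), 1.0),
        ((0.0, 0.0), 0.0),
        ((0.6, 0.8), math.sqrt((0.36 + 0.64) / 2)),
        ((1.0, float("nan"), 0.0), math.sqrt(0.5)),  # missing excluded, zero counted
    ],
)
def test_relsa_score_rms_semantics(weights, expected):
    assert relsa_score(weights) == pytest.approx(expected, abs=1e-12)


def test_relsa_score_all_missing_is_missing():
    assert math.isnan(relsa_score([float("nan")] * 3))


@given(
    st.lists(st.floats(min_value=0.0, max_value=5.0), min_size=1, max_size=8)
)
@settings(max_examples=100, derandomize=True)
def test_relsa_score_matches_manual_rms(weights):
    expected = math.sqrt(sum(w * w for w in weights) / len(weights))
    assert relsa_score(weights) == pytest.approx(expected, abs=1e-12)


@given(
    st.lists(st.floats(min_value=0.0, max_value=3.0), min_size=2, max_size=8),
    st.integers(min_value=0, max_value=7),
    st.floats(min_value=0.0, max_value=2.0),
)
@settings(max_examples=100, derandomize=True)
def test_relsa_score_monotone_in_each_weight(weights, idx, bump):
    """Raising one variable's deviation never lowers the composite score."""
    idx = idx % len(weights)
    bumped = list(weights)
    bumped[idx] = bumped[idx] + bump
    assert relsa_score(bumped) >= relsa_score(weights) - 1e-12


def test_missing_variable_neutrality_identity():
    """Dropping a weight equal to the RMS of the others leaves the score."""
    others = [0.3, 0.5, 0.4]
    rms = math.sqrt(sum(w * w for w in others) / len(others))
    full = others + [rms]
    dropped = others + [float("nan")]
    assert relsa_score(full) == pytest.approx(relsa_score(dropped), abs=1e-12)


# ------------------------------------------------------------------ timecourse

def _toy_reference():
    specs = (VariableSpec("bwc", "decrease"), VariableSpec("hr", "increase"))
    return ReferenceSet(
        variable_specs=specs, max_delta={"bwc": 30.0, "hr": 40.0},
        severity_context_label="moderate",
    )


def test_timecourse_flat_animal_scores_zero():
    ref = _toy_reference()
    animal = make_animal(
        "a1", {"bwc": {-1.0: 100.0, 0.0: 100.0, 1.0: 100.0},
               "hr": {-1.0: 100.0, 0.0: 100.0, 1.0: 100.0}},
    )
    res = relsa_timecourse(animal, ref)
    assert res.relsa_max == 0.0
    assert (res.score == 0.0).all()


def test_timecourse_single_variable_subset():
    """Any non-empty subset of the reference variables is scoreable."""
    ref = _toy_reference()
    animal = make_animal("a1", {"bwc": {-1.0: 100.0, 0.0: 85.0}})
    res = relsa_timecourse(animal, ref)
    assert res.relsa_max == pytest.approx(0.5, abs=1e-12)
    assert res.n_contributing.loc[0.0] == 1


def test_timecourse_empty_intersection_errors():
    ref = _toy_reference()
    animal = make_animal("a1", {"temp": {-1.0: 100.0, 0.0: 99.0}})
    with pytest.raises(ValueError, match="no variables"):
        relsa_timecourse(animal, ref)


def test_timecourse_all_missing_time_ignored_by_max():
    ref = _toy_reference()
    animal = make_animal(
        "a1", {"bwc": {-1.0: 100.0, 0.0: 85.0, 1.0: None},
               "hr": {-1.0: 100.0, 0.0: 100.0, 1.0: None}},
    )
    res = relsa_timecourse(animal, ref)
    assert np.isnan(res.score.loc[1.0])
    assert res.n_contributing.loc[1.0] == 0
    assert res.relsa_max == pytest.approx(relsa_score([0.5, 0.0]), abs=1e-12)


def test_scale_invariance_of_scores():
    """Rescaling a raw variable (sensor units) cannot change the scores."""
    specs = [VariableSpec("bwc", "decrease"), VariableSpec("hr", "increase")]
    base = {"bwc": {-1.0: 20.0, 0.0: 16.0, 1.0: 18.0},
            "hr": {-1.0: 600.0, 0.0: 690.0, 1.0: 620.0}}
    scaled = {"bwc": {t: v * 1000.0 for t, v in base["bwc"].items()},
              "hr": {t: v * 0.001 for t, v in base["hr"].items()}}
    cohort_a = [make_animal("a1", base)]
    cohort_b = [make_animal("a1", scaled)]
    ref_a = build_reference_set([normalize_to_baseline(a, specs) for a in cohort_a], specs)
    ref_b = build_reference_set([normalize_to_baseline(a, specs) for a in cohort_b], specs)
    res_a = relsa_timecourse(cohort_a[0], ref_a)
    res_b = relsa_timecourse(cohort_b[0], ref_b)
    np.testing.assert_allclose(res_a.score, res_b.score, atol=1e-12)
    np.testing.assert_allclose(res_a.weights, res_b.weights, atol=1e-12)


def test_self_reference_ceiling(fitted_scorer, default_sim):
    """Reference animals scored against their own reference stay at RW <= 1,
    and each variable's maximum weight is attained (RW = 1) somewhere."""
    _, cohort, _ = default_sim
    ref = fitted_scorer.reference_
    per_var_max = {v: 0.0 for v in ref.variables}
    for animal in cohort:
        res = relsa_timecourse(animal, ref)
        post = [t for t in res.times if t >= 0]
        w = res.weights.loc[post]
        assert np.nanmax(w.to_numpy()) <= 1.0 + 1e-12
        for v in ref.variables:
            per_var_max[v] = max(per_var_max[v], np.nanmax(w[v].to_numpy()))
    for v, m in per_var_max.items():
        assert m == pytest.approx(1.0, abs=1e-9), v


def test_timecourse_matches_brute_force_oracle(rng_seed=123):
    """Full pipeline agrees with the loop-level reimplementation."""
    from conftest import random_raw_cohort

    rng = np.random.default_rng(rng_seed)
    for _ in range(10):
        cohort, specs, bl = random_raw_cohort(rng)
        spec_objs = [
            VariableSpec(v, s["direction"], s["already_normalized"])
            for v, s in specs.items()
        ]
        series = raw_cohort_to_series(cohort)
        normed = [normalize_to_baseline(a, spec_objs) for a in series]
        try:
            ref = build_reference_set(normed, spec_objs)
        except ValueError:
            continue  # degenerate draw (a variable never deviates)
        expected_max = brute_reference_max(cohort, specs, bl)
        for v in ref.variables:
            assert ref.max_delta[v] == pytest.approx(expected_max[v], abs=1e-12)
        for a in series:
            res = relsa_timecourse(a, ref)
            want = brute_timecourse(cohort[a.animal_id], specs, bl, ref.max_delta)
            for t in res.times:
                w = want["scores"][t]
                got = res.score.loc[t]
                if w is None:
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(w, abs=1e-12)
            assert res.relsa_max == pytest.approx(want["relsa_max"], abs=1e-12)


# ------------------------------------------------------------- radar profiles

def test_radar_area_fraction_extremes():
    assert radar_area_fraction([1.0] * 5) == pytest.approx(1.0, abs=1e-12)
    assert radar_area_fraction([0.0] * 5) == 0.0
    # a single spoke spans no area (order-dependence caveat)
    assert radar_area_fraction([1.0, 0.0, 0.0, 0.0, 0.0]) == 0.0
    assert math.isnan(radar_area_fraction([1.0, 1.0]))


def test_contribution_profile_vectors_and_group_mean(fitted_scorer, default_sim):
    _, cohort, _ = default_sim
    ref = fitted_scorer.reference_
    results = [relsa_timecourse(a, ref) for a in cohort[:3]]
    order = list(reversed(ref.variables))
    vectors, areas = contribution_profile(results, at_times=[0.0], var_order=order)
    assert list(vectors.columns) == order
    stacked = np.array([r.weights.loc[0.0, order].to_numpy() for r in results])
    np.testing.assert_allclose(vectors.loc[0.0].to_numpy(), stacked.mean(axis=0), atol=1e-12)
    assert 0.0 <= float(areas.loc[0.0])


def test_contribution_profile_validates_order(fitted_scorer, default_sim):
    _, cohort, _ = default_sim
    res = relsa_timecourse(cohort[0], fitted_scorer.reference_)
    with pytest.raises(ValueError, match="permutation"):
        contribution_profile(res, at_times=[0.0], var_order=["bwc"])


# ----------------------------------------------------------- estimator surface

def test_scorer_sklearn_surface(default_sim):
    spec, cohort, _ = default_sim
    scorer = RelsaScorer(variables=[v.spec() for v in spec.variables])
    params = scorer.get_params()
    assert "variables" in params and "severity_context_label" in params
    scorer.set_params(severity_context_label="moderate").fit(cohort)
    tidy = scorer.transform(cohort[:2])
    assert set(tidy.columns) == {"animal_id", "group", "time", "n_contributing", "relsa"}
    summary = scorer.relsa_max(cohort[:2])
    assert len(summary) == 2
    assert (summary["relsa_max"] >= 0).all()


def test_scorer_requires_fit(default_sim):
    _, cohort, _ = default_sim
    with pytest.raises(ValueError, match="not fitted"):
        RelsaScorer().transform(cohort)


def test_engineered_ceiling_animal_scores_one(fitted_scorer):
    """An animal matching every reference maximum sits exactly at score 1."""
    ref = fitted_scorer.reference_
    animal = engineer_known_severity(ref, {0.0: 1.0})
    res = relsa_timecourse(animal, ref)
    assert res.score.loc[0.0] == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_allclose(res.weights.loc[0.0].to_numpy(), 1.0, atol=1e-12)
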