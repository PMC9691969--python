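from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from relsa import (
    AnimalSeries,
    RelsaScorer,
    SimSpec,
    VariableSpec,
    simulate_cohort,
)


def make_animal(animal_id, data: dict, baseline_window=None, group="test"):
    """Build an AnimalSeries from {variable: {time: value}} (None = missing)."""
    times = sorted({t for col in data.values() for t in col})
    frame = pd.DataFrame(
        {
            var: [np.nan if col.get(t) is None else float(col.get(t, np.nan)) for t in times]
            for var, col in data.items()
        },
        index=np.asarray(times, dtype=float),
    )
    return AnimalSeries(
        animal_id=animal_id, group=group, data=frame, baseline_window=baseline_window
    )


def random_raw_cohort(rng, n_animals=None, n_vars=None, n_times=None):
    """Random small study in the oracle's dict representation.

    Returns (cohort_dict, specs_dict, baseline_times).  Values stay well
    away from baseline-crossing pathologies only by bounded noise; missing
    entries are sprinkled post-baseline.
    """
    n_animals = n_animals or rng.integers(2, 6)
    n_vars = n_vars or rng.integers(1, 7)
    n_times = n_times or rng.integers(3, 11)
    baseline_times = [-1.0]
    post_times = [float(t) for t in range(n_times - 1)]
    specs = {}
    for j in range(n_vars):
        specs[f"v{j}"] = {
            "direction": "decrease" if rng.random() < 0.5 else "increase",
            "already_normalized": bool(rng.random() < 0.25),
        }
    cohort = {}
    for i in range(n_animals):
        animal = {}
        for var, sp in specs.items():
            base = 100.0 if sp["already_normalized"] else float(rng.uniform(5, 500))
            series = {-1.0: base}
            for t in post_times:
                if rng.random() < 0.15:
                    series[t] = None
                else:
                    series[t] = float(base * rng.uniform(0.3, 1.4))
            animal[var] = series
        cohort[f"a{i}"] = animal
    return cohort, specs, baseline_times


def raw_cohort_to_series(cohort: dict, group="ref"):
    return [make_animal(aid, data, baseline_window=(-1.0,), group=group)
            for aid, data in cohort.items()]


@pytest.fixture(scope="session")
def default_sim():
    spec = SimSpec(seed=42)
    cohort, truth = simulate_cohort(spec, return_truth=True)
    return spec, cohort, truth


@pytest.fixture(scope="session")
def fitted_scorer(default_sim):
    spec, cohort, _ = default_sim
    return RelsaScorer(
        variables=[v.spec() for v in spec.variables],
        severity_context_label="moderate",
    ).fit(cohort)


@pytest.fixture()
def two_var_specs():
    return [
        VariableSpec("bwc", "decrease"),
        VariableSpec("hr", "increase"),
    ]
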