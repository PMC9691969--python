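"""Independent brute-force oracles used by the tests.

Everything here is written in plain Python loops over dicts, deliberately
sharing no code path with the package: scores are recomputed directly from
the definitions (baseline normalization, directional deltas over reference
maxima, RMS over available weights), and 1-D clusterings are found by
exhaustive enumeration of contiguous partitions.
"""

from __future__ import annotations

import itertools
import math

# raw cohort representation for the oracle:
#   {animal_id: {variable: {time: value-or-None}}}
# specs: {variable: {"direction": "decrease"|"increase", "already_normalized": bool}}


def brute_baseline_mean(series: dict, baseline_times) -> float:
    vals = [series[t] for t in baseline_times if t in series and series[t] is not None]
    return sum(vals) / len(vals) if vals else float("nan")


def brute_normalize(series: dict, baseline_times, already_normalized: bool) -> dict:
    if already_normalized:
        return dict(series)
    base = brute_baseline_mean(series, baseline_times)
    return {
        t: (None if v is None else 100.0 * v / base) for t, v in series.items()
    }


def brute_delta(norm_value, direction: str):
    if norm_value is None:
        return None
    if direction == "decrease":
        return max(0.0, 100.0 - norm_value)
    return max(0.0, norm_value - 100.0)


def brute_reference_max(cohort: dict, specs: dict, baseline_times) -> dict:
    """Pooled maximum post-baseline deviation per variable."""
    out = {}
    for var, spec in specs.items():
        best = None
        for animal in cohort.values():
            if var not in animal:
                continue
            norm = brute_normalize(
                animal[var], baseline_times, spec["already_normalized"]
            )
            for t, v in norm.items():
                if t in baseline_times or v is None:
                    continue
                d = brute_delta(v, spec["direction"])
                if best is None or d > best:
                    best = d
        out[var] = best
    return out


def brute_score_at(weights: list) -> float | None:
    present = [w for w in weights if w is not None]
    if not present:
        return None
    return math.sqrt(sum(w * w for w in present) / len(present))


def brute_timecourse(
    animal: dict, specs: dict, baseline_times, max_delta: dict
) -> dict:
    """Per-time weights and scores for one animal, straight from definitions."""
    variables = [v for v in animal if v in max_delta]
    norm = {
        v: brute_normalize(animal[v], baseline_times, specs[v]["already_normalized"])
        for v in variables
    }
    times = sorted({t for v in variables for t in animal[v]})
    weights = {}
    scores = {}
    for t in times:
        w_t = []
        for v in variables:
            nv = norm[v].get(t)
            d = brute_delta(nv, specs[v]["direction"])
            w_t.append(None if d is None else d / max_delta[v])
        weights[t] = dict(zip(variables, w_t))
        scores[t] = brute_score_at(w_t)
    defined = [s for s in scores.values() if s is not None]
    return {
        "weights": weights,
        "scores": scores,
        "relsa_max": max(defined) if defined else None,
    }


def brute_best_contiguous_partition(values, k: int) -> tuple[list, float]:
    """Minimum-WSS split of sorted values into k contiguous blocks, by
    exhaustive enumeration of the split points."""
    xs = sorted(values)
    n = len(xs)

    def wss_block(block):
        m = sum(block) / len(block)
        return sum((x - m) ** 2 for x in block)

    best_labels, best_wss = None, float("inf")
    for splits in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *splits, n]
        total = 0.0
        labels = [0] * n
        for j in range(k):
            block = xs[bounds[j]: bounds[j + 1]]
            total += wss_block(block)
            for i in range(bounds[j], bounds[j + 1]):
                labels[i] = j
        if total < best_wss - 1e-15:
            best_wss, best_labels = total, labels
    return best_labels, best_wss
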