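"""End-to-end run: reference build, scoring, levels, bootstrap, bundle on disk."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .bootstrap import bootstrap_bca, bootstrap_cluster_centroids
from .containers import AnimalSeries, ReferenceSet, RelsaResult, SeverityLevels
from .core import RelsaScorer, relsa_timecourse
from .io import (
    StudyConfig,
    read_table,
    write_reference,
    write_scores,
    write_summary,
    write_weights,
)
from .levels import SeverityClassifier

log = logging.getLogger("relsa")


@dataclass
class PipelineResult:
    """In-memory view of a finished run (everything is also on disk)."""

    reference: ReferenceSet
    results: list[RelsaResult]
    summary: pd.DataFrame
    levels: SeverityLevels | None
    out_dir: Path


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"[stage {name}] {exc}") from exc
        return wrapper
    return deco


@_stage("read")
def _read(data_path, config: StudyConfig) -> list[AnimalSeries]:
    cohort = read_table(data_path, layout=config.layout, config=config)
    if not cohort:
        raise ValueError("no animals in the input table")
    return cohort


@_stage("reference")
def _build_reference(cohort: Sequence[AnimalSeries], config: StudyConfig) -> RelsaScorer:
    ref_cohort = [a for a in cohort if a.group == config.reference_group]
    if not ref_cohort:
        raise ValueError(
            f"no animals with reference group label {config.reference_group!r}"
        )
    scorer = RelsaScorer(
        variables=config.variable_specs() or None,
        severity_context_label=config.severity_context_label,
    )
    return scorer.fit(ref_cohort)


@_stage("score")
def _score(cohort: Sequence[AnimalSeries], scorer: RelsaScorer) -> list[RelsaResult]:
    return [relsa_timecourse(a, scorer.reference_) for a in cohort]


@_stage("levels")
def _levels(summary: pd.DataFrame, config: StudyConfig) -> SeverityClassifier:
    clf = SeverityClassifier(
        k=config.k,
        mode=config.level_mode,
        restarts=config.restarts,
        threshold_mode=config.threshold_mode,
        random_state=config.seed,
    )
    return clf.fit(summary["relsa_max"].to_numpy())


@_stage("bootstrap")
def _bootstrap(summary: pd.DataFrame, levels: SeverityLevels | None, config: StudyConfig) -> pd.DataFrame:
    rows = []
    for i, (group, sub) in enumerate(sorted(summary.groupby("group"))):
        vals = sub["relsa_max"].to_numpy()
        if vals.size < 2:
            log.warning("group %s has < 2 animals; skipping bootstrap", group)
            continue
        res = bootstrap_bca(
            vals, statistic="mean", B=config.bootstrap_B,
            seed=config.seed + i, level=0.95, label=f"mean[{group}]",
        )
        rows.append({"group": group, **res.as_row()})
    if levels is not None:
        for res in bootstrap_cluster_centroids(
            summary["relsa_max"].to_numpy(), levels,
            B=config.bootstrap_B, seed=config.seed + 1000,
        ):
            rows.append({"group": "", **res.as_row()})
    return pd.DataFrame(rows)


def run_pipeline(
    config: StudyConfig,
    data_path: str | Path,
    out_dir: str | Path,
    skip_levels: bool = False,
) -> PipelineResult:
    """Run the full severity-assessment pipeline and write the result bundle.

    Writes the reference-set JSON, tidy weight and score tables, the
    per-animal maximum-score summary (with level assignments when
    clustering ran), the level thresholds, bootstrap intervals and a run
    log recording seed and software version.  Outputs contain no wall-clock
    information, so a rerun under the same seed is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_log: list[str] = [f"relsa {__version__}", f"seed {config.seed}"]

    cohort = _read(data_path, config)
    run_log.append(f"read {len(cohort)} animals from {Path(data_path).name}")

    scorer = _build_reference(cohort, config)
    ref = scorer.reference_
    write_reference(ref, out / "reference_set.json")
    run_log.append(
        f"reference group {config.reference_group!r}: {ref.n_animals} animals, "
        f"variables {ref.variables}"
    )

    results = _score(cohort, scorer)
    meta = {"seed": config.seed, "version": __version__}
    write_weights(results, out / "weights.csv", meta)
    write_scores(results, out / "scores.csv", meta)
    summary = write_summary(results, out / "relsa_max.csv", meta)

    levels = None
    if not skip_levels:
        clf = _levels(summary, config)
        levels = clf.levels_
        thresholds = pd.DataFrame(
            {
                "level": [f"L{j + 1}" for j in range(levels.k)],
                "centroid": levels.centroids,
                "threshold": levels.thresholds,
            }
        )
        thresholds.to_csv(out / "thresholds.csv", index=False)
        summary = summary.assign(level=clf.predict(summary["relsa_max"].to_numpy()))
        summary.to_csv(out / "relsa_max.csv", index=False)
        run_log.append(
            f"severity levels: k={levels.k} mode={levels.mode} "
            f"thresholds={[round(t, 6) for t in levels.thresholds]}"
        )

    boot = _bootstrap(summary, levels, config)
    boot.to_csv(out / "bootstrap.csv", index=False)
    run_log.append(f"bootstrap: B={config.bootstrap_B}, {len(boot)} statistics")

    (out / "run_log.txt").write_text("\n".join(run_log) + "\n")
    (out / "config_used.json").write_text(
        json.dumps(
            {**config.__dict__, "version": __version__}, indent=2, sort_keys=True,
            default=str,
        )
        + "\n"
    )
    return PipelineResult(
        reference=ref, results=results, summary=summary, levels=levels, out_dir=out
    )
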