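"""Cohort aggregation and the study's summary artifacts.

Builds cohort means +/- SEM per strain x stage, the per-bin time-course
curves, the size-speed correlation, machine-readable comparison tables and
an ontogeny figure, together with a JSON manifest that contains every number
plotted (no figure-only values).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .stats import ComparisonMatrix, StatResult, pearson_test

COHORT_METRICS = ("total_distance_cm", "mean_speed_cm_s", "swim_time_s",
                  "n_events", "event_speed", "surface_mm2")


@dataclass
class CohortSummary:
    """Mean and SEM per metric for one strain x stage cohort."""

    strain: str
    stage: str
    n: int
    metrics: dict[str, tuple[float, float]]  # name -> (mean, sem)

    def mean(self, name: str) -> float:
        return self.metrics[name][0]

    def sem(self, name: str) -> float:
        return self.metrics[name][1]


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(len(v)))


def build_cohort_summary(summaries: pd.DataFrame,
                         fastswim_results: pd.DataFrame | None,
                         surfaces: Sequence[float] | None,
                         strain: str, stage: str) -> CohortSummary:
    """Aggregate per-animal results into a cohort summary.

    Metrics absent for a cohort (e.g. surface area at 6 dpf) are simply not
    recorded rather than filled with placeholders.
    """
    sub = summaries[(summaries["strain"] == strain) & (summaries["stage"] == stage)]
    if len(sub) < 2:
        raise ValidationError(f"cohort {strain}/{stage} needs at least 2 animals")
    metrics: dict[str, tuple[float, float]] = {}
    for name in ("total_distance_cm", "mean_speed_cm_s", "swim_time_s"):
        metrics[name] = _mean_sem(sub[name].to_numpy())
    if fastswim_results is not None and len(fastswim_results) >= 2:
        metrics["n_events"] = _mean_sem(fastswim_results["n_events"].to_numpy())
        speeds = fastswim_results["mean_event_speed_mm_s"].dropna().to_numpy()
        if len(speeds) >= 2:
            metrics["event_speed"] = _mean_sem(speeds)
    if surfaces is not None and len(surfaces) >= 2:
        metrics["surface_mm2"] = _mean_sem(np.asarray(surfaces))
    return CohortSummary(strain=strain, stage=stage, n=len(sub), metrics=metrics)


def size_speed_correlation(surfaces: Sequence[float],
                           speeds: Sequence[float]) -> dict:
    """Pearson r between body surface area and mean swimming speed.

    Sign convention: negative r means larger fish swim slower.  r is
    symmetric in the two variables; both regression slopes are reported
    since the choice of dependent variable only affects the fitted line.
    """
    surfaces = np.asarray(surfaces, dtype=float)
    speeds = np.asarray(speeds, dtype=float)
    if len(surfaces) != len(speeds):
        raise ValidationError("surfaces and speeds must be paired per animal")
    res: StatResult = pearson_test(speeds, surfaces)
    slope_surface_on_speed = float(np.polyfit(speeds, surfaces, 1)[0])
    slope_speed_on_surface = float(np.polyfit(surfaces, speeds, 1)[0])
    return {"r": res.statistic, "p_value": res.p_value, "df": res.df,
            "stars": res.stars,
            "slope_surface_on_speed": slope_surface_on_speed,
            "slope_speed_on_surface": slope_speed_on_surface}


def render_outputs(cohorts: Sequence[CohortSummary],
                   timecourses: Mapping[tuple[str, str], pd.DataFrame] | None,
                   comparisons: Mapping[tuple[str, str], ComparisonMatrix] | None,
                   out_dir: str | Path) -> dict:
    """Write the deterministic output bundle; returns the manifest dict.

    Outputs: ``cohort_summary.csv``, ``comparison_<metric>_<stage>.csv``,
    per-stage time-course figures, an ontogeny scatter, ``manifest.json``.
    An empty cohort list produces an empty manifest and no figures.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"cohorts": {}, "timecourses": {}, "comparisons": {}}
    if not cohorts:
        warnings.warn("no cohorts given; writing an empty manifest", stacklevel=2)
        _write_manifest(manifest, out_dir)
        return manifest

    rows = []
    for c in sorted(cohorts, key=lambda c: (c.stage, c.strain)):
        entry = {"n": c.n}
        for name, (mean, sem) in sorted(c.metrics.items()):
            entry[f"{name}_mean"] = mean
            entry[f"{name}_sem"] = sem
        manifest["cohorts"][f"{c.strain}/{c.stage}"] = entry
        rows.append({"strain": c.strain, "stage": c.stage, **entry})
    pd.DataFrame(rows).to_csv(out_dir / "cohort_summary.csv", index=False)

    if timecourses:
        for (strain, stage), tc in sorted(timecourses.items()):
            manifest["timecourses"][f"{strain}/{stage}"] = {
                "bin_start_s": [float(v) for v in tc.index],
                "mean": [float(v) for v in tc["mean"]],
                "sem": [float(v) for v in tc["sem"]],
            }
    if comparisons:
        for (metric, stage), cm in sorted(comparisons.items()):
            cm.long_frame().to_csv(out_dir / f"comparison_{metric}_{stage}.csv",
                                   index=False)
            manifest["comparisons"][f"{metric}/{stage}"] = {
                f"{a}|{b}": cm.get(a, b).p_value
                for a in cm.group_labels for b in cm.group_labels if a < b
            }
            if cm.adjusted_alpha is not None:
                manifest["comparisons"][f"{metric}/{stage}"]["adjusted_alpha"] = \
                    cm.adjusted_alpha

    _plot(cohorts, timecourses, out_dir)
    _write_manifest(manifest, out_dir)
    return manifest


def ontogeny_table(cohorts: Sequence[CohortSummary]) -> pd.DataFrame:
    """Per-strain ordered stage triples of (distance, speed, swim time) means.

    Strains missing a stage are kept with explicit gaps (NaN) and flagged in
    the ``complete`` column rather than dropped.
    """
    stage_order = ["6dpf", "1month", "3months"]
    by_strain: dict[str, dict[str, CohortSummary]] = {}
    for c in cohorts:
        by_strain.setdefault(c.strain, {})[c.stage] = c
    rows = []
    for strain in sorted(by_strain):
        row: dict = {"strain": strain}
        complete = True
        for stage in stage_order:
            c = by_strain[strain].get(stage)
            if c is None:
                complete = False
                row[f"distance_cm_{stage}"] = np.nan
                row[f"speed_cm_s_{stage}"] = np.nan
                row[f"swim_time_s_{stage}"] = np.nan
            else:
                row[f"distance_cm_{stage}"] = c.mean("total_distance_cm")
                row[f"speed_cm_s_{stage}"] = c.mean("mean_speed_cm_s")
                row[f"swim_time_s_{stage}"] = c.mean("swim_time_s")
        row["complete"] = complete
        rows.append(row)
    return pd.DataFrame(rows)


def _plot(cohorts, timecourses, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if timecourses:
        stages = sorted({stage for (_, stage) in timecourses})
        for stage in stages:
            fig, ax = plt.subplots(figsize=(6, 4))
            for (strain, st), tc in sorted(timecourses.items()):
                if st != stage:
                    continue
                ax.errorbar(tc.index, tc["mean"], yerr=tc["sem"], label=strain,
                            capsize=2)
            ax.set_xlabel("time (s)")
            ax.set_ylabel("distance per bin (mm)")
            ax.set_title(f"distance time course, {stage}")
            ax.legend(fontsize=8)
            fig.savefig(out_dir / f"timecourse_{stage}.png", dpi=120)
            plt.close(fig)

    table = ontogeny_table(cohorts)
    if len(table):
        fig, ax = plt.subplots(figsize=(6, 4))
        markers = {"6dpf": "o", "1month": "s", "3months": "^"}
        for stage in ("6dpf", "1month", "3months"):
            xs = table[f"speed_cm_s_{stage}"]
            ys = table[f"distance_cm_{stage}"]
            ax.scatter(xs, ys, marker=markers[stage], label=stage)
        ax.set_xlabel("mean speed (cm/s)")
        ax.set_ylabel("total distance (cm)")
        ax.set_title("ontogeny of locomotion")
        ax.legend()
        fig.savefig(out_dir / "ontogeny.png", dpi=120)
        plt.close(fig)


def _write_manifest(manifest: dict, out_dir: Path) -> None:
    text = json.dumps(manifest, sort_keys=True, indent=1)
    (out_dir / "manifest.json").write_text(text, encoding="utf-8")
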