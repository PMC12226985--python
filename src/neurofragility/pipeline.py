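"""Orchestration: per-patient runs and cohort-level analysis.

``analyze_patient`` chains the per-snapshot stages (resample to 500 Hz,
bandpass 0.1-30 Hz, bad-channel exclusion, windowed operator fits, fragility
map and normalization, channel features).  ``run_cohort_analysis`` adds the
cross-patient stages: LOPO random-forest SOZ prediction, per-patient
precision/recall, paired SOZ-vs-NSOZ fragility tests by outcome group, the
logistic outcome model and Engel-group summaries.  File-level wrappers
(`run_patient`, `run_cohort`) read EDF + CSV inputs and write all artifacts
plus the serialized effective config.

Patient-level fragility enters the statistics as the mean *normalized*
fragility over SOZE channels vs non-SOZE channels (bad channels excluded).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_stats import (
    OutcomeModelResult,
    PairedTestResult,
    engel_group_summary,
    fit_outcome_model,
    paired_fragility_test,
    plot_forest,
)
from .config import RunConfig
from .dynamics import fit_operator_series
from .fragility import (
    FragilityMap,
    compute_fragility_map,
    default_omega_grid,
    normalize_map,
    plot_fragility_heatmap,
)
from .io_formats import (
    ChannelAnnotation,
    CohortTable,
    SeegRecording,
    read_channel_annotation,
    read_cohort_table,
    read_edf,
    write_fragility_map,
)
from .preprocess import bandpass_filter, detect_bad_channels, drop_bad_channels, plan_windows, resample_to
from .soz_classifier import (
    PatientMetrics,
    extract_channel_features,
    predict_channels,
    score_patient,
    train_and_crossvalidate,
)

logger = logging.getLogger(__name__)


@dataclass
class PatientResult:
    """Everything the per-snapshot pipeline produces for one patient."""

    fragility_map: FragilityMap  # normalized filled
    features: pd.DataFrame
    annotation: ChannelAnnotation  # retained (good) channels only
    n_unstable_windows: int
    predictions: np.ndarray | None = None
    metrics: PatientMetrics | None = None


@dataclass
class CohortResult:
    """Cohort-level outputs: per-patient results, metrics and statistics."""

    patients: dict[str, PatientResult]
    metrics: pd.DataFrame  # indexed rows with patient_id + 4 metric columns
    pairs: pd.DataFrame  # patient_id, soz_fragility, nsoz_fragility, success
    cohort: CohortTable  # with metrics joined
    paired_tests: dict[str, PairedTestResult | None]
    paired_test_errors: dict[str, str] = field(default_factory=dict)
    outcome_model: OutcomeModelResult | None = None
    outcome_model_error: str | None = None
    engel_summary: pd.DataFrame | None = None
    failures: dict[str, str] = field(default_factory=dict)


def analyze_patient(rec: SeegRecording, ann: ChannelAnnotation, config: RunConfig | None = None) -> PatientResult:
    """Run the per-snapshot pipeline on an in-memory recording."""
    if config is None:
        config = RunConfig()
    pp = config.preprocess
    # artifact screening happens on the as-recorded broadband signal: the
    # narrowband analysis stages concentrate physiological power and would
    # inflate the amplitude-outlier ratio of genuinely fragile channels
    ann = detect_bad_channels(rec, ann, k=pp.bad_k, flat_eps=pp.flat_eps)
    rec, ann = drop_bad_channels(rec, ann)
    rec = resample_to(rec, pp.target_fs)
    rec = bandpass_filter(rec, *pp.band)
    if pp.car:
        data = rec.data - rec.data.mean(axis=0, keepdims=True)
        rec = SeegRecording(data, rec.fs, list(rec.channel_names), rec.t0)
    plan = plan_windows(rec.n_samples, rec.fs, pp.win_ms, pp.overlap_ms)
    series = fit_operator_series(rec, plan, reg=config.dynamics.reg)
    grid = default_omega_grid(config.fragility.omega_points)
    fmap = compute_fragility_map(series, mode=config.fragility.mode, omega_grid=grid)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fmap = normalize_map(fmap)
    features = extract_channel_features(fmap)
    n_unstable = int((fmap.raw.max(axis=0) <= 0).sum())
    return PatientResult(
        fragility_map=fmap, features=features, annotation=ann, n_unstable_windows=n_unstable
    )


def fragility_pair(result: PatientResult) -> tuple[float, float]:
    """Patient-level (mean SOZE fragility, mean non-SOZE fragility), normalized scale."""
    values = result.fragility_map.normalized
    soze = result.annotation.is_soze
    ch_mean = values.mean(axis=1)
    soz = float(ch_mean[soze].mean()) if soze.any() else float("nan")
    nsoz = float(ch_mean[~soze].mean()) if (~soze).any() else float("nan")
    return soz, nsoz


def run_cohort_analysis(
    patients: dict[str, tuple[SeegRecording, ChannelAnnotation]],
    cohort: CohortTable,
    config: RunConfig | None = None,
) -> CohortResult:
    """Cohort pipeline on in-memory patients: per-snapshot stages, LOPO
    classification, concordance metrics and all cohort statistics.

    Per-patient stage failures are recorded in ``result.failures`` and the
    statistics are computed on the completed subset.
    """
    if config is None:
        config = RunConfig()
    if len(patients) < 2:
        raise ValueError("cohort analysis needs at least 2 patients (no LOPO folds otherwise)")
    results: dict[str, PatientResult] = {}
    failures: dict[str, str] = {}
    for pid, (rec, ann) in patients.items():
        t0 = time.perf_counter()
        try:
            results[pid] = analyze_patient(rec, ann, config)
        except Exception as exc:
            failures[pid] = f"{type(exc).__name__}: {exc}"
            logger.warning("patient %s failed: %s", pid, failures[pid])
            continue
        logger.info(
            "patient %s analyzed in %.1fs (%d unstable windows)",
            pid,
            time.perf_counter() - t0,
            results[pid].n_unstable_windows,
        )
    if len(results) < 2:
        raise RuntimeError(f"fewer than 2 patients completed; failures: {failures}")

    lopo = train_and_crossvalidate(
        [(pid, r.features, r.annotation) for pid, r in results.items()],
        seed=config.seed,
        n_trees=config.classifier.n_trees,
        threshold=config.classifier.threshold,
    )
    metric_rows, pair_rows = [], []
    success_by_pid = dict(zip(cohort.table["patient_id"], cohort.success))
    for pid, r in results.items():
        pred = lopo.patient_pred(pid)
        r.predictions = pred
        r.metrics = score_patient(pred, r.annotation, list(r.features.index))
        metric_rows.append({"patient_id": pid, **r.metrics.as_dict()})
        soz, nsoz = fragility_pair(r)
        pair_rows.append(
            {
                "patient_id": pid,
                "soz_fragility": soz,
                "nsoz_fragility": nsoz,
                "success": bool(success_by_pid.get(pid, False)),
            }
        )
    metrics = pd.DataFrame(metric_rows)
    pairs = pd.DataFrame(pair_rows)
    cohort_full = cohort.with_metrics(metrics)

    paired_tests: dict[str, PairedTestResult | None] = {}
    paired_errors: dict[str, str] = {}
    for group in ("success", "failure"):
        try:
            paired_tests[group] = paired_fragility_test(pairs, group)
        except ValueError as exc:
            paired_tests[group] = None
            paired_errors[group] = str(exc)

    outcome_model: OutcomeModelResult | None = None
    outcome_error: str | None = None
    try:
        outcome_model = fit_outcome_model(cohort_full.table)
    except ValueError as exc:
        outcome_error = str(exc)

    engel = engel_group_summary(cohort_full.table) if cohort_full.has_metrics else None
    return CohortResult(
        patients=results,
        metrics=metrics,
        pairs=pairs,
        cohort=cohort_full,
        paired_tests=paired_tests,
        paired_test_errors=paired_errors,
        outcome_model=outcome_model,
        outcome_model_error=outcome_error,
        engel_summary=engel,
        failures=failures,
    )


# ---------------------------------------------------------------------------
# File-level entry points
# ---------------------------------------------------------------------------

def _write_effective_config(config: RunConfig, out_dir: Path) -> None:
    from . import __version__

    config.dump(out_dir / "effective_config.json")
    (out_dir / "package_version.txt").write_text(__version__ + "\n")


def run_patient(
    recording_path: str | Path,
    annotation_path: str | Path,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
    model=None,
) -> PatientResult:
    """Single-patient file entry point: EDF + annotation CSV in, artifacts out.

    Writes the fragility container, heatmap image, feature CSV and (when a
    trained cross-patient model is supplied) predictions and metrics CSVs.
    On any stage failure, partial outputs are removed and the error carries
    the stage name.
    """
    if config is None:
        config = RunConfig()
    recording_path = Path(recording_path)
    written: list[Path] = []
    stage = "read"
    try:
        rec = read_edf(recording_path)
        ann = read_channel_annotation(annotation_path, rec.channel_names)
        stage = "analyze"
        result = analyze_patient(rec, ann, config)
        if model is not None:
            stage = "predict"
            result.predictions = predict_channels(model, result.features, config.classifier.threshold)
            result.metrics = score_patient(
                result.predictions, result.annotation, list(result.features.index)
            )
        if out_dir is not None:
            stage = "write"
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            stem = recording_path.stem
            container = out_dir / f"{stem}_fragility.npz"
            write_fragility_map(result.fragility_map, container)
            written += [container, container.with_suffix(".npz.json")]
            png = out_dir / f"{stem}_heatmap.png"
            plot_fragility_heatmap(result.fragility_map, png)
            written.append(png)
            feats = out_dir / f"{stem}_features.csv"
            result.features.to_csv(feats)
            written.append(feats)
            if result.predictions is not None:
                pred_csv = out_dir / f"{stem}_predictions.csv"
                pd.DataFrame(
                    {"channel": list(result.features.index), "pred_soz": result.predictions.astype(int)}
                ).to_csv(pred_csv, index=False)
                written.append(pred_csv)
                metrics_csv = out_dir / f"{stem}_metrics.csv"
                pd.DataFrame([result.metrics.as_dict()]).to_csv(metrics_csv, index=False)
                written.append(metrics_csv)
            _write_effective_config(config, out_dir)
        return result
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"patient run failed at stage {stage!r} for {recording_path.name}: {exc}") from exc


def run_cohort(
    cohort_dir: str | Path, config: RunConfig | None = None, out_dir: str | Path | None = None
) -> CohortResult:
    """Cohort file entry point.

    ``cohort_dir`` must contain ``cohort.csv`` plus, per patient,
    ``<patient_id>.edf`` and ``<patient_id>_channels.csv``.  Emits per-patient
    artifacts, the metrics table, the statistics report (JSON + CSVs) and a
    failure manifest for any patient that could not be analyzed.
    """
    if config is None:
        config = RunConfig()
    cohort_dir = Path(cohort_dir)
    cohort = read_cohort_table(cohort_dir / "cohort.csv")
    patients: dict[str, tuple[SeegRecording, ChannelAnnotation]] = {}
    read_failures: dict[str, str] = {}
    for pid in cohort.table["patient_id"]:
        try:
            rec = read_edf(cohort_dir / f"{pid}.edf")
            ann = read_channel_annotation(cohort_dir / f"{pid}_channels.csv", rec.channel_names)
            patients[pid] = (rec, ann)
        except Exception as exc:
            read_failures[pid] = f"{type(exc).__name__}: {exc}"
    if len(patients) < 2:
        raise RuntimeError(f"cohort has fewer than 2 readable patients; failures: {read_failures}")
    result = run_cohort_analysis(patients, cohort, config)
    result.failures.update(read_failures)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for pid, r in result.patients.items():
            write_fragility_map(r.fragility_map, out_dir / f"{pid}_fragility.npz")
            plot_fragility_heatmap(r.fragility_map, out_dir / f"{pid}_heatmap.png")
            pd.DataFrame(
                {"channel": list(r.features.index), "pred_soz": r.predictions.astype(int)}
            ).to_csv(out_dir / f"{pid}_predictions.csv", index=False)
        result.metrics.to_csv(out_dir / "metrics.csv", index=False)
        result.pairs.to_csv(out_dir / "fragility_pairs.csv", index=False)
        if result.engel_summary is not None:
            result.engel_summary.to_csv(out_dir / "engel_summary.csv", index=False)
        if result.outcome_model is not None:
            result.outcome_model.table.to_csv(out_dir / "outcome_model.csv")
            plot_forest(result.outcome_model, out_dir / "outcome_forest.png")
        (out_dir / "stats_report.json").write_text(json.dumps(cohort_report(result), indent=1))
        if result.failures:
            (out_dir / "failure_manifest.json").write_text(json.dumps(result.failures, indent=1))
        _write_effective_config(config, out_dir)
    return result


def cohort_report(result: CohortResult) -> dict:
    """JSON-serializable summary of all cohort statistics."""
    report: dict = {"n_patients": len(result.patients), "failures": result.failures}
    report["paired_tests"] = {}
    for group, test in result.paired_tests.items():
        if test is None:
            report["paired_tests"][group] = {"error": result.paired_test_errors.get(group)}
        else:
            report["paired_tests"][group] = {
                "n_pairs": test.n_pairs,
                "t_statistic": test.t_statistic,
                "p_value": test.p_value,
                "mean_difference": test.mean_difference,
            }
    if result.outcome_model is not None:
        report["outcome_model"] = {
            str(k): {
                "coef": float(row["coef"]),
                "se": float(row["se"]),
                "ci_lo": float(row["ci_lo"]),
                "ci_hi": float(row["ci_hi"]),
                "p_value": float(row["p_value"]),
            }
            for k, row in result.outcome_model.table.iterrows()
        }
        report["outcome_model_separation"] = result.outcome_model.separation
    else:
        report["outcome_model"] = {"error": result.outcome_model_error}
    by_group = result.metrics.merge(
        result.cohort.table[["patient_id", "engel"]], on="patient_id"
    )
    for label, mask in (("success", by_group["engel"] == 1), ("failure", by_group["engel"] > 1)):
        sub = by_group.loc[mask]
        report[f"{label}_group_means"] = {
            c: (float(sub[c].mean()) if sub[c].notna().any() else None)
            for c in ("precision_soze", "recall_soze", "precision_sozc", "recall_sozc")
        }
    return report
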