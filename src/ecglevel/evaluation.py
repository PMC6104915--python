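"""Evaluation protocol: cohort split, triplicate aggregation, metrics, reports.

Follows the source protocol: models are fit on the training subjects only;
on the held-out subjects each replicate ECG is predicted separately and the
median of the triplicate predictions is the estimate for that blood draw
(aggregate first, correlate second).  Reported metrics are the Pearson
correlation between draw-level predictions and measured levels, and the
mean +/- SD of the absolute error in pg/ml.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Cohort
from .linear import LinearModelArtifact, predict_linear

#: Test-set size per sex for a full-size cohort (the last six male and six
#: female subjects in study-id order).
FULL_TEST_PER_SEX = 6
FULL_COHORT_PER_SEX = 21


@dataclass
class EvaluationReport:
    """Predicted-vs-actual pairs and summary metrics for each model."""

    pairs: pd.DataFrame          # subject_id, timepoint_h, model, predicted, actual
    metrics: dict                # per model: pearson_r, error_mean, error_sd, n_pairs
    qtc_table: pd.DataFrame      # per subject: baseline QTc, QTc at peak level
    timecourse: pd.DataFrame     # per subject/timepoint: actual + per-model predictions
    metadata: dict = field(default_factory=dict)


def split_cohort(cohort: Cohort) -> tuple[list[str], list[str]]:
    """Train/test subject split by study-id order within each sex.

    The test set is the last six male and last six female subjects by id
    for full-size cohorts; smaller synthetic cohorts use the proportional
    rule ceil(n_sex / 7) per sex (recorded in report metadata).  Train and
    test are disjoint by construction.
    """
    test: list[str] = []
    train: list[str] = []
    for sex in ("M", "F"):
        ids = sorted(cohort.subjects.loc[cohort.subjects["sex"] == sex,
                                         "subject_id"])
        if len(ids) < 2:
            raise ValueError(f"need at least 2 subjects of sex {sex!r} to split")
        k = FULL_TEST_PER_SEX if len(ids) >= FULL_COHORT_PER_SEX \
            else math.ceil(len(ids) / 7)
        test += ids[-k:]
        train += ids[:-k]
    assert not set(train) & set(test)
    return sorted(train), sorted(test)


def aggregate_triplicates(per_replicate_predictions) -> float | None:
    """Median of the three replicate predictions for one blood draw.

    Missing replicates (NaN/None) are dropped; the median of the remainder
    is returned.  With no usable replicate the draw is missing (``None``).
    """
    vals = list(per_replicate_predictions)
    if len(vals) != 3:
        raise ValueError(f"expected exactly 3 replicate predictions, got {len(vals)}")
    usable = [float(v) for v in vals if v is not None and np.isfinite(v)]
    if not usable:
        return None
    return float(np.median(usable))


def pearson_r(predicted, actual) -> float:
    """Product-moment correlation between two equal-length sequences."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(actual, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length sequences of at least 3 values")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("correlation undefined: zero variance input")
    return float(np.corrcoef(x, y)[0, 1])


def error_stats(predicted, actual) -> tuple[float, float]:
    """Mean and sample SD (ddof=1) of the absolute error |pred - actual|."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(actual, dtype=float)
    if x.shape != y.shape:
        raise ValueError("predicted and actual must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    err = np.abs(x - y)
    return float(err.mean()), float(err.std(ddof=1))


def _delin_lookup(delineations: pd.DataFrame) -> dict:
    out = {}
    for _, row in delineations.iterrows():
        out[(row.subject_id, row.timepoint_h, int(row.replicate_index))] = row
    return out


def _check_leakage(artifact, cohort: Cohort, model_id: str) -> None:
    trained_on = set(getattr(artifact, "train_subject_ids", []) or [])
    overlap = trained_on & set(cohort.subject_ids)
    if overlap:
        raise ValueError(
            f"leakage: {model_id} model was trained on test subjects {sorted(overlap)}"
        )


def build_report(cohort: Cohort, delineations: pd.DataFrame,
                 linear_artifact: LinearModelArtifact | None = None,
                 deep_artifact=None, clip_negative: bool = False,
                 metadata: dict | None = None) -> EvaluationReport:
    """Evaluate the available models on (test) ``cohort``.

    ``deep_artifact`` needs a ``predict_record(record) -> pg/ml`` method and
    a ``train_subject_ids`` attribute; both artifacts are checked against
    the cohort for train/test leakage.  Draws where every replicate fails
    are excluded and counted in the model's diagnostics.
    """
    lookup = _delin_lookup(delineations)
    models: dict[str, object] = {}
    if linear_artifact is not None:
        _check_leakage(linear_artifact, cohort, "linear")
        models["linear_qtc"] = linear_artifact
    if deep_artifact is not None:
        _check_leakage(deep_artifact, cohort, "deep")
        models["deep"] = deep_artifact

    pair_rows, tc_rows = [], []
    diagnostics: dict[str, list] = {m: [] for m in models}
    for s in cohort.samples:
        tc = {"subject_id": s.subject_id, "timepoint_h": s.timepoint_h,
              "actual_pg_ml": s.concentration_pg_ml}
        for model_id, artifact in models.items():
            reps = []
            for rec in s.replicates:
                if model_id == "linear_qtc":
                    row = lookup.get((s.subject_id, s.timepoint_h,
                                      rec.replicate_index))
                    if row is None or not np.isfinite(row.qtc_bazett_ms):
                        reps.append(np.nan)
                    else:
                        reps.append(predict_linear(artifact, row.qtc_bazett_ms,
                                                   clip_negative=clip_negative))
                else:
                    reps.append(float(artifact.predict_record(rec)))
            agg = aggregate_triplicates(reps)
            tc[f"predicted_{model_id}_pg_ml"] = np.nan if agg is None else agg
            if agg is None:
                diagnostics[model_id].append(
                    f"draw ({s.subject_id}, {s.timepoint_h}) excluded: "
                    "no usable replicate")
                continue
            pair_rows.append({"subject_id": s.subject_id,
                              "timepoint_h": s.timepoint_h, "model": model_id,
                              "predicted_pg_ml": agg,
                              "actual_pg_ml": s.concentration_pg_ml})
        tc_rows.append(tc)

    pairs = pd.DataFrame(pair_rows, columns=["subject_id", "timepoint_h",
                                             "model", "predicted_pg_ml",
                                             "actual_pg_ml"])
    metrics = {}
    for model_id in models:
        sub = pairs[pairs["model"] == model_id]
        entry: dict = {"n_pairs": int(len(sub)),
                       "excluded_draws": diagnostics[model_id]}
        try:
            entry["pearson_r"] = pearson_r(sub["predicted_pg_ml"],
                                           sub["actual_pg_ml"])
        except ValueError as exc:
            entry["pearson_r"] = None
            entry["pearson_r_diagnostic"] = str(exc)
        if len(sub) >= 2:
            mean, sd = error_stats(sub["predicted_pg_ml"], sub["actual_pg_ml"])
            entry["error_mean_pg_ml"], entry["error_sd_pg_ml"] = mean, sd
        metrics[model_id] = entry

    return EvaluationReport(
        pairs=pairs, metrics=metrics,
        qtc_table=_qtc_table(cohort, delineations),
        timecourse=pd.DataFrame(tc_rows),
        metadata=dict(metadata or {}, models=sorted(models),
                      split_rule="last-6-per-sex or ceil(n/7) scaled"),
    )


def _qtc_table(cohort: Cohort, delineations: pd.DataFrame) -> pd.DataFrame:
    """Per-subject Bazett QTc at the predose draw and at peak measured level."""
    draw = (delineations.groupby(["subject_id", "timepoint_h"])["qtc_bazett_ms"]
            .median().reset_index())
    rows = []
    for subject_id in cohort.subject_ids:
        subj_samples = cohort.samples_for(subject_id)
        sub = draw[draw["subject_id"] == subject_id]

        def qtc_at(tp: float) -> float:
            hit = sub[np.isclose(sub["timepoint_h"], tp)]
            return float(hit["qtc_bazett_ms"].iloc[0]) if len(hit) else np.nan

        predose = [s for s in subj_samples if s.timepoint_h <= 0]
        baseline = qtc_at(min(s.timepoint_h for s in predose)) if predose else np.nan
        concs = {s.timepoint_h: s.concentration_pg_ml for s in subj_samples}
        peak_conc = max(concs.values()) if concs else 0.0
        flags = []
        if peak_conc <= 0:
            peak = np.nan
            flags.append("no positive concentration; peak draw undefined")
        else:
            peak_tp = max(concs, key=concs.get)
            peak = qtc_at(peak_tp)
        rows.append({"subject_id": subject_id, "baseline_qtc_ms": baseline,
                     "peak_qtc_ms": peak,
                     "peak_concentration_pg_ml": peak_conc,
                     "flags": ";".join(flags)})
    return pd.DataFrame(rows)


def write_report(report: EvaluationReport, outdir, plots: bool = True) -> Path:
    """Write report.json, the CSV tables and the standard figures."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(
        json.dumps({"metrics": report.metrics, "metadata": report.metadata},
                   indent=2, default=str) + "\n")
    report.pairs.to_csv(outdir / "pairs.csv", index=False)
    report.qtc_table.to_csv(outdir / "qtc_table.csv", index=False)
    report.timecourse.to_csv(outdir / "timecourse.csv", index=False)
    if plots:
        _write_plots(report, outdir)
    return outdir


_MODEL_COLORS = {"deep": "tab:blue", "linear_qtc": "tab:orange"}


def _write_plots(report: EvaluationReport, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    models = [m for m in report.metrics]
    if models:
        fig, axes = plt.subplots(1, len(models), figsize=(5 * len(models), 4),
                                 squeeze=False)
        for ax, model_id in zip(axes[0], models):
            sub = report.pairs[report.pairs["model"] == model_id]
            ax.scatter(sub["actual_pg_ml"], sub["predicted_pg_ml"], s=12,
                       color=_MODEL_COLORS.get(model_id, "k"), alpha=0.7)
            lim = max(1.0, sub[["actual_pg_ml", "predicted_pg_ml"]].max().max())
            ax.plot([0, lim], [0, lim], "k--", lw=0.8)
            r = report.metrics[model_id].get("pearson_r")
            ax.set_title(f"{model_id} (r = {r:.2f})" if r is not None else model_id)
            ax.set_xlabel("measured level (pg/ml)")
            ax.set_ylabel("predicted level (pg/ml)")
        fig.tight_layout()
        fig.savefig(outdir / "scatter.png", dpi=120)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(6, 4))
        for model_id in models:
            sub = report.pairs[report.pairs["model"] == model_id]
            err = np.abs(sub["predicted_pg_ml"] - sub["actual_pg_ml"])
            ax.hist(err, bins=20, alpha=0.5, label=model_id,
                    color=_MODEL_COLORS.get(model_id))
        ax.set_xlabel("|predicted - measured| (pg/ml)")
        ax.set_ylabel("draws")
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / "error_hist.png", dpi=120)
        plt.close(fig)

    subjects = report.timecourse["subject_id"].unique()
    if len(subjects):
        ncol = min(4, len(subjects))
        nrow = int(np.ceil(len(subjects) / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.4 * nrow),
                                 squeeze=False, sharex=True)
        for ax, subject_id in zip(axes.ravel(), subjects):
            sub = report.timecourse[report.timecourse["subject_id"] == subject_id]
            sub = sub.sort_values("timepoint_h")
            ax.plot(sub["timepoint_h"], sub["actual_pg_ml"], "r-", lw=1.2,
                    label="measured")
            for model_id in models:
                col = f"predicted_{model_id}_pg_ml"
                if col in sub:
                    ax.plot(sub["timepoint_h"], sub[col], lw=1.0,
                            color=_MODEL_COLORS.get(model_id), label=model_id)
            ax.set_title(subject_id, fontsize=8)
        for ax in axes.ravel()[len(subjects):]:
            ax.axis("off")
        axes.ravel()[0].legend(fontsize=6)
        fig.supxlabel("time after dose (h)")
        fig.supylabel("dofetilide (pg/ml)")
        fig.tight_layout()
        fig.savefig(outdir / "timecourse.png", dpi=120)
        plt.close(fig)
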