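"""Evaluation protocol: split rule, triplicate medians, metrics, report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ecglevel.cohort_gen import generate_cohort
from ecglevel.delineation import delineate_cohort
from ecglevel.evaluation import (aggregate_triplicates, build_report,
                                 error_stats, pearson_r, split_cohort,
                                 write_report)
from ecglevel.io import Cohort
from ecglevel.linear import LinearModelArtifact, fit_linear


def _subjects_only(n_m: int, n_f: int) -> Cohort:
    rows = [{"subject_id": f"S{i + 1:03d}", "sex": "M" if i < n_m else "F",
             "arm": "dofetilide", "protocol": "A"} for i in range(n_m + n_f)]
    return Cohort(samples=[], subjects=pd.DataFrame(rows))


def test_full_cohort_splits_thirty_twelve():
    cohort = _subjects_only(21, 21)
    train, test = split_cohort(cohort)
    assert len(train) == 30 and len(test) == 12
    # the last six ids of each sex are the test set
    males = sorted(s for s in cohort.subject_ids if s <= "S021")
    females = sorted(s for s in cohort.subject_ids if s > "S021")
    assert set(test) == set(males[-6:] + females[-6:])


def test_small_cohort_uses_scaled_rule():
    train, test = split_cohort(_subjects_only(2, 2))
    assert len(train) == 2 and len(test) == 2


def test_split_requires_two_subjects_per_sex():
    with pytest.raises(ValueError):
        split_cohort(_subjects_only(5, 1))


@settings(deadline=None, max_examples=30)
@given(n_m=st.integers(2, 40), n_f=st.integers(2, 40))
def test_split_is_disjoint_and_exhaustive(n_m, n_f):
    cohort = _subjects_only(n_m, n_f)
    train, test = split_cohort(cohort)
    assert not set(train) & set(test)
    assert sorted(train + test) == sorted(cohort.subject_ids)


def test_triplicate_median_examples():
    assert aggregate_triplicates([100.0, 900.0, 2000.0]) == 900.0
    assert aggregate_triplicates([500.0, 500.0, 500.0]) == 500.0
    assert aggregate_triplicates([np.nan, 300.0, 100.0]) == 200.0
    assert aggregate_triplicates([np.nan] * 3) is None
    with pytest.raises(ValueError):
        aggregate_triplicates([1.0, 2.0])


@settings(deadline=None, max_examples=50)
@given(st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=3))
def test_triplicate_median_is_permutation_symmetric(vals):
    base = aggregate_triplicates(vals)
    assert aggregate_triplicates(vals[::-1]) == base
    assert aggregate_triplicates([vals[1], vals[2], vals[0]]) == base


def test_pearson_r_known_values():
    x = np.arange(1.0, 11.0)
    assert pearson_r(2 * x + 1, x) == pytest.approx(1.0)
    assert pearson_r(-x, x) == pytest.approx(-1.0)
    # hand-computed from the covariance definition
    assert pearson_r([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)
    with pytest.raises(ValueError):
        pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        pearson_r([1.0, 2.0], [1.0, 2.0])


def test_error_stats_closed_form_and_definitional_oracle():
    assert error_stats([1.0, 2.0], [1.0, 2.0]) == (0.0, 0.0)
    mean, sd = error_stats([100.0, 300.0], [0.0, 0.0])
    assert mean == pytest.approx(200.0)
    assert sd == pytest.approx(np.sqrt(((100 - 200) ** 2 + (300 - 200) ** 2) / 1))
    rng = np.random.default_rng(3)
    p, a = rng.normal(size=50), rng.normal(size=50)
    mean, sd = error_stats(p, a)
    err = np.abs(p - a)
    assert mean == pytest.approx(err.sum() / 50)
    assert sd == pytest.approx(np.sqrt(np.sum((err - err.mean()) ** 2) / 49))
    with pytest.raises(ValueError):
        error_stats([1.0], [1.0, 2.0])


@pytest.fixture(scope="module")
def evaluated(small_cohort):
    cohort, truth = small_cohort
    delin = delineate_cohort(cohort)
    train_ids, test_ids = split_cohort(cohort)
    conc = {(s.subject_id, s.timepoint_h): s.concentration_pg_ml
            for s in cohort.samples}
    pairs = [(r.qtc_bazett_ms, conc[(r.subject_id, r.timepoint_h)])
             for _, r in delin.iterrows() if r.subject_id in train_ids]
    linear = fit_linear(pairs, train_subject_ids=train_ids)
    test = cohort.subset(test_ids)
    report = build_report(test, delin[delin.subject_id.isin(test_ids)],
                          linear_artifact=linear)
    return cohort, delin, linear, test_ids, report


def test_report_pairs_accounting(evaluated):
    cohort, _, _, test_ids, report = evaluated
    n_draws = sum(1 for s in cohort.samples if s.subject_id in test_ids)
    sub = report.pairs[report.pairs.model == "linear_qtc"]
    excluded = len(report.metrics["linear_qtc"]["excluded_draws"])
    assert len(sub) == n_draws - excluded


def test_report_correlates_draw_level_medians(evaluated):
    """The reported r must come from triplicate-median (draw-level) values,
    matching the aggregate-then-correlate protocol."""
    _, _, _, _, report = evaluated
    sub = report.pairs[report.pairs.model == "linear_qtc"]
    assert report.metrics["linear_qtc"]["pearson_r"] == pytest.approx(
        pearson_r(sub.predicted_pg_ml, sub.actual_pg_ml))
    # one pair per (subject, timepoint): medians, not replicates
    assert not sub.duplicated(["subject_id", "timepoint_h"]).any()


def test_leakage_guard_rejects_contaminated_artifact(evaluated):
    cohort, delin, _, test_ids, _ = evaluated
    test = cohort.subset(test_ids)
    tainted = fit_linear([(380.0, 0.0), (420.0, 1000.0), (460.0, 2000.0)],
                         train_subject_ids=list(test_ids))
    with pytest.raises(ValueError, match="leakage"):
        build_report(test, delin[delin.subject_id.isin(test_ids)],
                     linear_artifact=tainted)


def test_qtc_table_has_one_row_per_subject_with_baseline_and_peak(evaluated):
    _, _, _, test_ids, report = evaluated
    assert sorted(report.qtc_table.subject_id) == sorted(test_ids)
    assert report.qtc_table.baseline_qtc_ms.notna().all()
    assert report.qtc_table.peak_qtc_ms.notna().all()
    # dofetilide prolongs repolarization: peak QTc above baseline
    assert (report.qtc_table.peak_qtc_ms
            > report.qtc_table.baseline_qtc_ms).all()


def test_placebo_subject_peak_flagged_not_fabricated(tmp_path):
    cohort, _ = generate_cohort(2, protocol="A", master_seed=3,
                                arm_fractions={"placebo": 1.0})
    delin = delineate_cohort(cohort)
    report = build_report(cohort, delin)
    assert report.qtc_table.peak_qtc_ms.isna().all()
    assert report.qtc_table["flags"].str.contains("undefined").all()
    out = write_report(report, tmp_path / "rep", plots=False)
    assert (out / "report.json").exists() and (out / "qtc_table.csv").exists()
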