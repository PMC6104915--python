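"""R-peak detection, tangent-method QT, and rate corrections."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecglevel import delineation as dl
from ecglevel.cohort_gen import SubjectProfile
from ecglevel.errors import DelineationFailure, UndetectableRhythmError
from ecglevel.waveform import beat_r_times_ms, synthesize_ecg


@pytest.fixture(scope="module")
def record_hr60(noise_free_profile):
    return synthesize_ecg(noise_free_profile, 420, 1000, 0.0, 1, seed=60)


def test_r_peaks_found_at_generated_beat_positions(record_hr60):
    peaks = dl.detect_r_peaks(record_hr60.signal[1], 500.0)
    truth_ms = beat_r_times_ms(1000.0,
                               np.random.default_rng(60).uniform(0, 2 * np.pi))
    assert 9 <= len(peaks) <= 11
    matched = truth_ms[:len(peaks)]
    assert np.all(np.abs(peaks * 2.0 - matched) <= 10.0)


def test_peak_count_scales_with_heart_rate(noise_free_profile, record_hr60):
    fast = synthesize_ecg(noise_free_profile, 360, 500, 0.0, 1, seed=61)
    n_slow = len(dl.detect_r_peaks(record_hr60.signal[1], 500.0))
    n_fast = len(dl.detect_r_peaks(fast.signal[1], 500.0))
    assert abs(n_fast / n_slow - 2.0) <= 0.4


def test_flat_signal_is_undetectable():
    with pytest.raises(UndetectableRhythmError):
        dl.detect_r_peaks(np.zeros(5000), 500.0)


@pytest.mark.parametrize("qt,rr,expected", [
    (400.0, 1000.0, 400.0),
    (400.0, 640.0, 500.0),
    (350.0, 250.0, 700.0),
])
def test_bazett_exact_values(qt, rr, expected):
    assert dl.bazett(qt, rr) == pytest.approx(expected)


@pytest.mark.parametrize("qt,hr,expected", [
    (400.0, 60.0, 400.0),
    (400.0, 100.0, 470.0),
    (450.0, 40.0, 415.0),
])
def test_hodges_exact_values(qt, hr, expected):
    assert dl.hodges(qt, hr) == pytest.approx(expected)


@settings(deadline=None, max_examples=50)
@given(qt=st.floats(200, 600))
def test_corrections_agree_at_60_bpm(qt):
    assert dl.bazett(qt, 1000.0) == pytest.approx(dl.hodges(qt, 60.0))


@pytest.mark.parametrize("bad", [(0, 1000), (400, 0), (-5, 900)])
def test_corrections_reject_non_positive_inputs(bad):
    with pytest.raises(ValueError):
        dl.bazett(*bad)
    with pytest.raises(ValueError):
        dl.hodges(*bad)


def test_tangent_root_of_gaussian_matches_closed_form():
    """For a Gaussian flank the steepest-descent tangent crosses the
    baseline at mu + 2*sigma; the discrete computation must land within
    one sample of that."""
    fs = 500.0
    t = np.arange(0, 1000) / fs * 1000.0  # ms
    mu, sigma, amp = 600.0, 44.0, 300.0
    x = amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)
    slope = np.gradient(x)
    peak = int(np.argmax(x))
    s_idx = peak + int(np.argmin(slope[peak:peak + 200]))
    root_ms = dl._tangent_root(s_idx, x, slope, baseline=0.0, fs_hz=fs)
    assert abs(root_ms - (mu + 2 * sigma)) <= 1000.0 / fs


def test_lead_without_t_wave_is_missing(record_hr60):
    peaks = dl.detect_r_peaks(record_hr60.signal[1], 500.0)
    lead = record_hr60.signal[1].copy()
    # erase every T wave (window from +100 ms after each R to the next P)
    for p in peaks:
        lead[p + 50:p + 350] = 0.0
    assert dl.measure_qt(lead, 500.0, peaks) is None


def test_measured_qt_within_tolerance(record_hr60):
    peaks = dl.detect_r_peaks(record_hr60.signal[1], 500.0)
    qt = dl.measure_qt(record_hr60.signal[1], 500.0, peaks)
    assert qt == pytest.approx(420.0, abs=10.0)


def test_record_fails_when_too_few_leads_delineate(record_hr60):
    rec_bad = record_hr60
    sig = rec_bad.signal.copy()
    sig[7:, :] = 0.0  # 5 leads erased leaves 7 usable: below the 8-lead floor
    from dataclasses import replace
    broken = replace(rec_bad, signal=sig)
    with pytest.raises(DelineationFailure, match="delineation failure"):
        dl.delineate_record(broken)


def test_cross_lead_aggregate_is_median(record_hr60, monkeypatch):
    forced = iter([400.0] * 6 + [410.0] * 6)

    def fake(lead_signal, fs_hz, r_peaks):
        return next(forced), 9

    monkeypatch.setattr(dl, "_measure_qt_beats", fake)
    res = dl.delineate_record(record_hr60)
    assert res.qt_ms == pytest.approx(405.0)
    assert res.n_beats_used == 9


def test_delineation_invariant_to_amplitude_scaling(record_hr60):
    """Scaling all amplitudes by a power of two changes nothing: every
    threshold and tangent construction in the pipeline is relative."""
    from dataclasses import replace
    scaled = replace(record_hr60, signal=record_hr60.signal * 4.0)
    a = dl.delineate_record(record_hr60)
    b = dl.delineate_record(scaled)
    assert a.qt_ms == b.qt_ms
    assert a.rr_ms == b.rr_ms
    assert a.qtc_bazett_ms == b.qtc_bazett_ms


def test_delineated_qtc_tracks_concentration_within_subjects(small_cohort):
    """Across a dofetilide cohort, per-subject Spearman correlation between
    Bazett QTc and true concentration is positive."""
    from scipy.stats import spearmanr
    cohort, truth = small_cohort
    delin = dl.delineate_cohort(cohort)
    merged = delin.groupby(["subject_id", "timepoint_h"]).qtc_bazett_ms.median() \
        .reset_index().merge(truth.table, on=["subject_id", "timepoint_h"])
    for subject_id, grp in merged.groupby("subject_id"):
        rho = spearmanr(grp.qtc_bazett_ms, grp.concentration_pg_ml).statistic
        assert rho > 0, subject_id
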