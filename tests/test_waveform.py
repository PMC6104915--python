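"""Synthetic 12-lead beat generator: determinism, isoelectric baseline,
landmark placement, and the generator/delineator closed loop."""

import numpy as np
import pytest

from ecglevel.cohort_gen import SubjectProfile
from ecglevel.delineation import delineate_record
from ecglevel.waveform import (FIRST_R_MS, MS_PER_SAMPLE, P_MU, P_SIGMA,
                               beat_r_times_ms, synthesize_ecg)


def test_same_arguments_and_seed_give_bit_identical_records(noise_free_profile):
    a = synthesize_ecg(noise_free_profile, 420, 937, 0.4, 1, seed=9)
    b = synthesize_ecg(noise_free_profile, 420, 937, 0.4, 1, seed=9)
    assert np.array_equal(a.signal, b.signal)
    noisy = SubjectProfile(subject_id="S", noise_uv=6.0)
    c = synthesize_ecg(noisy, 420, 937, 0.4, 1, seed=9)
    d = synthesize_ecg(noisy, 420, 937, 0.4, 1, seed=10)
    assert not np.array_equal(c.signal, d.signal)


def test_baseline_is_isoelectric_before_each_beat(noise_free_profile):
    """With no noise, the 40 ms before every beat onset is exactly 0 uV."""
    qt, rr, seed = 440, 1000, 5
    rec = synthesize_ecg(noise_free_profile, qt, rr, 0.0, 1, seed=seed)
    phase = np.random.default_rng(seed).uniform(0.0, 2.0 * np.pi)
    onsets_ms = beat_r_times_ms(rr, phase) + P_MU - 4.0 * P_SIGMA
    for onset in onsets_ms:
        lo = int(np.ceil((onset - 40.0) / MS_PER_SAMPLE))
        hi = int(np.floor(onset / MS_PER_SAMPLE))
        if lo < 0:
            continue
        assert np.all(rec.signal[:, lo:hi] == 0.0), f"onset at {onset} ms"


def test_invalid_qt_rr_combinations_rejected(noise_free_profile):
    with pytest.raises(ValueError):
        synthesize_ecg(noise_free_profile, 900, 800, 0.0, 1, seed=0)
    with pytest.raises(ValueError):
        synthesize_ecg(noise_free_profile, 350, 1600, 0.0, 1, seed=0)


@pytest.mark.parametrize("qt_ms", [360, 420, 500])
def test_delineator_recovers_generated_qt(noise_free_profile, qt_ms):
    rec = synthesize_ecg(noise_free_profile, qt_ms, 1000, 0.0, 1, seed=qt_ms)
    res = delineate_record(rec)
    assert abs(res.qt_ms - qt_ms) <= 10.0
    assert abs(res.rr_ms - 1000) <= 15.0


def test_morphology_offset_changes_t_wave_but_not_measured_qt(noise_free_profile):
    plain = synthesize_ecg(noise_free_profile, 420, 1000, 0.0, 1, seed=3)
    morphed = synthesize_ecg(noise_free_profile, 420, 1000, 0.8, 1, seed=3)
    assert not np.array_equal(plain.signal, morphed.signal)
    qt_plain = delineate_record(plain).qt_ms
    qt_morph = delineate_record(morphed).qt_ms
    # the morphology channel must be invisible to the QT measurement
    assert abs(qt_plain - qt_morph) <= 5.0


def test_duration_only_waveform_independent_of_concentration(noise_free_profile):
    """At fixed (qt, rr) and zero morphology offset the waveform is one
    fixed array: concentration has no second channel into the signal."""
    a = synthesize_ecg(noise_free_profile, 430, 950, 0.0, 1, seed=11)
    b = synthesize_ecg(noise_free_profile, 430, 950, 0.0, 1, seed=11)
    assert np.array_equal(a.signal, b.signal)


def test_beat_times_span_record_and_respect_rr():
    times = beat_r_times_ms(1000.0, phase=0.3)
    assert times[0] == FIRST_R_MS
    assert 9 <= len(times) <= 11
    rr = np.diff(times)
    assert np.all(np.abs(rr - 1000.0) <= 0.02 * 1000.0 + 1e-9)
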