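"""One-compartment oral PK and sigmoid-Emax PD against closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecglevel.cohort_gen import SubjectProfile
from ecglevel.errors import DegeneratePKError
from ecglevel.pk import (pk_concentration, qt_effect,
                         single_dose_concentration, time_of_peak)


def _profile(**kw):
    return SubjectProfile(subject_id="S", **kw)


def test_concentration_zero_at_and_before_dose():
    prof = _profile()
    assert pk_concentration(0.0, prof) == 0.0
    assert pk_concentration(-0.5, prof) == 0.0


def test_placebo_concentration_identically_zero():
    prof = _profile(arm="placebo")
    t = np.linspace(-1, 48, 200)
    assert np.all(pk_concentration(t, prof) == 0.0)


def test_time_of_peak_matches_brute_force_grid_search():
    """Closed-form t_max = ln(ka/ke)/(ka-ke) vs argmax on a 0.01 h grid."""
    prof = _profile()
    grid = np.arange(0.0, 24.0, 0.01)
    c = pk_concentration(grid, prof)
    t_grid = grid[np.argmax(c)]
    t_closed = time_of_peak(prof.ka_per_h, prof.ke_per_h)
    assert abs(t_grid - t_closed) <= 0.01


def test_multi_dose_curve_is_superposition_of_shifted_single_doses():
    prof = _profile(protocol="B", dose_times_h=(0.0, 5.0, 10.0))
    t = np.linspace(-0.5, 36.0, 400)
    total = pk_concentration(t, prof)
    oracle = sum(
        single_dose_concentration(t - td, prof.dose_ug, prof.ka_per_h,
                                  prof.ke_per_h, prof.v_over_f_scale)
        for td in prof.dose_times_h)
    assert np.allclose(total, oracle, rtol=1e-12, atol=1e-12)


def test_single_dose_has_one_interior_maximum_and_stays_nonnegative():
    prof = _profile()
    t = np.linspace(0.0, 48.0, 5000)
    c = pk_concentration(t, prof)
    assert np.all(c >= 0)
    d = np.diff(c)
    sign_changes = np.sum(np.diff(np.sign(d[np.abs(d) > 1e-12])) != 0)
    assert sign_changes == 1


def test_default_scale_puts_single_dose_peak_near_2000_pg_ml():
    prof = _profile()
    peak = pk_concentration(time_of_peak(prof.ka_per_h, prof.ke_per_h), prof)
    assert 1800 <= peak <= 2200


def test_equal_rates_raise_degenerate_pk():
    with pytest.raises((DegeneratePKError, ValueError)):
        prof = _profile()
        single_dose_concentration(1.0, prof.dose_ug, 0.5, 0.5, prof.v_over_f_scale)
    with pytest.raises(ValueError):
        _profile(ka_per_h=0.5, ke_per_h=0.5)


def test_qt_effect_anchor_points():
    prof = _profile()
    assert qt_effect(0.0, prof) == 0.0
    assert qt_effect(prof.ec50_pg_ml, prof) == pytest.approx(prof.emax_ms / 2)
    near_max = qt_effect(1e6 * prof.ec50_pg_ml, prof)
    assert prof.emax_ms - near_max <= 0.001 * prof.emax_ms
    with pytest.raises(ValueError):
        qt_effect(-1.0, prof)


@settings(deadline=None, max_examples=50)
@given(c1=st.floats(0, 1e5), c2=st.floats(0, 1e5))
def test_qt_effect_monotone_and_bounded(c1, c2):
    prof = _profile()
    lo, hi = sorted((c1, c2))
    assert qt_effect(lo, prof) <= qt_effect(hi, prof) < prof.emax_ms
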