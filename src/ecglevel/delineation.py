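"""QT / RR measurement from 12-lead ECG records.

Per lead, each beat is delineated with two tangent landmarks against the
isoelectric baseline (estimated as the median of the PR segment):

* QRS onset — the steepest downslope into the Q wave, projected back to the
  baseline;
* T end — the steepest slope of the T-wave flank returning to baseline
  (classic tangent method), projected forward to the baseline.

Both constructions are invariant to any positive rescaling of the signal:
peaks, slopes and the tangent/baseline intersection all scale together.
QT is averaged over all complete beats (at least five, following the FDA
5–10 beat guidance), then aggregated across leads by the median, which is
robust to individual lead failures; at least eight leads must delineate or
the record is flagged unusable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import DelineationFailure, UndetectableRhythmError
from .io import Cohort, ECGRecord

MIN_BEATS = 5
MIN_LEADS = 8
QT_RANGE_MS = (200.0, 700.0)
HR_RANGE_BPM = (30.0, 200.0)

# analysis windows relative to the R peak (ms)
PR_BASELINE_WINDOW_MS = (-60.0, -46.0)
Q_SEARCH_WINDOW_MS = (-60.0, -6.0)
T_SEARCH_START_MS = 100.0
T_SEARCH_END_FRAC = 0.70       # of the local RR interval
T_DOWNSLOPE_SPAN_MS = 220.0
MIN_T_REL_AMPLITUDE = 0.02     # of the R amplitude, else lead has no usable T


@dataclass
class DelineationResult:
    """Per-record QT/RR measurement with rate-corrected intervals."""

    per_lead_qt_ms: list[float | None]
    rr_ms: float
    hr_bpm: float
    qt_ms: float
    qtc_bazett_ms: float
    qtc_hodges_ms: float
    n_beats_used: int
    flags: list[str] = field(default_factory=list)


def _oriented(x: np.ndarray) -> np.ndarray:
    """Flip polarity so the dominant (R) deflection is positive."""
    x = np.asarray(x, dtype=np.float64)
    return -x if abs(x.min()) > abs(x.max()) else x


def detect_r_peaks(lead_signal: np.ndarray, fs_hz: float) -> np.ndarray:
    """Locate R peaks on one lead; indices are strictly increasing.

    Detection runs on the squared first derivative (the QRS upstroke is an
    order of magnitude steeper than any T wave, so slope energy separates
    beats even when T amplitudes rival the R wave), then refines each
    detection to the nearby apex of the raw deflection.  All thresholds are
    relative, so detection is amplitude-scale free.  Raises
    :class:`UndetectableRhythmError` when fewer than two beats are found.
    """
    x = _oriented(lead_signal)
    if x.size < 2 * fs_hz:
        raise UndetectableRhythmError("signal shorter than 2 s")
    kernel = np.ones(5) / 5.0
    xs = np.convolve(x - np.median(x), kernel, mode="same")
    energy = np.gradient(xs) ** 2
    height = 0.2 * energy.max()
    if height <= 0:
        raise UndetectableRhythmError("undetectable rhythm: no dominant deflection")
    cand, _ = find_peaks(energy, height=height, distance=int(0.25 * fs_hz))
    half_qrs = _ms(fs_hz, 40.0)
    apexes: list[int] = []
    for p in cand:
        lo, hi = max(p - half_qrs, 0), min(p + half_qrs + 1, x.size)
        apex = lo + int(np.argmax(np.abs(xs[lo:hi])))
        if not apexes or apex - apexes[-1] > int(0.25 * fs_hz):
            apexes.append(apex)
    if len(apexes) < 2:
        raise UndetectableRhythmError(
            f"undetectable rhythm: found {len(apexes)} R peak(s)"
        )
    return np.asarray(apexes)


def _tangent_root(t_idx: int, x: np.ndarray, slope: np.ndarray,
                  baseline: float, fs_hz: float) -> float:
    """Time (ms) where the tangent at sample ``t_idx`` meets the baseline."""
    m = slope[t_idx]  # uV per sample
    if m == 0:
        return np.nan
    t_cross = t_idx + (baseline - x[t_idx]) / m
    return t_cross * 1000.0 / fs_hz


def _ms(fs_hz: float, ms: float) -> int:
    return int(round(ms * fs_hz / 1000.0))


def measure_qt(lead_signal: np.ndarray, fs_hz: float,
               r_peaks: np.ndarray) -> float | None:
    """Mean QT (ms) over all complete beats on one lead.

    Returns ``None`` (a lead-level missing value) when fewer than
    :data:`MIN_BEATS` beats delineate or the mean falls outside the
    physiological range.
    """
    qt, _ = _measure_qt_beats(lead_signal, fs_hz, r_peaks)
    return qt


SLOPE_SMOOTH_SAMPLES = 7  # ~14 ms; stabilizes the steepest-slope pick under noise


def _measure_qt_beats(lead_signal: np.ndarray, fs_hz: float,
                      r_peaks: np.ndarray) -> tuple[float | None, int]:
    x = _oriented(lead_signal)
    w = SLOPE_SMOOTH_SAMPLES
    x = np.convolve(x, np.ones(w) / w, mode="same")
    slope = np.gradient(x)
    r_peaks = np.asarray(r_peaks)
    rr_med = float(np.median(np.diff(r_peaks))) if len(r_peaks) > 1 else x.size
    qts = []
    for i, r in enumerate(r_peaks):
        rr_local = (r_peaks[i + 1] - r) if i + 1 < len(r_peaks) else rr_med
        t_end_limit = r + int(T_SEARCH_END_FRAC * rr_local)
        if r + _ms(fs_hz, Q_SEARCH_WINDOW_MS[0]) < 0 or t_end_limit >= x.size:
            continue  # incomplete beat at a record edge

        b_lo, b_hi = (r + _ms(fs_hz, PR_BASELINE_WINDOW_MS[0]),
                      r + _ms(fs_hz, PR_BASELINE_WINDOW_MS[1]))
        baseline = float(np.median(x[b_lo:b_hi + 1]))

        # QRS onset: steepest downslope into the Q trough, tangent to baseline
        q_lo, q_hi = (r + _ms(fs_hz, Q_SEARCH_WINDOW_MS[0]),
                      r + _ms(fs_hz, Q_SEARCH_WINDOW_MS[1]))
        q_trough = q_lo + int(np.argmin(x[q_lo:q_hi + 1]))
        d_lo = max(q_lo - _ms(fs_hz, 20.0), 0)
        if q_trough <= d_lo:
            continue
        s_idx = d_lo + int(np.argmin(slope[d_lo:q_trough + 1]))  # first minimum
        onset_ms = _tangent_root(s_idx, x, slope, baseline, fs_hz)

        # T end: largest deflection in the T window, tangent on the flank
        # returning towards baseline
        t_lo = r + _ms(fs_hz, T_SEARCH_START_MS)
        seg = x[t_lo:t_end_limit + 1] - baseline
        if seg.size < 3:
            continue
        t_peak = t_lo + int(np.argmax(np.abs(seg)))
        t_amp = x[t_peak] - baseline
        r_amp = x[r] - baseline
        if abs(t_amp) < MIN_T_REL_AMPLITUDE * abs(r_amp):
            continue  # no usable T wave on this lead
        pol = np.sign(t_amp)
        d_hi = min(t_peak + _ms(fs_hz, T_DOWNSLOPE_SPAN_MS), t_end_limit)
        if d_hi <= t_peak:
            continue
        flank = pol * slope[t_peak:d_hi + 1]
        s_idx = t_peak + int(np.argmin(flank))
        t_end_ms = _tangent_root(s_idx, x, slope, baseline, fs_hz)

        qt_ms = t_end_ms - onset_ms
        if np.isfinite(qt_ms) and QT_RANGE_MS[0] <= qt_ms <= QT_RANGE_MS[1]:
            qts.append(qt_ms)

    if len(qts) < MIN_BEATS:
        return None, len(qts)
    mean_qt = float(np.mean(qts))
    if not (QT_RANGE_MS[0] <= mean_qt <= QT_RANGE_MS[1]):
        return None, len(qts)
    return mean_qt, len(qts)


def bazett(qt_ms: float, rr_ms: float) -> float:
    """Bazett-corrected QT: QT / sqrt(RR in seconds)."""
    if qt_ms <= 0 or rr_ms <= 0:
        raise ValueError("qt_ms and rr_ms must be positive")
    return qt_ms / np.sqrt(rr_ms / 1000.0)


def hodges(qt_ms: float, hr_bpm: float) -> float:
    """Hodges-corrected QT: QT + 1.75 * (HR - 60)."""
    if qt_ms <= 0 or hr_bpm <= 0:
        raise ValueError("qt_ms and hr_bpm must be positive")
    return qt_ms + 1.75 * (hr_bpm - 60.0)


def delineate_record(record: ECGRecord) -> DelineationResult:
    """Measure RR, HR, QT and both QTc corrections for one record.

    R peaks are detected on the most reliable lead (lead II first, then by
    peak amplitude); QT is measured on every lead against those shared beat
    positions and aggregated by the cross-lead median.
    """
    fs = record.sampling_rate_hz
    flags: list[str] = []

    order = [1] + [i for i in np.argsort(
        -np.max(np.abs(record.signal), axis=1)) if i != 1]
    r_peaks = None
    for lead_idx in order:
        try:
            r_peaks = detect_r_peaks(record.signal[lead_idx], fs)
            break
        except UndetectableRhythmError:
            continue
    if r_peaks is None:
        raise DelineationFailure("delineation failure: no lead with detectable rhythm")

    rr_ms = float(np.mean(np.diff(r_peaks))) * 1000.0 / fs
    hr_bpm = 60000.0 / rr_ms
    if not (HR_RANGE_BPM[0] <= hr_bpm <= HR_RANGE_BPM[1]):
        flags.append(f"heart rate {hr_bpm:.0f} bpm outside {HR_RANGE_BPM}")

    per_lead: list[float | None] = []
    n_beats: list[int] = []
    for lead_idx in range(12):
        qt, n = _measure_qt_beats(record.signal[lead_idx], fs, r_peaks)
        per_lead.append(qt)
        if qt is not None:
            n_beats.append(n)

    available = [q for q in per_lead if q is not None]
    if len(available) < MIN_LEADS:
        raise DelineationFailure(
            f"delineation failure: only {len(available)} of 12 leads usable "
            f"(need {MIN_LEADS})",
            diagnostics={record.lead_names[i]: per_lead[i] for i in range(12)},
        )
    qt_ms = float(np.median(available))
    n_used = int(np.median(n_beats))
    if n_used < MIN_BEATS:
        flags.append(f"only {n_used} beats used")
    return DelineationResult(
        per_lead_qt_ms=per_lead,
        rr_ms=rr_ms,
        hr_bpm=hr_bpm,
        qt_ms=qt_ms,
        qtc_bazett_ms=float(bazett(qt_ms, rr_ms)),
        qtc_hodges_ms=float(hodges(qt_ms, hr_bpm)),
        n_beats_used=n_used,
        flags=flags,
    )


def delineate_cohort(cohort: Cohort) -> pd.DataFrame:
    """Delineate every replicate record; one row per (subject, timepoint, replicate).

    Records that fail delineation produce NaN measurements with a flag
    rather than aborting the batch.
    """
    rows = []
    for s in cohort.samples:
        for rec in s.replicates:
            base = {"subject_id": s.subject_id, "timepoint_h": s.timepoint_h,
                    "replicate_index": rec.replicate_index}
            try:
                res = delineate_record(rec)
                rows.append({**base, "qt_ms": res.qt_ms, "rr_ms": res.rr_ms,
                             "hr_bpm": res.hr_bpm,
                             "qtc_bazett_ms": res.qtc_bazett_ms,
                             "qtc_hodges_ms": res.qtc_hodges_ms,
                             "n_beats_used": res.n_beats_used,
                             "flags": ";".join(res.flags)})
            except DelineationFailure as exc:
                rows.append({**base, "qt_ms": np.nan, "rr_ms": np.nan,
                             "hr_bpm": np.nan, "qtc_bazett_ms": np.nan,
                             "qtc_hodges_ms": np.nan, "n_beats_used": 0,
                             "flags": str(exc)})
    return pd.DataFrame(rows)
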