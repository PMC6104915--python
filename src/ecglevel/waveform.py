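"""Analytic 12-lead ECG beat synthesis.

Each beat is a sum of Gaussian deflections (P, Q, R, S and an asymmetric T)
sharing one temporal profile across leads, scaled by lead-specific amplitude
coefficients.  Components are truncated at +/- 4 sigma so the inter-beat
baseline is exactly isoelectric (0 uV) in the noise-free case.

Two landmarks define the true QT interval analytically, mirroring how the
delineator measures it on real tracings:

* QRS onset: tangent projection of the steepest Q downslope onto the
  baseline.  For a Gaussian flank ``a*exp(-(t-mu)^2 / 2 sigma^2)`` the
  steepest point sits at ``mu - sigma`` and its tangent meets the baseline
  at ``mu - 2 sigma`` regardless of amplitude.
* T end: tangent projection of the steepest T downslope, which for the
  (right) Gaussian flank lands at ``mu_T + 2 sigma_right``.

The synthesizer places the T-wave centre so that the tangent T end falls
exactly ``qt_ms`` after the tangent QRS onset.  T-wave morphology
(amplitude and left/right asymmetry) is modulated by a concentration-coupled
offset that leaves both landmarks, and hence the QT interval, untouched —
this is the information channel available to a waveform model but invisible
to any QT-only model.
"""

from __future__ import annotations

import numpy as np

from .io import ECGRecord, RECORD_SAMPLES, SAMPLING_RATE_HZ, STANDARD_LEADS

MS_PER_SAMPLE = 1000.0 / SAMPLING_RATE_HZ  # 2 ms

# Component timing relative to the R-wave centre (ms).
P_MU, P_SIGMA = -150.0, 22.0
Q_MU, Q_SIGMA = -26.0, 5.0
R_MU, R_SIGMA = 0.0, 7.0
S_MU, S_SIGMA = 24.0, 6.0

#: Analytic QRS onset relative to the R centre: tangent root of the Q flank.
QRS_ONSET_MS = Q_MU - 2.0 * Q_SIGMA  # -36 ms

# T-wave width grows mildly with QT; the right flank fixes the tangent end.
T_SIGMA_RIGHT_BASE = 30.0
T_SIGMA_RIGHT_PER_QT = 0.025
T_ASYMMETRY_BASE = 1.15        # sigma_left / sigma_right at zero morphology
T_AMP_GAIN = 0.35              # fractional T-amplitude rise per unit offset
T_ASYM_GAIN = 0.25             # asymmetry-ratio rise per unit offset

#: Per-lead amplitude coefficients (uV) for [P, Q, R, S, T], ordered as
#: :data:`STANDARD_LEADS`.  Values give every lead a dominant R deflection
#: and a concordant T wave (aVR inverted), adequate for healthy sinus beats.
LEAD_AMPLITUDES_UV = np.array([
    #  P     Q      R      S      T
    [ 60.0, -40.0,  700.0, -120.0, 250.0],   # I
    [ 90.0, -50.0, 1000.0, -150.0, 350.0],   # II
    [ 40.0, -30.0,  400.0,  -80.0, 150.0],   # III
    [-75.0,  45.0, -850.0,  135.0, -300.0],  # aVR
    [ 25.0, -25.0,  320.0,  -70.0, 120.0],   # aVL
    [ 65.0, -40.0,  700.0, -110.0, 250.0],   # aVF
    [ 30.0, -30.0,  420.0, -200.0, 180.0],   # V1
    [ 40.0, -35.0,  620.0, -230.0, 400.0],   # V2
    [ 50.0, -40.0,  820.0, -200.0, 450.0],   # V3
    [ 60.0, -45.0, 1000.0, -180.0, 420.0],   # V4
    [ 60.0, -45.0,  900.0, -150.0, 380.0],   # V5
    [ 55.0, -40.0,  750.0, -130.0, 320.0],   # V6
])
assert LEAD_AMPLITUDES_UV.shape == (len(STANDARD_LEADS), 5)

RR_MODULATION = 0.02  # +/- fractional sinusoidal RR variation within a record
FIRST_R_MS = 260.0    # leaves room for the first beat's P wave


def t_sigma_right(qt_ms: float) -> float:
    return T_SIGMA_RIGHT_BASE + T_SIGMA_RIGHT_PER_QT * qt_ms


def t_wave_centre(qt_ms: float) -> float:
    """T-wave Gaussian centre (ms relative to R) for a target QT."""
    return qt_ms + QRS_ONSET_MS - 2.0 * t_sigma_right(qt_ms)


def beat_r_times_ms(rr_ms: float, phase: float, duration_ms: float = 10000.0,
                    modulation: float = RR_MODULATION) -> np.ndarray:
    """R-peak times with a small sinusoidal RR modulation (non-degenerate HR)."""
    times = [FIRST_R_MS]
    k = 0
    while True:
        nxt = times[-1] + rr_ms * (1.0 + modulation * np.sin(2.0 * np.pi * k / 8.0 + phase))
        if nxt > duration_ms - 1.0:
            break
        times.append(nxt)
        k += 1
    return np.asarray(times)


def _add_gaussian(signal: np.ndarray, amps: np.ndarray, centre_ms: float,
                  sigma_left: float, sigma_right: float) -> None:
    """Accumulate a (possibly asymmetric) Gaussian deflection, truncated at 4 sigma."""
    lo = int(np.ceil((centre_ms - 4.0 * sigma_left) / MS_PER_SAMPLE))
    hi = int(np.floor((centre_ms + 4.0 * sigma_right) / MS_PER_SAMPLE))
    lo, hi = max(lo, 0), min(hi, signal.shape[1] - 1)
    if hi < lo:
        return
    t = np.arange(lo, hi + 1) * MS_PER_SAMPLE
    sigma = np.where(t < centre_ms, sigma_left, sigma_right)
    shape = np.exp(-0.5 * ((t - centre_ms) / sigma) ** 2)
    signal[:, lo:hi + 1] += amps[:, None] * shape[None, :]


def synthesize_ecg(profile, qt_ms: float, rr_ms: float,
                   morphology_offset: float = 0.0, replicate_index: int = 1,
                   seed: int = 0) -> ECGRecord:
    """Render a 10-s, 12-lead, 500-Hz record with the requested QT and RR.

    ``profile`` supplies ``subject_id``, ``noise_uv`` (additive white noise
    scale, uV) and ``t_amp_scale`` (per-subject baseline T-amplitude factor).
    ``morphology_offset`` modulates T amplitude and left/right asymmetry
    without moving the tangent landmarks.  Deterministic given all arguments.
    """
    if not (300.0 <= qt_ms < rr_ms):
        raise ValueError(f"need 300 <= qt_ms < rr_ms, got qt={qt_ms}, rr={rr_ms}")
    if not (400.0 <= rr_ms <= 1500.0):
        raise ValueError(f"rr_ms must lie in [400, 1500], got {rr_ms}")
    if morphology_offset < 0:
        raise ValueError("morphology_offset must be non-negative")

    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    noise_uv = float(getattr(profile, "noise_uv", 0.0))
    t_amp_scale = float(getattr(profile, "t_amp_scale", 1.0))

    sig = np.zeros((12, RECORD_SAMPLES), dtype=np.float64)
    sig_r = t_sigma_right(qt_ms)
    sig_l = sig_r * (T_ASYMMETRY_BASE + T_ASYM_GAIN * morphology_offset)
    t_centre = t_wave_centre(qt_ms)
    t_amps = (LEAD_AMPLITUDES_UV[:, 4] * t_amp_scale
              * (1.0 + T_AMP_GAIN * morphology_offset))

    for r_ms in beat_r_times_ms(rr_ms, phase):
        _add_gaussian(sig, LEAD_AMPLITUDES_UV[:, 0], r_ms + P_MU, P_SIGMA, P_SIGMA)
        _add_gaussian(sig, LEAD_AMPLITUDES_UV[:, 1], r_ms + Q_MU, Q_SIGMA, Q_SIGMA)
        _add_gaussian(sig, LEAD_AMPLITUDES_UV[:, 2], r_ms + R_MU, R_SIGMA, R_SIGMA)
        _add_gaussian(sig, LEAD_AMPLITUDES_UV[:, 3], r_ms + S_MU, S_SIGMA, S_SIGMA)
        _add_gaussian(sig, t_amps, r_ms + t_centre, sig_l, sig_r)

    if noise_uv > 0:
        sig += rng.normal(0.0, noise_uv, size=sig.shape)

    return ECGRecord(
        signal=sig.astype(np.float32),
        subject_id=getattr(profile, "subject_id", ""),
        timepoint_h=0.0,
        replicate_index=replicate_index,
    )
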