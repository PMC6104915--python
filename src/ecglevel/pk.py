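"""One-compartment oral pharmacokinetics and sigmoid-Emax QT pharmacodynamics.

The synthetic cohorts couple a per-subject plasma concentration trajectory

    C(t) = sum over doses  S * D * ka/(ka - ke) * (e^{-ke (t-td)} - e^{-ka (t-td)}),
           for t >= td,

(first-order absorption rate ``ka`` in 1/h, elimination rate ``ke`` in 1/h,
dose ``D`` in ug, ``S`` a lumped scale mapping dose to plasma level in pg/ml)
to QT prolongation through a saturating concentration-effect curve

    dQT(C) = Emax * C / (EC50 + C)    [ms].

Multiple administrations superpose linearly, which is exact for a linear
compartment model.
"""

from __future__ import annotations

import numpy as np

from .errors import DegeneratePKError

# Default dofetilide-like scales (plausible magnitudes for a 500 ug oral
# dose; the lumped scale puts the single-dose peak near 2000 pg/ml so that
# prediction errors are commensurate with the pg/ml level scale).
DEFAULT_KA_PER_H = 1.5
DEFAULT_KE_PER_H = 0.07
DEFAULT_DOSE_UG = 500.0
DEFAULT_V_OVER_F_SCALE = 4.65   # pg/ml per ug of dose (lumped 1/(V/F))
DEFAULT_EMAX_MS = 80.0
DEFAULT_EC50_PG_ML = 1000.0


def single_dose_concentration(t_h, dose_ug: float, ka_per_h: float,
                              ke_per_h: float, scale: float) -> np.ndarray:
    """Plasma level (pg/ml) after one oral dose at t=0; 0 before the dose."""
    if ka_per_h == ke_per_h:
        raise DegeneratePKError(
            "degenerate PK: ka == ke makes the two-exponential model singular; "
            "perturb ke instead"
        )
    if min(ka_per_h, ke_per_h, dose_ug, scale) <= 0:
        raise ValueError("PK rates, dose and scale must be strictly positive")
    t = np.asarray(t_h, dtype=float)
    front = scale * dose_ug * ka_per_h / (ka_per_h - ke_per_h)
    c = front * (np.exp(-ke_per_h * t) - np.exp(-ka_per_h * t))
    c = np.where(t >= 0, c, 0.0)
    # clip tiny negative round-off for ka < ke parameterizations
    return np.maximum(c, 0.0)


def pk_concentration(t_h, profile) -> np.ndarray | float:
    """Total plasma concentration (pg/ml) at ``t_h`` for a subject profile.

    Sums the single-dose response over the profile's administration times;
    placebo-arm profiles are identically zero.
    """
    t = np.asarray(t_h, dtype=float)
    if np.any(t < -1.0) or np.any(t > 48.0):
        raise ValueError("t_h must lie within [-1, 48] hours")
    if profile.arm == "placebo":
        out = np.zeros_like(t)
        return float(out) if np.isscalar(t_h) else out
    out = np.zeros_like(t)
    for td in profile.dose_times_h:
        out = out + single_dose_concentration(
            t - td, profile.dose_ug, profile.ka_per_h, profile.ke_per_h,
            profile.v_over_f_scale,
        )
    return float(out) if np.isscalar(t_h) else out


def time_of_peak(ka_per_h: float, ke_per_h: float) -> float:
    """Closed-form time of the single-dose concentration maximum (hours)."""
    if ka_per_h == ke_per_h:
        raise DegeneratePKError("degenerate PK: ka == ke")
    return float(np.log(ka_per_h / ke_per_h) / (ka_per_h - ke_per_h))


def qt_effect(c_pg_ml, profile) -> np.ndarray | float:
    """QT prolongation (ms) at concentration ``c_pg_ml``: Emax*C/(EC50+C)."""
    c = np.asarray(c_pg_ml, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    d = profile.emax_ms * c / (profile.ec50_pg_ml + c)
    return float(d) if np.isscalar(c_pg_ml) else d
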