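"""Synthetic drug-trial cohort generation with stored ground truth.

Emulates the statistical structure of a thorough-QT style cross-over trial:
each subject has a pharmacokinetic plasma-concentration trajectory after
oral dosing, concentration-coupled QT prolongation (sigmoid Emax), optional
concentration-coupled T-wave morphology change, and triplicate 10-s 12-lead
ECGs at every protocol-defined blood draw.

``effect_config`` controls which information channels carry the drug level:

``duration_only``
    Concentration influences the ECG solely through the QT interval; a
    QTc-based model then has access to all available signal.
``duration_plus_morphology``
    Concentration additionally modulates T-wave amplitude and asymmetry
    (per-subject gain), information invisible to a QT-only model — the
    mechanism by which a waveform-level model can outperform the QTc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pk
from .io import Cohort, CohortSample, PROTOCOL_GRIDS
from .waveform import synthesize_ecg

DEFAULT_NOISE_UV = 6.0
BASELINE_QT_MEAN_MS, BASELINE_QT_SD_MS = 390.0, 20.0
BASELINE_HR_MEAN_BPM, BASELINE_HR_SD_BPM = 64.0, 6.0
MORPHOLOGY_GAIN_MEAN, MORPHOLOGY_GAIN_SD = 1.0, 0.15
MORPHOLOGY_C_REF_PG_ML = 2000.0  # concentration giving one unit of offset
# Inter-subject variability enters through baseline QT/HR and the
# morphology gain only; T amplitude has no independent per-subject scale by
# default (t_amp_scale stays configurable on the profile).
T_AMP_SCALE_SD = 0.0
DRAW_HR_SD_BPM = 2.0  # draw-to-draw heart-rate wobble

DOSE_TIMES_H = {"A": (0.0,), "B": (0.0, 5.0, 10.0)}

EFFECT_CONFIGS = ("duration_only", "duration_plus_morphology")


@dataclass
class SubjectProfile:
    """Ground-truth pharmacology and waveform parameters for one subject."""

    subject_id: str
    sex: str = "M"
    arm: str = "dofetilide"
    protocol: str = "A"
    dose_ug: float = pk.DEFAULT_DOSE_UG
    dose_times_h: tuple[float, ...] = (0.0,)
    ka_per_h: float = pk.DEFAULT_KA_PER_H
    ke_per_h: float = pk.DEFAULT_KE_PER_H
    v_over_f_scale: float = pk.DEFAULT_V_OVER_F_SCALE
    emax_ms: float = pk.DEFAULT_EMAX_MS
    ec50_pg_ml: float = pk.DEFAULT_EC50_PG_ML
    baseline_qt_ms: float = BASELINE_QT_MEAN_MS  # rate-corrected (at RR = 1 s)
    baseline_hr_bpm: float = BASELINE_HR_MEAN_BPM
    morphology_gain: float = MORPHOLOGY_GAIN_MEAN
    t_amp_scale: float = 1.0
    noise_uv: float = DEFAULT_NOISE_UV
    reverse_use_gamma: float = 0.0  # optional reverse use dependence, off by default
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.ka_per_h == self.ke_per_h:
            raise ValueError("degenerate PK: ka_per_h must differ from ke_per_h")
        for name in ("dose_ug", "ka_per_h", "ke_per_h", "v_over_f_scale",
                     "emax_ms", "ec50_pg_ml"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.baseline_qt_ms >= 60000.0 / self.baseline_hr_bpm:
            raise ValueError("baseline QT must be shorter than the RR interval")


@dataclass
class GroundTruth:
    """True per-draw state of a synthetic cohort, for recovery tests."""

    table: pd.DataFrame  # one row per (subject, timepoint)
    profiles: dict[str, SubjectProfile] = field(default_factory=dict)


def _draw_profile(subject_id: str, sex: str, arm: str, protocol: str,
                  rng: np.random.Generator, noise_uv: float,
                  overrides: dict | None) -> SubjectProfile:
    baseline_qt = float(np.clip(rng.normal(BASELINE_QT_MEAN_MS, BASELINE_QT_SD_MS),
                                340.0, 450.0))
    baseline_hr = float(np.clip(rng.normal(BASELINE_HR_MEAN_BPM, BASELINE_HR_SD_BPM),
                                48.0, 90.0))
    kwargs = dict(
        subject_id=subject_id, sex=sex, arm=arm, protocol=protocol,
        dose_times_h=DOSE_TIMES_H[protocol],
        baseline_qt_ms=baseline_qt,
        baseline_hr_bpm=baseline_hr,
        morphology_gain=float(max(0.3, rng.normal(MORPHOLOGY_GAIN_MEAN,
                                                  MORPHOLOGY_GAIN_SD))),
        t_amp_scale=float(max(0.5, rng.normal(1.0, T_AMP_SCALE_SD)))
        if T_AMP_SCALE_SD > 0 else 1.0,
        noise_uv=noise_uv,
        rng_seed=int(rng.integers(2**31)),
    )
    if overrides:
        kwargs.update(overrides)
    return SubjectProfile(**kwargs)


def generate_cohort(n_subjects: int, protocol: str = "A",
                    arm_fractions: dict[str, float] | None = None,
                    master_seed: int = 0,
                    effect_config: str = "duration_plus_morphology",
                    noise_uv: float = DEFAULT_NOISE_UV,
                    profile_overrides: dict | None = None,
                    ) -> tuple[Cohort, GroundTruth]:
    """Generate a sex-balanced synthetic cohort on the protocol's time grid.

    Returns the cohort (triplicate records per blood draw, concentrations in
    pg/ml) and the ground truth (true concentration, QT, RR and morphology
    offset per draw, plus the per-subject profiles).  Fully deterministic
    given ``master_seed``.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects (train/test split impossible)")
    if protocol not in PROTOCOL_GRIDS:
        raise ValueError(f"unknown protocol {protocol!r}")
    if effect_config not in EFFECT_CONFIGS:
        raise ValueError(f"effect_config must be one of {EFFECT_CONFIGS}")
    arm_fractions = arm_fractions or {"dofetilide": 1.0}
    if not np.isclose(sum(arm_fractions.values()), 1.0):
        raise ValueError("arm_fractions must sum to 1")

    # deterministic arm sequence, interleaved so arms do not confound the
    # id-ordered train/test split
    n_dof = int(round(arm_fractions.get("dofetilide", 0.0) * n_subjects))
    arm_seq = ["placebo"] * n_subjects
    if n_dof > 0:
        for i, j in enumerate(np.linspace(0, n_subjects - 1, n_dof).round().astype(int)):
            arm_seq[int(j)] = "dofetilide"

    root = np.random.SeedSequence(master_seed)
    subject_seeds = root.spawn(n_subjects)
    grid = PROTOCOL_GRIDS[protocol]

    samples: list[CohortSample] = []
    subject_rows, truth_rows = [], []
    profiles: dict[str, SubjectProfile] = {}

    for i in range(n_subjects):
        subject_id = f"S{i + 1:03d}"
        sex = "M" if i % 2 == 0 else "F"
        rng = np.random.default_rng(subject_seeds[i])
        prof = _draw_profile(subject_id, sex, arm_seq[i], protocol, rng,
                             noise_uv, profile_overrides)
        profiles[subject_id] = prof
        subject_rows.append({"subject_id": subject_id, "sex": sex,
                             "arm": prof.arm, "protocol": protocol})

        for t_h in grid:
            conc = float(pk.pk_concentration(t_h, prof))
            hr = float(np.clip(prof.baseline_hr_bpm + rng.normal(0, DRAW_HR_SD_BPM),
                               45.0, 150.0))
            rr = 60000.0 / hr
            dqt = float(pk.qt_effect(conc, prof))
            if prof.reverse_use_gamma != 0.0:
                dqt *= (rr / 1000.0) ** prof.reverse_use_gamma
            # baseline_qt_ms is the subject's rate-corrected (RR = 1 s)
            # baseline; the uncorrected QT tracks the draw's RR as real
            # repolarization does, so baseline QTc is rate-stable
            qt = min(prof.baseline_qt_ms * np.sqrt(rr / 1000.0) + dqt,
                     rr - 120.0)
            if effect_config == "duration_plus_morphology":
                # T-wave morphology indexes instantaneous channel block and
                # tracks plasma level near-linearly over the observed range
                # (unlike the saturating QT effect); normalized to the
                # typical single-dose peak so the offset is O(1) at C_max
                morph = min(prof.morphology_gain * conc / MORPHOLOGY_C_REF_PG_ML,
                            2.0)
            else:
                morph = 0.0

            reps = []
            for k in (1, 2, 3):
                rec = synthesize_ecg(prof, qt, rr, morphology_offset=morph,
                                     replicate_index=k,
                                     seed=int(rng.integers(2**31)))
                rec.subject_id = subject_id
                rec.timepoint_h = t_h
                reps.append(rec)
            samples.append(CohortSample(
                subject_id=subject_id, sex=sex, arm=prof.arm, protocol=protocol,
                timepoint_h=t_h, replicates=reps, concentration_pg_ml=conc,
            ))
            truth_rows.append({
                "subject_id": subject_id, "timepoint_h": t_h, "arm": prof.arm,
                "concentration_pg_ml": conc, "qt_ms": qt, "rr_ms": rr,
                "morphology_offset": morph,
                "baseline_qt_ms": prof.baseline_qt_ms,
                "baseline_hr_bpm": prof.baseline_hr_bpm,
            })

    cohort = Cohort(
        samples=samples,
        subjects=pd.DataFrame(subject_rows),
        provenance={
            "generator": "ecglevel.cohort_gen.generate_cohort",
            "n_subjects": n_subjects, "protocol": protocol,
            "arm_fractions": arm_fractions, "master_seed": master_seed,
            "effect_config": effect_config, "noise_uv": noise_uv,
        },
    )
    truth = GroundTruth(table=pd.DataFrame(truth_rows), profiles=profiles)
    return cohort, truth
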