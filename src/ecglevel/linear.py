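"""Reference model: ordinary least squares of plasma concentration on QTc."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DegenerateDesignError


@dataclass
class LinearModelArtifact:
    """Fitted concentration = slope * QTc + intercept model."""

    slope: float            # pg/ml per ms
    intercept: float        # pg/ml
    n_pairs: int
    residual_variance: float
    qtc_mean_ms: float
    concentration_mean_pg_ml: float
    train_subject_ids: list[str] = field(default_factory=list)

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.__dict__, indent=2) + "\n")
        return path

    @classmethod
    def from_json(cls, path) -> "LinearModelArtifact":
        return cls(**json.loads(Path(path).read_text()))


def fit_linear(pairs, train_subject_ids=None) -> LinearModelArtifact:
    """Least-squares fit of concentration (pg/ml) on QTc (ms).

    ``pairs`` is a sequence of ``(qtc_ms, concentration_pg_ml)``.  Refuses
    degenerate designs (fewer than 3 pairs or zero QTc variance).
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise DegenerateDesignError("need at least 3 (qtc, concentration) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if not np.all(np.isfinite(arr)):
        raise DegenerateDesignError("non-finite values in training pairs")
    if np.var(x) == 0:
        raise DegenerateDesignError("degenerate design: QTc has zero variance")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    dof = max(len(x) - 2, 1)
    return LinearModelArtifact(
        slope=float(slope), intercept=float(intercept), n_pairs=len(x),
        residual_variance=float(resid @ resid / dof),
        qtc_mean_ms=float(x.mean()),
        concentration_mean_pg_ml=float(y.mean()),
        train_subject_ids=list(train_subject_ids or []),
    )


def predict_linear(model: LinearModelArtifact, qtc_ms,
                   clip_negative: bool = False):
    """Predicted concentration (pg/ml) for one or many QTc values.

    Negative predictions are reported as-is by default, keeping the
    estimator strictly affine; ``clip_negative`` floors them at zero.
    """
    if model is None or not np.isfinite(model.slope):
        raise ValueError("predict_linear requires a fitted model")
    qtc = np.asarray(qtc_ms, dtype=float)
    pred = model.slope * qtc + model.intercept
    if clip_negative:
        pred = np.maximum(pred, 0.0)
    return float(pred) if np.isscalar(qtc_ms) else pred
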