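"""OLS concentration-on-QTc reference model."""

import numpy as np
import pytest

from ecglevel.errors import DegenerateDesignError
from ecglevel.linear import LinearModelArtifact, fit_linear, predict_linear


def test_exact_line_recovered_to_machine_precision():
    x = np.array([380.0, 400.0, 420.0, 450.0, 470.0])
    pairs = [(xi, 10.0 * xi - 2000.0) for xi in x]
    model = fit_linear(pairs)
    assert model.slope == pytest.approx(10.0, rel=1e-12)
    assert model.intercept == pytest.approx(-2000.0, rel=1e-9)
    assert predict_linear(model, 400.0) == pytest.approx(2000.0)


def test_degenerate_designs_rejected():
    with pytest.raises(DegenerateDesignError):
        fit_linear([(400.0, 1.0), (400.0, 2.0), (400.0, 3.0)])
    with pytest.raises(DegenerateDesignError):
        fit_linear([(400.0, 1.0), (410.0, 2.0)])


def test_fit_invariant_to_pair_order():
    rng = np.random.default_rng(0)
    pairs = [(float(x), float(8 * x + rng.normal(0, 50))) for x in
             rng.uniform(350, 500, 50)]
    a = fit_linear(pairs)
    b = fit_linear(pairs[::-1])
    assert a.slope == pytest.approx(b.slope, rel=1e-9)
    assert a.intercept == pytest.approx(b.intercept, rel=1e-9)


def test_prediction_passes_through_training_centroid():
    rng = np.random.default_rng(1)
    pairs = [(float(x), float(5 * x + rng.normal(0, 100))) for x in
             rng.uniform(350, 500, 80)]
    model = fit_linear(pairs)
    assert predict_linear(model, model.qtc_mean_ms) == pytest.approx(
        model.concentration_mean_pg_ml, rel=1e-9)


def test_prediction_is_affine_and_clippable():
    model = LinearModelArtifact(slope=0.0, intercept=-5.0, n_pairs=3,
                                residual_variance=0.0, qtc_mean_ms=400.0,
                                concentration_mean_pg_ml=-5.0)
    assert predict_linear(model, 999.0) == -5.0
    assert predict_linear(model, 999.0, clip_negative=True) == 0.0


def test_fitted_slope_within_bootstrap_sampling_band():
    """Slope recovery on y = 8x + 100 + N(0, 50): the fit must fall inside
    the 99% bootstrap band computed from the definitional covariance
    estimator (independent of the fitting routine)."""
    rng = np.random.default_rng(2024)
    x = rng.uniform(350, 500, 200)
    y = 8.0 * x + 100.0 + rng.normal(0, 50, 200)
    model = fit_linear(list(zip(x, y)))

    def slope_cov(xs, ys):  # definitional: cov(x, y) / var(x)
        xc, yc = xs - xs.mean(), ys - ys.mean()
        return float((xc @ yc) / (xc @ xc))

    boots = []
    for _ in range(500):
        idx = rng.integers(0, 200, 200)
        boots.append(slope_cov(x[idx], y[idx]))
    lo, hi = np.percentile(boots, [0.5, 99.5])
    assert lo <= model.slope <= hi
    assert model.slope == pytest.approx(slope_cov(x, y), rel=1e-9)


def test_artifact_json_round_trip(tmp_path):
    model = fit_linear([(380.0, 100.0), (420.0, 900.0), (460.0, 2100.0)],
                       train_subject_ids=["S001", "S002"])
    path = model.to_json(tmp_path / "linear.json")
    back = LinearModelArtifact.from_json(path)
    assert back == model
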