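"""Network layers (gradient checks), architecture audit, parameter count."""

import numpy as np
import pytest

from ecglevel.errors import ConfigError
from ecglevel.nn import NetworkConfig, build_network, demo_network_config
from ecglevel.nn import layers as L


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def _num_grad_x(layer, x, dy, rng, n_checks=5, eps=1e-2):
    """Central-difference input gradient at random entries."""
    layer.forward(x.copy(), train=True)
    dx = layer.backward(dy.copy())
    errs = []
    for _ in range(n_checks):
        ix = tuple(rng.integers(0, s) for s in x.shape)
        xp, xm = x.copy(), x.copy()
        xp[ix] += eps
        xm[ix] -= eps
        num = (np.sum(layer.forward(xp, True) * dy)
               - np.sum(layer.forward(xm, True) * dy)) / (2 * eps)
        errs.append(abs(num - dx[ix]) / max(abs(num), 1e-3))
    return max(errs)


@pytest.mark.parametrize("make,shape", [
    (lambda r: L.Conv1d(2, 3, 4, r), (3, 2, 20)),
    (lambda r: L.Conv1d(1, 2, 16, r, stride=5), (3, 1, 50)),
    (lambda r: L.Conv1d(2, 3, 8, r, stride=4), (2, 2, 21)),
    (lambda r: L.BatchNorm(2), (3, 2, 20)),
    (lambda r: L.ReLU(), (3, 2, 20)),
    (lambda r: L.MaxPool1d(2), (3, 2, 20)),
    (lambda r: L.LeadConv(2, 12, 4, r), (3, 2, 12, 5)),
    (lambda r: L.Dense(7, 3, r), (6, 7)),
])
def test_layer_input_gradients_match_finite_differences(make, shape, rng):
    layer = make(rng)
    x = rng.standard_normal(shape).astype(np.float32)
    y = layer.forward(x.copy(), train=True)
    dy = rng.standard_normal(y.shape).astype(np.float32)
    assert _num_grad_x(layer, x, dy, rng) < 2e-2


@pytest.mark.parametrize("make,shape,wname", [
    (lambda r: L.Conv1d(2, 3, 4, r, stride=2), (3, 2, 20), "W"),
    (lambda r: L.LeadConv(2, 12, 4, r), (3, 2, 12, 5), "W"),
    (lambda r: L.Dense(7, 3, r), (6, 7), "W"),
    (lambda r: L.BatchNorm(2), (3, 2, 20), "gamma"),
])
def test_layer_weight_gradients_match_finite_differences(make, shape, wname, rng):
    layer = make(rng)
    x = rng.standard_normal(shape).astype(np.float32)
    y = layer.forward(x.copy(), True)
    dy = rng.standard_normal(y.shape).astype(np.float32)
    layer.backward(dy.copy())
    g = getattr(layer, "g" + wname).copy()
    w0 = getattr(layer, wname).copy()
    errs = []
    for _ in range(5):
        ix = tuple(rng.integers(0, s) for s in w0.shape)
        eps = 1e-2
        wp, wm = w0.copy(), w0.copy()
        wp[ix] += eps
        wm[ix] -= eps
        setattr(layer, wname, wp)
        up = np.sum(layer.forward(x, True) * dy)
        setattr(layer, wname, wm)
        dn = np.sum(layer.forward(x, True) * dy)
        setattr(layer, wname, w0)
        num = (up - dn) / (2 * eps)
        errs.append(abs(num - g[ix]) / max(abs(num), 1e-3))
    assert max(errs) < 2e-2


def test_config_monotonicity_constraints_enforced():
    with pytest.raises(ConfigError):
        NetworkConfig(conv_filters=(16, 8, 32, 32, 64, 64))
    with pytest.raises(ConfigError):
        NetworkConfig(conv_kernel_lengths=(16, 32, 16, 16, 8, 8))
    with pytest.raises(ConfigError):
        NetworkConfig(conv_filters=(16,) * 5)
    with pytest.raises(ConfigError):
        NetworkConfig(fc_sizes=(256, 64))
    with pytest.raises(ConfigError):
        NetworkConfig(dropout_p=0.3)


@pytest.mark.parametrize("config_fn", [NetworkConfig, demo_network_config])
def test_architecture_audit(config_fn):
    """Seven conv layers, BN+ReLU after every conv and FC layer, dropout
    only on the two FC hidden layers, one linear output neuron."""
    net = build_network(config_fn(), seed=0)
    desc = net.description
    convs = [d for d in desc if d["kind"] == "conv"]
    assert len(convs) == 7
    assert convs[-1]["kernel"] == [12, 1]  # lead combiner
    for i, d in enumerate(desc):
        if d["kind"] in ("conv", "dense") and d.get("role") != "output":
            assert desc[i + 1]["kind"] == "batch_norm"
            assert desc[i + 2]["kind"] == "relu"
    dropouts = [i for i, d in enumerate(desc) if d["kind"] == "dropout"]
    denses = [d for d in desc if d["kind"] == "dense"]
    assert [d["units"] for d in denses] == [128, 64, 1]
    assert len(dropouts) == 2
    for i in dropouts:  # dropout follows an FC block's ReLU only
        assert desc[i - 1]["kind"] == "relu" and desc[i - 3]["kind"] == "dense"
        assert desc[i - 3]["units"] in (128, 64)
    assert desc[-1] == {"kind": "dense", "units": 1, "activation": "linear",
                        "role": "output"}


def _independent_parameter_count(cfg: NetworkConfig) -> int:
    """Layer-by-layer arithmetic, written independently of the builder."""
    total = 0
    c_in, t = 1, 5000
    for n, k, p in zip(cfg.conv_filters, cfg.conv_kernel_lengths, cfg.pooling):
        total += n * c_in * k + n      # conv weights + bias
        total += 2 * n                 # batch-norm gamma/beta
        t = -(-t // p)                 # ceil division: strided downsampling
        c_in = n
    oc = cfg.lead_combiner_filters
    total += oc * c_in * 12 + oc + 2 * oc
    n_in = oc * t
    for units in (128, 64):
        total += n_in * units + units + 2 * units
        n_in = units
    total += 64 * 1 + 1
    return total


@pytest.mark.parametrize("config_fn", [NetworkConfig, demo_network_config])
def test_parameter_count_matches_independent_arithmetic(config_fn):
    cfg = config_fn()
    net = build_network(cfg, seed=1)
    assert net.count_parameters() == _independent_parameter_count(cfg)


def test_forward_shape_contract_and_determinism():
    net = build_network(demo_network_config(), seed=3)
    rng = np.random.default_rng(0)
    x = rng.standard_normal((2, 12, 5000)).astype(np.float32)
    y1 = net.forward(x, train=False)
    y2 = net.forward(x, train=False)
    assert y1.shape == (2,)
    assert np.array_equal(y1, y2)
    with pytest.raises(ValueError, match="12, 5000"):
        net.forward(rng.standard_normal((2, 12, 4000)).astype(np.float32))


def test_same_seed_builds_identical_networks():
    a = build_network(demo_network_config(), seed=7)
    b = build_network(demo_network_config(), seed=7)
    for (la, na), (lb, nb) in zip(a.parameters(), b.parameters()):
        assert np.array_equal(getattr(la, na), getattr(lb, nb))


def test_state_round_trip_preserves_outputs():
    net = build_network(demo_network_config(), seed=5)
    rng = np.random.default_rng(1)
    x = rng.standard_normal((2, 12, 5000)).astype(np.float32)
    y_ref = net.forward(x)
    state = net.get_state()
    other = build_network(demo_network_config(), seed=99)
    other.set_state(state)
    assert np.allclose(other.forward(x), y_ref)
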