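"""The raw-ECG regression network.

Architecture (input: one 12-lead x 5000-sample record):

* six temporal convolution blocks applied per lead — [1 x k_i] kernels with
  zero padding, n_i filters, kernel length non-increasing and filter count
  non-decreasing with depth — each followed by batch normalization and
  ReLU, with an optional per-layer temporal downsampling factor (fused into
  the convolution as its stride);
* one lead-combining convolution with a [12 x 1] kernel (plus BN and ReLU)
  that merges the per-lead feature maps;
* flatten, then two fully connected hidden layers of 128 and 64 units, each
  with batch normalization, ReLU and dropout at p = 0.5;
* a single linear output neuron (plasma concentration, standardized units).

Weights use Xavier (Glorot) uniform initialization.  The loss is plain MSE
with no additional regularization beyond the FC dropout.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from ..errors import ConfigError
from . import layers as L

N_LEADS = 12
RECORD_SAMPLES = 5000
FC_SIZES = (128, 64)
DROPOUT_P = 0.5


@dataclass
class NetworkConfig:
    """Sizes of the convolutional feature extractor (the FC head is fixed)."""

    conv_filters: tuple[int, ...] = (16, 16, 32, 32, 64, 64)
    conv_kernel_lengths: tuple[int, ...] = (64, 32, 16, 16, 8, 8)
    lead_combiner_filters: int = 64
    pooling: tuple[int, ...] = (2, 2, 2, 2, 2, 2)
    fc_sizes: tuple[int, ...] = FC_SIZES
    dropout_p: float = DROPOUT_P

    def __post_init__(self) -> None:
        self.conv_filters = tuple(self.conv_filters)
        self.conv_kernel_lengths = tuple(self.conv_kernel_lengths)
        self.pooling = tuple(self.pooling)
        self.fc_sizes = tuple(self.fc_sizes)
        if len(self.conv_filters) != 6 or len(self.conv_kernel_lengths) != 6:
            raise ConfigError("exactly six temporal convolution layers required")
        if len(self.pooling) != 6 or any(p < 1 for p in self.pooling):
            raise ConfigError("pooling needs six factors >= 1")
        if any(b < a for a, b in zip(self.conv_filters, self.conv_filters[1:])):
            raise ConfigError("conv_filters must be non-decreasing with depth")
        if any(b > a for a, b in zip(self.conv_kernel_lengths,
                                     self.conv_kernel_lengths[1:])):
            raise ConfigError("conv_kernel_lengths must be non-increasing with depth")
        if self.fc_sizes != FC_SIZES:
            raise ConfigError(f"fully connected sizes are fixed at {FC_SIZES}")
        if self.dropout_p != DROPOUT_P:
            raise ConfigError(f"dropout probability is fixed at {DROPOUT_P}")


def demo_network_config() -> NetworkConfig:
    """A reduced configuration that trains on one CPU in minutes.

    Same topology as the default (six per-lead conv blocks, lead combiner,
    FC 128/64), with fewer filters, shorter kernels and stronger early
    pooling.
    """
    return NetworkConfig(
        conv_filters=(4, 4, 8, 8, 16, 16),
        conv_kernel_lengths=(16, 16, 8, 8, 8, 8),
        lead_combiner_filters=16,
        pooling=(5, 5, 4, 2, 2, 2),
    )


class Network:
    """Built network: layer objects plus an auditable description."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        self.config = config
        self.temporal: list[L.Layer] = []
        self.description: list[dict] = []
        in_ch = 1
        t = RECORD_SAMPLES
        for i in range(6):
            n, k, p = (config.conv_filters[i], config.conv_kernel_lengths[i],
                       config.pooling[i])
            conv = L.Conv1d(in_ch, n, k, rng, stride=p, needs_dx=(i > 0))
            self.temporal.append(conv)
            self.description.append({"kind": "conv", "filters": n,
                                     "kernel": [1, k], "padding": "zero",
                                     "downsample": p})
            self.temporal.append(L.BatchNorm(n))
            self.description.append({"kind": "batch_norm", "channels": n})
            self.temporal.append(L.ReLU())
            self.description.append({"kind": "relu"})
            t = conv.out_length(t)
            in_ch = n
        self.feature_t = t
        self.feature_ch = in_ch

        oc = config.lead_combiner_filters
        self.combiner = L.LeadConv(in_ch, N_LEADS, oc, rng)
        self.description.append({"kind": "conv", "filters": oc,
                                 "kernel": [N_LEADS, 1], "role": "lead_combiner"})
        self.combiner_bn = L.BatchNorm(oc)
        self.description.append({"kind": "batch_norm", "channels": oc})
        self.combiner_relu = L.ReLU()
        self.description.append({"kind": "relu"})

        self.flatten = L.Flatten()
        self.description.append({"kind": "flatten", "size": oc * t})
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))
        self.head: list[L.Layer] = []
        n_in = oc * t
        for units in config.fc_sizes:
            self.head.append(L.Dense(n_in, units, rng))
            self.description.append({"kind": "dense", "units": units})
            self.head.append(L.BatchNorm(units))
            self.description.append({"kind": "batch_norm", "channels": units})
            self.head.append(L.ReLU())
            self.description.append({"kind": "relu"})
            self.head.append(L.Dropout(config.dropout_p, self._dropout_rng))
            self.description.append({"kind": "dropout", "p": config.dropout_p})
            n_in = units
        self.output = L.Dense(n_in, 1, rng)
        self.description.append({"kind": "dense", "units": 1,
                                 "activation": "linear", "role": "output"})

    # -- execution ---------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, 12, 5000) standardized; returns (N,) standardized output."""
        n = x.shape[0]
        if x.shape[1:] != (N_LEADS, RECORD_SAMPLES):
            raise ValueError(
                f"expected input of shape (N, {N_LEADS}, {RECORD_SAMPLES}), "
                f"got {x.shape}")
        h = x.reshape(n * N_LEADS, 1, RECORD_SAMPLES).astype(L.F32)
        for layer in self.temporal:
            h = layer.forward(h, train)
        h = h.reshape(n, N_LEADS, self.feature_ch, self.feature_t) \
             .transpose(0, 2, 1, 3)
        h = self.combiner.forward(np.ascontiguousarray(h), train)
        h = self.combiner_relu.forward(self.combiner_bn.forward(h, train), train)
        h = self.flatten.forward(h, train)
        for layer in self.head:
            h = layer.forward(h, train)
        return self.output.forward(h, train)[:, 0]

    def backward(self, dy: np.ndarray) -> None:
        n = dy.shape[0]
        g = self.output.backward(dy[:, None].astype(L.F32))
        for layer in reversed(self.head):
            g = layer.backward(g)
        g = self.flatten.backward(g)
        g = self.combiner_bn.backward(self.combiner_relu.backward(g))
        g = self.combiner.backward(g)
        g = g.transpose(0, 2, 1, 3).reshape(n * N_LEADS, self.feature_ch,
                                            self.feature_t)
        g = np.ascontiguousarray(g)
        for layer in reversed(self.temporal):
            g = layer.backward(g)

    # -- bookkeeping -------------------------------------------------------

    def _all_layers(self) -> list[L.Layer]:
        return (self.temporal + [self.combiner, self.combiner_bn]
                + self.head + [self.output])

    def parameters(self):
        out = []
        for layer in self._all_layers():
            out.extend(layer.params())
        return out

    def count_parameters(self) -> int:
        return int(sum(getattr(l, n).size for l, n in self.parameters()))

    def get_state(self) -> list[np.ndarray]:
        state = [getattr(l, n).copy() for l, n in self.parameters()]
        for layer in self._all_layers():
            if isinstance(layer, L.BatchNorm):
                state += [layer.running_mean.copy(), layer.running_var.copy()]
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for (layer, name), arr in zip(params, state[:len(params)]):
            setattr(layer, name, arr.copy())
        it = iter(state[len(params):])
        for layer in self._all_layers():
            if isinstance(layer, L.BatchNorm):
                layer.running_mean = next(it).copy()
                layer.running_var = next(it).copy()

    def clone_state(self) -> list[np.ndarray]:
        return copy.deepcopy(self.get_state())


def build_network(config: NetworkConfig | None = None,
                  seed: int = 0) -> Network:
    """Construct the network with Xavier-initialized weights."""
    return Network(config or NetworkConfig(), np.random.default_rng(seed))
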