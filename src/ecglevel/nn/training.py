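"""Training and inference for the raw-ECG concentration regressor.

Targets (pg/ml) are standardized to zero mean / unit variance and inputs
are z-scored per lead with training-set statistics; both transforms are
stored in the artifact and inverted at prediction time.  Training minimizes
MSE with Adam; 10% of the training set is held out for internal validation
and the checkpoint with the best validation MSE is the one kept.  Dropout
is disabled and batch-norm running statistics are used at inference, so
prediction is deterministic given the artifact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..io import ECGRecord
from .network import Network, NetworkConfig, N_LEADS, RECORD_SAMPLES
from .layers import Adam, F32

VALIDATION_FRACTION = 0.10


@dataclass
class TrainConfig:
    """Optimization settings.

    The internal validation split takes 10% of the training *subjects*
    (falling back to 10% of records when fewer than five subjects are
    present), so the best-validation checkpoint reflects generalization to
    unseen subjects rather than to unseen replicates of seen subjects.
    The learning rate drops by ``lr_decay_factor`` after two thirds of the
    epochs (or at ``lr_decay_at`` if given).
    """

    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    validation_fraction: float = VALIDATION_FRACTION
    seed: int = 0
    lr_decay_at: int | None = None
    lr_decay_factor: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.validation_fraction != VALIDATION_FRACTION:
            raise ValueError(
                f"validation fraction is fixed at {VALIDATION_FRACTION}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


@dataclass
class DeepModelArtifact:
    """Trained network plus the normalization constants and history."""

    network: Network
    net_config: NetworkConfig
    train_config: TrainConfig
    lead_mean_uv: np.ndarray     # (12,)
    lead_std_uv: np.ndarray      # (12,)
    target_mean_pg_ml: float
    target_std_pg_ml: float
    best_val_mse: float
    history: pd.DataFrame        # epoch, train_mse, val_mse (standardized units)
    train_subject_ids: list[str] = field(default_factory=list)

    def _standardize(self, signals: np.ndarray) -> np.ndarray:
        return ((signals - self.lead_mean_uv[:, None])
                / self.lead_std_uv[:, None]).astype(F32)

    def predict_record(self, record: ECGRecord) -> float:
        return float(self.predict_signals(record.signal[None])[0])

    def predict_signals(self, signals: np.ndarray) -> np.ndarray:
        """Predict pg/ml for a (N, 12, 5000) stack of raw signals in uV."""
        signals = np.asarray(signals, dtype=F32)
        if signals.ndim != 3 or signals.shape[1:] != (N_LEADS, RECORD_SAMPLES):
            raise ValueError(
                f"expected signals of shape (N, {N_LEADS}, {RECORD_SAMPLES}), "
                f"got {signals.shape}")
        out = np.empty(signals.shape[0], dtype=np.float64)
        for lo in range(0, signals.shape[0], 64):
            batch = self._standardize(signals[lo:lo + 64])
            out[lo:lo + batch.shape[0]] = self.network.forward(batch, train=False)
        return out * self.target_std_pg_ml + self.target_mean_pg_ml

    # -- persistence (weights as npz; configs and history as text) --------

    def save(self, dirpath) -> Path:
        dirpath = Path(dirpath)
        dirpath.mkdir(parents=True, exist_ok=True)
        state = self.network.get_state()
        np.savez(dirpath / "weights.npz",
                 *state,
                 lead_mean=self.lead_mean_uv, lead_std=self.lead_std_uv)
        (dirpath / "config.json").write_text(json.dumps({
            "net_config": self.net_config.__dict__,
            "train_config": self.train_config.__dict__,
            "target_mean_pg_ml": self.target_mean_pg_ml,
            "target_std_pg_ml": self.target_std_pg_ml,
            "best_val_mse": self.best_val_mse,
            "train_subject_ids": self.train_subject_ids,
            "n_state_arrays": len(state),
        }, indent=2, default=list) + "\n")
        self.history.to_csv(dirpath / "history.csv", index=False)
        return dirpath

    @classmethod
    def load(cls, dirpath) -> "DeepModelArtifact":
        dirpath = Path(dirpath)
        meta = json.loads((dirpath / "config.json").read_text())
        nc = NetworkConfig(**{k: tuple(v) if isinstance(v, list) else v
                              for k, v in meta["net_config"].items()})
        tc = TrainConfig(**meta["train_config"])
        net = Network(nc, np.random.default_rng(0))
        blob = np.load(dirpath / "weights.npz")
        state = [blob[f"arr_{i}"] for i in range(meta["n_state_arrays"])]
        net.set_state(state)
        return cls(
            network=net, net_config=nc, train_config=tc,
            lead_mean_uv=blob["lead_mean"], lead_std_uv=blob["lead_std"],
            target_mean_pg_ml=meta["target_mean_pg_ml"],
            target_std_pg_ml=meta["target_std_pg_ml"],
            best_val_mse=meta["best_val_mse"],
            history=pd.read_csv(dirpath / "history.csv"),
            train_subject_ids=list(meta["train_subject_ids"]),
        )


def _as_arrays(training_samples):
    signals, targets, subjects = [], [], []
    for rec, conc in training_samples:
        rec.validate()
        signals.append(rec.signal)
        targets.append(float(conc))
        subjects.append(rec.subject_id)
    return (np.stack(signals).astype(F32), np.asarray(targets, dtype=np.float64),
            np.asarray(subjects))


def _validation_split(subjects: np.ndarray, fraction: float,
                      rng: np.random.Generator):
    """Hold out ~``fraction`` of subjects (or records, below 5 subjects)."""
    n = len(subjects)
    uniq = sorted(set(subjects))
    if len(uniq) >= 5:
        n_val_subj = max(1, int(round(fraction * len(uniq))))
        val_subjects = rng.choice(uniq, n_val_subj, replace=False)
        mask = np.isin(subjects, val_subjects)
        return np.where(mask)[0], np.where(~mask)[0]
    perm = rng.permutation(n)
    n_val = int(round(fraction * n))
    return perm[:n_val], perm[n_val:]


def train(training_samples, net_config: NetworkConfig | None = None,
          train_config: TrainConfig | None = None,
          verbose: bool = False) -> DeepModelArtifact:
    """Train on ``[(ECGRecord, concentration_pg_ml), ...]``.

    Each replicate record is a separate training sample (triplicates are
    aggregated at prediction time, not here).  Returns the artifact holding
    the minimum-validation-MSE checkpoint and the per-epoch loss history.
    Fully reproducible given ``train_config.seed`` on a fixed platform.
    """
    net_config = net_config or NetworkConfig()
    train_config = train_config or TrainConfig()
    x, y, subjects = _as_arrays(training_samples)
    n = x.shape[0]
    if n < 20:
        raise ValueError(f"need at least 20 training records, got {n}")

    rng = np.random.default_rng(train_config.seed)
    val_idx, tr_idx = _validation_split(subjects,
                                        train_config.validation_fraction, rng)
    if len(val_idx) < 2:
        raise ValueError(
            f"validation split of {n} records would contain "
            f"{len(val_idx)} (< 2) records")

    lead_mean = x[tr_idx].mean(axis=(0, 2))
    lead_std = x[tr_idx].std(axis=(0, 2))
    lead_std[lead_std == 0] = 1.0
    xs = ((x - lead_mean[:, None]) / lead_std[:, None]).astype(F32)

    y_mean = float(y[tr_idx].mean())
    y_std = float(y[tr_idx].std()) or 1.0
    ys = ((y - y_mean) / y_std).astype(np.float64)

    net = Network(net_config, rng)
    adam = Adam(net.parameters(), lr=train_config.learning_rate)

    decay_at = (train_config.lr_decay_at if train_config.lr_decay_at is not None
                else (2 * train_config.epochs) // 3)
    best_val = np.inf
    best_state = net.clone_state()
    history = []
    for epoch in range(train_config.epochs):
        if epoch == decay_at and train_config.lr_decay_factor != 1.0:
            adam.lr *= train_config.lr_decay_factor
        order = rng.permutation(tr_idx)
        losses = []
        for lo in range(0, len(order), train_config.batch_size):
            idx = order[lo:lo + train_config.batch_size]
            pred = net.forward(xs[idx], train=True)
            resid = pred - ys[idx]
            losses.append(float(np.mean(resid ** 2)))
            net.backward((2.0 / len(idx)) * resid)
            adam.step()
        val_pred = _forward_eval(net, xs[val_idx])
        val_mse = float(np.mean((val_pred - ys[val_idx]) ** 2))
        history.append({"epoch": epoch, "train_mse": float(np.mean(losses)),
                        "val_mse": val_mse})
        if verbose:
            print(f"epoch {epoch:3d}  train {history[-1]['train_mse']:.4f}  "
                  f"val {val_mse:.4f}")
        if val_mse < best_val:
            best_val = val_mse
            best_state = net.clone_state()

    net.set_state(best_state)
    return DeepModelArtifact(
        network=net, net_config=net_config, train_config=train_config,
        lead_mean_uv=lead_mean.astype(F32), lead_std_uv=lead_std.astype(F32),
        target_mean_pg_ml=y_mean, target_std_pg_ml=y_std,
        best_val_mse=best_val,
        history=pd.DataFrame(history),
        train_subject_ids=sorted(set(subjects)),
    )


def _forward_eval(net: Network, xs: np.ndarray, batch: int = 64) -> np.ndarray:
    out = np.empty(xs.shape[0], dtype=np.float64)
    for lo in range(0, xs.shape[0], batch):
        out[lo:lo + batch] = net.forward(xs[lo:lo + batch], train=False)
    return out


def predict(artifact: DeepModelArtifact, record: ECGRecord) -> float:
    """Deterministic pg/ml prediction for one record."""
    return artifact.predict_record(record)
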