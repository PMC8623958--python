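"""Feed-forward network regressing the variant-class value.

A single-hidden-layer network (16 inputs -> tanh hidden units -> linear
output) is trained by full-batch gradient-descent backpropagation with
momentum on mean-squared error, predicting the ACMG class value
(0, 0.25, 0.5, 0.75, 1) from the encoded factor vector.  The cohort is
partitioned 160/54/54-proportionally into train/test/validation sets;
training stops early when validation error stops improving.  Success is
reported as the Pearson correlation R between network outputs and
targets on each partition, the conventional regression "success rate".

Missing inputs are imputed with the mid-scale value 0.5 for the network
only (the fuzzy engine has its own skip mechanism).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .datamodel import (
    EncodedRecord,
    FactorDefinition,
    PatientRecord,
    encode_record,
)

__all__ = [
    "NetworkModel",
    "TrainConfig",
    "TrainingReport",
    "split_cohort",
    "features",
    "forward",
    "train",
    "regression_r",
]

#: Reference split of the 268-patient cohort: train/test/validation.
SPLIT_REFERENCE = (160, 54, 54)
MISSING_FILL = 0.5


@dataclass
class TrainConfig:
    """Hyperparameters of the regressor (defaults fit the 268-cohort
    problem in a few seconds on one CPU)."""

    hidden_units: int = 10
    learning_rate: float = 0.05
    momentum: float = 0.9
    max_epochs: int = 2000
    patience: int = 50
    seed: int = 0
    include_classification: bool = True


@dataclass
class NetworkModel:
    """Layer weights of a 16-H-1 feed-forward network."""

    w1: np.ndarray  # (hidden, n_inputs)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (1, hidden)
    b2: np.ndarray  # (1,)
    seed: int = 0
    include_classification: bool = True

    @property
    def n_inputs(self) -> int:
        return self.w1.shape[1]

    def predict(self, x: np.ndarray, clamp: bool = False) -> np.ndarray:
        """Forward pass for a (n, n_inputs) matrix or single vector."""
        arr = np.atleast_2d(np.asarray(x, dtype=float))
        if arr.shape[1] != self.n_inputs:
            raise ValueError(
                f"input has {arr.shape[1]} features, network expects {self.n_inputs}"
            )
        hidden = np.tanh(arr @ self.w1.T + self.b1)
        out = (hidden @ self.w2.T + self.b2).ravel()
        if clamp:
            out = np.clip(out, 0.0, 1.0)
        return out


@dataclass(frozen=True)
class TrainingReport:
    """Pearson-R success metrics of a training run."""

    r_train: float
    r_validation: float
    r_test: float
    r_all: float
    epochs: int
    stopping_reason: str
    mse_train: float = float("nan")
    mse_validation: float = float("nan")


def split_cohort(
    cohort: Sequence[PatientRecord], seed: int
) -> tuple[list[PatientRecord], list[PatientRecord], list[PatientRecord]]:
    """Random disjoint train/test/validation partition.

    A 268-patient cohort splits exactly 160/54/54; other sizes use the
    same proportions with test and validation rounded down and the
    remainder going to training.
    """
    n = len(cohort)
    if n < 3:
        raise ValueError("need at least 3 patients to split")
    n_test = int(n * SPLIT_REFERENCE[1] / sum(SPLIT_REFERENCE))
    n_val = n_test
    n_test = max(n_test, 1)
    n_val = max(n_val, 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_idx = order[: n - n_test - n_val]
    test_idx = order[n - n_test - n_val : n - n_val]
    val_idx = order[n - n_val :]
    pick = lambda idx: [cohort[i] for i in idx]
    return pick(train_idx), pick(test_idx), pick(val_idx)


def features(
    cohort: Sequence[PatientRecord],
    catalogue: Sequence[FactorDefinition],
    include_classification: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode a cohort into a feature matrix and class-value targets.

    Missing entries are imputed with 0.5.
    """
    rows, targets = [], []
    for patient in cohort:
        enc = encode_record(patient, catalogue)
        if enc.class_value is None:
            raise ValueError(
                f"patient {patient.record_id or '<unnamed>'} has no class label"
            )
        vec = np.where(enc.mask, enc.values, MISSING_FILL)
        if not include_classification:
            vec = vec[:-1]
        rows.append(vec)
        targets.append(enc.class_value)
    return np.array(rows), np.array(targets)


def forward(net: NetworkModel, encoded: EncodedRecord) -> tuple[float, float]:
    """Score one encoded record; returns (raw, clamped-to-[0,1])."""
    vec = np.where(encoded.mask, encoded.values, MISSING_FILL)
    if not net.include_classification:
        vec = vec[:-1]
    raw = float(net.predict(vec)[0])
    return raw, float(np.clip(raw, 0.0, 1.0))


def regression_r(outputs: Sequence[float], targets: Sequence[float]) -> float:
    """Pearson product-moment correlation between outputs and targets."""
    out = np.asarray(outputs, dtype=float)
    tgt = np.asarray(targets, dtype=float)
    if out.shape != tgt.shape or out.size < 2:
        raise ValueError("outputs and targets must be equal-length, size >= 2")
    if np.ptp(out) == 0 or np.ptp(tgt) == 0:
        raise ValueError("regression R undefined for a constant vector")
    return float(stats.pearsonr(out, tgt).statistic)


def _init_weights(rng: np.random.Generator, n_in: int, hidden: int):
    w1 = rng.standard_normal((hidden, n_in)) / np.sqrt(n_in)
    b1 = np.zeros(hidden)
    w2 = rng.standard_normal((1, hidden)) / np.sqrt(hidden)
    b2 = np.zeros(1)
    return w1, b1, w2, b2


def train(
    cohort: Sequence[PatientRecord],
    catalogue: Sequence[FactorDefinition],
    config: Optional[TrainConfig] = None,
) -> tuple[NetworkModel, TrainingReport]:
    """Backpropagation training with early stopping on validation MSE.

    The best-validation weights are restored before the report is
    computed, so the returned model is the early-stopped one.
    """
    config = config or TrainConfig()
    train_set, test_set, val_set = split_cohort(cohort, config.seed)
    x_tr, y_tr = features(train_set, catalogue, config.include_classification)
    x_te, y_te = features(test_set, catalogue, config.include_classification)
    x_va, y_va = features(val_set, catalogue, config.include_classification)
    x_all, y_all = features(cohort, catalogue, config.include_classification)

    rng = np.random.default_rng(config.seed)
    w1, b1, w2, b2 = _init_weights(rng, x_tr.shape[1], config.hidden_units)
    vel = [np.zeros_like(p) for p in (w1, b1, w2, b2)]
    best = (np.inf, [w1.copy(), b1.copy(), w2.copy(), b2.copy()], 0)
    wait = 0
    reason = "max_epochs"
    n = x_tr.shape[0]
    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        hidden = np.tanh(x_tr @ w1.T + b1)
        out = (hidden @ w2.T + b2).ravel()
        err = out - y_tr
        loss = float(np.mean(err**2))
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch} "
                f"(lr={config.learning_rate}, momentum={config.momentum})"
            )
        d_out = (2.0 / n) * err[:, None]  # (n, 1)
        g_w2 = d_out.T @ hidden
        g_b2 = d_out.sum(axis=0)
        d_hidden = (d_out @ w2) * (1.0 - hidden**2)
        g_w1 = d_hidden.T @ x_tr
        g_b1 = d_hidden.sum(axis=0)
        params = [w1, b1, w2, b2]
        for p, v, g in zip(params, vel, (g_w1, g_b1, g_w2, g_b2)):
            v *= config.momentum
            v -= config.learning_rate * g
            p += v

        val_out = (np.tanh(x_va @ w1.T + b1) @ w2.T + b2).ravel()
        val_mse = float(np.mean((val_out - y_va) ** 2))
        if val_mse < best[0] - 1e-12:
            best = (val_mse, [w1.copy(), b1.copy(), w2.copy(), b2.copy()], epoch)
            wait = 0
        else:
            wait += 1
            if wait >= config.patience:
                reason = "early_stopping"
                break

    w1, b1, w2, b2 = best[1]
    net = NetworkModel(
        w1=w1, b1=b1, w2=w2, b2=b2, seed=config.seed,
        include_classification=config.include_classification,
    )
    report = TrainingReport(
        r_train=regression_r(net.predict(x_tr), y_tr),
        r_validation=regression_r(net.predict(x_va), y_va),
        r_test=regression_r(net.predict(x_te), y_te),
        r_all=regression_r(net.predict(x_all), y_all),
        epochs=epoch,
        stopping_reason=reason,
        mse_train=float(np.mean((net.predict(x_tr) - y_tr) ** 2)),
        mse_validation=best[0],
    )
    return net, report


def save_network(path, net: NetworkModel, config: Optional[TrainConfig] = None):
    import json
    from pathlib import Path

    payload = {
        "format": "brcarisk-network-v1",
        "seed": net.seed,
        "include_classification": net.include_classification,
        "layers": {
            "w1": net.w1.tolist(),
            "b1": net.b1.tolist(),
            "w2": net.w2.tolist(),
            "b2": net.b2.tolist(),
        },
    }
    if config is not None:
        payload["config"] = {
            "hidden_units": config.hidden_units,
            "learning_rate": config.learning_rate,
            "momentum": config.momentum,
            "max_epochs": config.max_epochs,
            "patience": config.patience,
        }
    Path(path).write_text(json.dumps(payload) + "\n")


def load_network(path) -> NetworkModel:
    import json
    from pathlib import Path

    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "brcarisk-network-v1":
        raise ValueError(f"{path}: not a brcarisk network file")
    layers = payload["layers"]
    return NetworkModel(
        w1=np.array(layers["w1"]),
        b1=np.array(layers["b1"]),
        w2=np.array(layers["w2"]),
        b2=np.array(layers["b2"]),
        seed=payload.get("seed", 0),
        include_classification=payload.get("include_classification", True),
    )
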