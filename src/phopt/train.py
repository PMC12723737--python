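"""Training protocol: dev split, target scaling, mini-batch Adam on MSE.

Targets are rescaled as pH/14 before optimization and unscaled at inference.
The learning rate follows a step decay: it starts at 5e-4 and is halved every
10 epochs, so ``lr(e) = initial_lr * decay_factor ** floor(e / decay_every)``
exactly. The returned state is the snapshot with the best dev RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .embed import Embedder, embed_batch
from .exceptions import ContractError, TrainingError
from .io import LabeledRecord
from .metrics import mae, r_squared, rmse
from .network import (PH_SCALE, ModelConfig, ModelState, init_state,
                      mse_loss_and_grads, predict_batch)


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization hyperparameters (defaults are the published protocol)."""

    batch_size: int = 32
    initial_lr: float = 5e-4
    lr_decay_factor: float = 0.5
    lr_decay_every: int = 10
    n_epochs: int = 50
    dev_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.dev_fraction < 1.0:
            raise ContractError("dev_fraction must be in (0, 1)")
        if self.batch_size < 1 or self.n_epochs < 1:
            raise ContractError("batch_size and n_epochs must be >= 1")
        if (self.initial_lr <= 0 or self.lr_decay_factor <= 0
                or self.lr_decay_every <= 0):
            raise ContractError("learning-rate schedule parameters must be "
                                "positive")

    def lr_at(self, epoch: int) -> float:
        return self.initial_lr * self.lr_decay_factor ** (
            epoch // self.lr_decay_every)


def scale_target(ph: float | np.ndarray) -> float | np.ndarray:
    """pH -> network target on the [0, 1]-ish scale (divide by 14)."""
    return ph / PH_SCALE


def unscale_target(y: float | np.ndarray) -> float | np.ndarray:
    return y * PH_SCALE


def split_train_dev(records: Sequence[LabeledRecord], dev_fraction: float,
                    seed: int) -> tuple[list[LabeledRecord], list[LabeledRecord]]:
    """Seeded uniform-random disjoint exhaustive split.

    Dev size is ``round(dev_fraction * n)``; same seed gives the same split.
    """
    n = len(records)
    if n < 10:
        raise ContractError(f"need at least 10 records to split, got {n}")
    n_dev = int(round(dev_fraction * n))
    if n_dev < 1 or n_dev >= n:
        raise ContractError("dev_fraction leaves an empty train or dev set")
    perm = np.random.default_rng(seed).permutation(n)
    dev_idx = set(perm[:n_dev].tolist())
    train = [records[i] for i in range(n) if i not in dev_idx]
    dev = [records[i] for i in sorted(dev_idx)]
    return train, dev


class _Adam:
    """Adam with published defaults (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: dict[str, np.ndarray],
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)


def _length_bucketed_batches(records: Sequence[LabeledRecord],
                             batch_size: int) -> list[list[int]]:
    # sorting by length before chunking limits padding waste; output-neutral
    # because padding is provably inert (masked attention)
    order = sorted(range(len(records)), key=lambda i: len(records[i].sequence))
    return [order[s:s + batch_size] for s in range(0, len(order), batch_size)]


def train(model_config: ModelConfig, training_config: TrainingConfig,
          records: Sequence[LabeledRecord], embedder: Embedder,
          dev_records: Sequence[LabeledRecord] | None = None,
          ) -> tuple[ModelState, pd.DataFrame]:
    """Run the full training protocol.

    Splits off a dev set (unless one is passed explicitly), optimizes MSE on
    scaled targets with mini-batch Adam under the step-decay schedule, and
    returns the parameter snapshot with the lowest dev RMSE together with the
    per-epoch history (columns: epoch, lr, train_mse, dev_rmse, dev_mae,
    dev_r2). Fully reproducible given the seeds, data and config.
    """
    if not records:
        raise ContractError("no training records")
    if dev_records is None:
        train_recs, dev_recs = split_train_dev(
            records, training_config.dev_fraction, training_config.seed)
    else:
        train_recs, dev_recs = list(records), list(dev_records)

    state = init_state(model_config)
    opt = _Adam(state.params)
    rng = np.random.default_rng(training_config.seed + 1)

    # embed every training sequence once; fixture embeddings are cheap but
    # this also keeps the adapter path from recomputing per epoch
    batches = _length_bucketed_batches(train_recs, training_config.batch_size)
    batch_data = []
    for idx in batches:
        recs = [train_recs[i] for i in idx]
        r, mask = embed_batch(embedder, recs)
        t = np.array([scale_target(rec.ph_opt) for rec in recs])
        batch_data.append((r, mask, t))

    dev_true = np.array([rec.ph_opt for rec in dev_recs])

    history: list[dict] = []
    best_rmse = np.inf
    best_params = None
    for epoch in range(training_config.n_epochs):
        lr = training_config.lr_at(epoch)
        order = rng.permutation(len(batch_data))
        sq_sum, n_seen = 0.0, 0
        for bi in order:
            r, mask, t = batch_data[bi]
            loss, grads = mse_loss_and_grads(state, r, mask, t)
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}, batch {int(bi)}")
            opt.step(state.params, grads, lr)
            sq_sum += loss * len(t)
            n_seen += len(t)
        dev_pred = predict_batch(state, dev_recs, embedder, clamp=False)
        dev_r2 = r_squared(dev_true, dev_pred)
        row = {
            "epoch": epoch,
            "lr": lr,
            "train_mse": sq_sum / n_seen,
            "dev_rmse": rmse(dev_true, dev_pred),
            "dev_mae": mae(dev_true, dev_pred),
            "dev_r2": np.nan if dev_r2 is None else dev_r2,
        }
        history.append(row)
        if row["dev_rmse"] < best_rmse:
            best_rmse = row["dev_rmse"]
            best_params = {k: v.copy() for k, v in state.params.items()}

    assert best_params is not None
    return ModelState(model_config, best_params), pd.DataFrame(history)
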