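"""Joint two-task optimization and the experimental protocol.

The total loss is the convex combination L = λ·L_main + (1−λ)·L_aux of the
per-task mean binary cross-entropies (both tasks are multi-label, scored
per class through a logistic).  Protocol defaults: Adam, initial learning
rate 5e-4 reduced by a factor of 10 every 10 epochs, batch size 32, early
stop after 10 epochs without validation-loss improvement (best-epoch
weights restored).  Data splitting supports the recommended fold scheme
(folds 1–8 train / 9 validation / 10 test) and a seeded label-stratified
ten-fold partition.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .autodiff import Tensor, bce_with_logits
from .metrics import compute_report
from .model import ModelConfig, MultiTaskECGNet
from .nn import Adam
from .preprocessing import EcgRecord

__all__ = ["TrainingConfig", "joint_loss", "lr_at_epoch", "early_stop",
           "make_folds", "encode_labels", "train"]


@dataclass
class TrainingConfig:
    """Optimization protocol parameters (defaults follow the reference setup).

    ``lambda_weight`` balances main vs auxiliary loss; it is a free choice
    and defaults to the symmetric 0.5.
    """

    lambda_weight: float = 0.5
    lr0: float = 0.0005
    lr_decay_every: int = 10
    lr_decay_factor: float = 0.1
    batch_size: int = 32
    patience: int = 10
    max_epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.lambda_weight <= 1.0:
            raise ValueError("lambda_weight must lie in [0, 1]")
        if self.lr0 <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("invalid training configuration")

    def to_dict(self) -> dict:
        return asdict(self)


def joint_loss(main_scores, main_targets, aux_scores, aux_targets,
               lambda_weight: float) -> Tensor:
    """λ·L_main + (1−λ)·L_aux with per-task mean binary cross-entropy."""
    if not 0.0 <= lambda_weight <= 1.0:
        raise ValueError("lambda_weight must lie in [0, 1]")
    l_main = bce_with_logits(main_scores, main_targets)
    l_aux = bce_with_logits(aux_scores, aux_targets)
    return lambda_weight * l_main + (1.0 - lambda_weight) * l_aux


def lr_at_epoch(epoch: int, cfg: TrainingConfig) -> float:
    """Step schedule: lr0 · factor^floor(epoch / decay_every)."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    return cfg.lr0 * cfg.lr_decay_factor ** (epoch // cfg.lr_decay_every)


def early_stop(loss_history, patience: int) -> bool:
    """True iff the best loss lies ``patience`` or more epochs in the past."""
    history = list(loss_history)
    if not history:
        raise ValueError("loss history is empty")
    best_idx = int(np.argmin(history))  # first occurrence: ties do not improve
    return (len(history) - 1 - best_idx) >= patience


def make_folds(records: list[EcgRecord], scheme: str, seed: int = 0,
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(train, validation, test) index arrays.

    ``ptbxl_recommended``: use each record's fold tag; folds 1–8 train,
    fold 9 validation, fold 10 test.  ``stratified_10fold``: seeded
    label-stratified assignment of folds 1–10 (stratum = first main label),
    then the same 8/1/1 use of folds.
    """
    if scheme == "ptbxl_recommended":
        folds = []
        for r in records:
            if r.fold is None:
                raise ValueError(
                    f"record {r.record_id} has no fold tag; "
                    "the recommended scheme requires fold metadata")
            folds.append(r.fold)
        folds = np.asarray(folds)
    elif scheme == "stratified_10fold":
        # per-stratum shuffled round-robin deal into folds 1..10; unlike a
        # plain k-fold this tolerates classes rarer than the fold count
        rng = np.random.default_rng(seed)
        strata = np.asarray([min(r.main_labels) for r in records])
        folds = np.zeros(len(records), dtype=int)
        offset = 0
        for label in sorted(set(strata)):
            members = np.flatnonzero(strata == label)
            members = members[rng.permutation(len(members))]
            folds[members] = (offset + np.arange(len(members))) % 10 + 1
            offset += len(members)
    else:
        raise ValueError(f"unknown split scheme: {scheme!r}")
    idx = np.arange(len(records))
    return idx[folds <= 8], idx[folds == 9], idx[folds == 10]


def encode_labels(records: list[EcgRecord], classes, which: str = "main"
                  ) -> np.ndarray:
    """Multi-hot (N, C) target matrix from record label sets."""
    index = {c: i for i, c in enumerate(classes)}
    out = np.zeros((len(records), len(index)))
    for i, r in enumerate(records):
        for c in (r.main_labels if which == "main" else r.aux_labels):
            out[i, index[c]] = 1.0
    return out


def _epoch_eval(model, x, y_main, y_aux, lam, batch_size=128):
    """Validation total loss and main-task report, eval mode, no autodiff."""
    probs_main, probs_aux = model.predict_proba(x, batch_size=batch_size)
    eps = 1e-12

    def bce(p, y):
        return float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))

    loss = lam * bce(probs_main, y_main) + (1 - lam) * bce(probs_aux, y_aux)
    return loss, probs_main


def train(records: list[EcgRecord], model_cfg: ModelConfig,
          train_cfg: TrainingConfig, main_classes, aux_classes,
          scheme: str = "ptbxl_recommended"):
    """Fit the multi-task network; returns (model, per-epoch log, split).

    Records must be preprocessed to one common (leads, samples) shape and
    carry both label sets.  Fully seeded: identical inputs and seeds yield
    identical parameter trajectories.  The best-validation-loss weights are
    restored before returning.
    """
    if not records:
        raise ValueError("empty training set")
    if len(main_classes) != model_cfg.n_main_classes:
        raise ValueError("main head size does not match main class list")
    if len(aux_classes) != model_cfg.n_aux_classes:
        raise ValueError("aux head size does not match aux class list")
    shapes = {r.signal.shape for r in records}
    if len(shapes) != 1:
        raise ValueError("records are not preprocessed to a uniform shape")

    x = np.stack([r.signal for r in records])
    y_main = encode_labels(records, main_classes, "main")
    y_aux = encode_labels(records, aux_classes, "aux")
    train_idx, val_idx, test_idx = make_folds(records, scheme, train_cfg.seed)
    if len(train_idx) == 0:
        raise ValueError("empty training split")

    model = MultiTaskECGNet(model_cfg, seed=train_cfg.seed)
    opt = Adam(model.parameters(), lr=train_cfg.lr0)
    rng = np.random.default_rng(train_cfg.seed)
    lam = train_cfg.lambda_weight

    log_rows = []
    val_history: list[float] = []
    best_state = None
    best_loss = np.inf
    for epoch in range(train_cfg.max_epochs):
        opt.lr = lr_at_epoch(epoch, train_cfg)
        model.train()
        order = rng.permutation(train_idx)
        tot_main = tot_aux = 0.0
        n_batches = 0
        for start in range(0, len(order), train_cfg.batch_size):
            batch = order[start:start + train_cfg.batch_size]
            ms, as_ = model.forward(x[batch])
            l_main = bce_with_logits(ms, y_main[batch])
            l_aux = bce_with_logits(as_, y_aux[batch])
            loss = lam * l_main + (1.0 - lam) * l_aux
            opt.zero_grad()
            loss.backward()
            opt.step()
            tot_main += float(l_main.data)
            tot_aux += float(l_aux.data)
            n_batches += 1
        if len(val_idx):
            val_loss, val_probs = _epoch_eval(
                model, x[val_idx], y_main[val_idx], y_aux[val_idx], lam)
            try:
                val_f1 = compute_report(val_probs, y_main[val_idx],
                                        list(main_classes)).macro_f1
            except ValueError:
                val_f1 = float("nan")
        else:
            val_loss, val_f1 = float("nan"), float("nan")
        log_rows.append({
            "epoch": epoch, "lr": opt.lr,
            "train_loss_main": tot_main / n_batches,
            "train_loss_aux": tot_aux / n_batches,
            "train_loss_total": (lam * tot_main + (1 - lam) * tot_aux) / n_batches,
            "val_loss_total": val_loss, "val_macro_f1": val_f1,
        })
        if len(val_idx):
            val_history.append(val_loss)
            if val_loss < best_loss:
                best_loss = val_loss
                best_state = [a.copy() for a in model.state_arrays()]
            if early_stop(val_history, train_cfg.patience):
                break
    if best_state is not None:
        model.load_state_arrays(best_state)
    model.eval()
    log = pd.DataFrame(log_rows)
    split = {"train": train_idx, "val": val_idx, "test": test_idx}
    return model, log, split
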