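"""Training, evaluation and prediction on top of the model library.

`RunConfig` carries the model/loss/optimizer settings; its optimizer
defaults follow the reference recipe — batch size 12, Adam with learning
rate 1e-4 and weight decay 1e-4, or SGD with base learning rate 0.05,
momentum 0.9 and weight decay 1e-4.  Epoch counts and schedules are not
part of that recipe; the constant-LR default plus optional early
stopping on validation Dice is this package's choice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .losses import LossConfig, total_loss
from .metrics import (TTestReport, confusion_metrics, dsc_per_class, hd95,
                      paired_t_test)
from .model import ScaleFormer, ScaleFormerConfig
from .nn import SGD, Adam
from .exceptions import ConfigurationError

__all__ = ["RunConfig", "TrainResult", "train", "evaluate", "predict",
           "save_checkpoint", "load_checkpoint", "samples_to_arrays"]


@dataclass
class RunConfig:
    model: ScaleFormerConfig = field(default_factory=ScaleFormerConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    optimizer: str = "adam"          # "adam" or "sgd"
    learning_rate: float | None = None   # None -> optimizer default
    weight_decay: float = 1e-4
    momentum: float = 0.9            # SGD only
    batch_size: int = 12
    epochs: int = 10
    seed: int = 0
    early_stop_patience: int | None = None

    def resolved_lr(self) -> float:
        if self.learning_rate is not None:
            return self.learning_rate
        return {"adam": 1e-4, "sgd": 0.05}[self.optimizer]

    def make_optimizer(self, params):
        if self.optimizer == "adam":
            return Adam(params, lr=self.resolved_lr(),
                        weight_decay=self.weight_decay)
        if self.optimizer == "sgd":
            return SGD(params, lr=self.resolved_lr(),
                       momentum=self.momentum,
                       weight_decay=self.weight_decay)
        raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "loss": {
                "ce_weight": self.loss.ce_weight,
                "dice_weight": self.loss.dice_weight,
                "branch_weights": list(self.loss.branch_weights),
                "dice_eps": self.loss.dice_eps,
            },
            "optimizer": self.optimizer,
            "learning_rate": self.learning_rate,
            "weight_decay": self.weight_decay,
            "momentum": self.momentum,
            "batch_size": self.batch_size,
            "epochs": self.epochs,
            "seed": self.seed,
            "early_stop_patience": self.early_stop_patience,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        model = ScaleFormerConfig.from_dict(d.pop("model", {}))
        loss_d = d.pop("loss", {})
        loss = LossConfig(
            ce_weight=loss_d.get("ce_weight", 0.3),
            dice_weight=loss_d.get("dice_weight", 0.7),
            branch_weights=tuple(loss_d.get("branch_weights",
                                            (0.7, 0.1, 0.1, 0.1))),
            dice_eps=loss_d.get("dice_eps", 1e-5))
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(model=model, loss=loss, **known)


@dataclass
class TrainResult:
    model: ScaleFormer
    history: list
    best_val_dsc: float | None


def samples_to_arrays(samples):
    images = np.stack([s.image for s in samples]).astype(np.float32)
    masks = np.stack([s.mask for s in samples]).astype(np.int64)
    return images, masks


def train(cfg: RunConfig, train_samples, val_samples=None,
          checkpoint_path=None, log=None) -> TrainResult:
    """Optimize the deep-supervision loss; returns the model and history."""
    cfg.loss.validate()
    model = ScaleFormer(cfg.model, np.random.default_rng(cfg.seed))
    images, masks = samples_to_arrays(train_samples)
    n = len(images)
    rng = np.random.default_rng(cfg.seed + 1)
    optimizer = cfg.make_optimizer(model.parameters())
    history = []
    best_dsc, best_state, patience_left = -np.inf, None, cfg.early_stop_patience
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(n)
        epoch_losses, branch_sums = [], {}
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            bundle = model(Tensor(images[idx]))
            loss, breakdown = total_loss(bundle, masks[idx], cfg.loss)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss.data!r}, "
                    f"branches={breakdown}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(float(loss.data))
            for k, v in breakdown.items():
                branch_sums[k] = branch_sums.get(k, 0.0) + v
        record = {
            "epoch": epoch,
            "loss": float(np.mean(epoch_losses)),
            **{f"loss_{k}": v / max(1, len(epoch_losses))
               for k, v in branch_sums.items()},
        }
        if val_samples:
            val_dsc = _mean_foreground_dsc(model, val_samples)
            record["val_mean_dsc_pct"] = val_dsc
            if val_dsc > best_dsc:
                best_dsc, best_state = val_dsc, model.state_dict()
                patience_left = cfg.early_stop_patience
            elif cfg.early_stop_patience is not None:
                patience_left -= 1
        history.append(record)
        if log:
            log(" ".join(f"{k}={v:.4f}" if isinstance(v, float) else f"{k}={v}"
                         for k, v in record.items()))
        if val_samples and cfg.early_stop_patience is not None \
                and patience_left is not None and patience_left < 0:
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path, run_config=cfg.to_dict(),
                        history=history)
    return TrainResult(model=model, history=history,
                       best_val_dsc=(best_dsc if val_samples else None))


def predict(model: ScaleFormer, images: np.ndarray,
            batch_size: int = 8) -> np.ndarray:
    """Argmax class masks [B,H,W] from image batch [B,C,H,W]."""
    model.eval()
    out = []
    for start in range(0, len(images), batch_size):
        bundle = model(Tensor(images[start:start + batch_size]))
        out.append(np.argmax(bundle.main.data, axis=1))
    model.train()
    return np.concatenate(out).astype(np.uint8)


def _mean_foreground_dsc(model, samples) -> float:
    images, masks = samples_to_arrays(samples)
    preds = predict(model, images)
    K = model.config.num_classes
    scores = [dsc_per_class(p, m, K)[1:].mean() for p, m in zip(preds, masks)]
    return float(np.mean(scores))


def evaluate(model: ScaleFormer, samples, spacing=(1.0, 1.0),
             compare_model: ScaleFormer | None = None):
    """Per-case metrics table plus aggregates; optional paired comparison.

    Returns ``(per_case DataFrame, aggregates dict, TTestReport | None)``.
    DSC is reported in percent; HD95 in pixels (scaled by ``spacing``);
    mIoU/Acc/Sen/Spe use the foreground-vs-background binarization.
    """
    K = model.config.num_classes
    images, masks = samples_to_arrays(samples)
    preds = predict(model, images)
    rows = []
    for s, pred, mask in zip(samples, preds, masks):
        row = {"case": s.case_id}
        per_class = dsc_per_class(pred, mask, K)
        for c in range(K):
            row[f"dsc_class{c}"] = per_class[c]
        row["dsc_mean_fg"] = float(per_class[1:].mean())
        hd, flagged = hd95(pred != 0, mask != 0, spacing, return_flag=True)
        row["hd95"] = hd
        row["hd95_empty_flag"] = flagged
        row.update(confusion_metrics(pred != 0, mask != 0))
        rows.append(row)
    table = pd.DataFrame(rows)
    numeric = table.select_dtypes(include=[float, int])
    aggregates = {f"{k}_mean": float(v) for k, v in numeric.mean().items()}
    aggregates.update({f"{k}_std": float(v) for k, v in numeric.std().items()})
    report = None
    if compare_model is not None:
        if compare_model.config.num_classes != K:
            raise ConfigurationError(
                "cannot compare checkpoints with different class counts")
        other = predict(compare_model, images)
        a = [dsc_per_class(p, m, K)[1:].mean() / 100.0
             for p, m in zip(preds, masks)]
        b = [dsc_per_class(p, m, K)[1:].mean() / 100.0
             for p, m in zip(other, masks)]
        report = paired_t_test(a, b)
    return table, aggregates, report


# ---------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------

def save_checkpoint(model: ScaleFormer, path, run_config: dict | None = None,
                    history=None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "model_config": model.config.to_dict(),
        "run_config": run_config,
        "history": history,
    }
    state = model.state_dict()
    np.savez_compressed(path, __meta__=json.dumps(meta), **state)


def load_checkpoint(path):
    """Returns ``(model, metadata dict)`` with weights restored."""
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model = ScaleFormer(ScaleFormerConfig.from_dict(meta["model_config"]))
    model.load_state_dict(state)
    return model, meta
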