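"""Training loop, block-wise inference and run evaluation.

Training follows the published recipe: Adam, learning rate 0.03, batch size
2, the mixed cross-entropy + generalized-Dice objective, and early stopping
supervised by the validation metric (mean Dice over the three regions by
default) with a patience counter.  Inference runs a case through the same
geometric pipeline as training (standardize -> pad -> crop -> blockify),
feeds each depth block through the network, averages overlapping
predictions, thresholds at 0.5 and maps the result back to native case
geometry through the recorded sidecar.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .core_layers import Module
from .losses_metrics import (LossWeights, MetricError, metric_report,
                             mixed_loss, region_metrics, soft_dice)
from .networks import IResUnet3Plus, ModelSpec, build_model
from .preprocessing import (BlockSpec, CaseRecord, RegionMask,
                            preprocess_case_3d, reassemble_case_3d)


class TrainingError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    model_spec: ModelSpec = field(default_factory=ModelSpec)
    block_spec: BlockSpec = field(default_factory=BlockSpec)
    learning_rate: float = 0.03
    batch_size: int = 2
    max_epochs: int = 50
    patience: int = 10
    early_stop_metric: str = "dice"  # "dice" or "loss"
    loss_weights: LossWeights = field(default_factory=LossWeights)
    dice_weighting: str = "generalized"
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("positive learning rate and batch size required")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.early_stop_metric not in ("dice", "loss"):
            raise ValueError("early_stop_metric must be 'dice' or 'loss'")


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                np.float32)


def prepare_blocks(cases: list[CaseRecord], spec: BlockSpec
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Preprocess cases to stacked (B, 4, bd, ch, cw) image blocks and
    (B, 3, bd, ch, cw) region blocks."""
    imgs, regs = [], []
    for case in cases:
        ib, rb, _ = preprocess_case_3d(case, spec)
        imgs.extend(ib)
        regs.extend(rb)
    return (np.stack(imgs).astype(np.float32),
            np.stack(regs).astype(np.float32))


def _batch_loss(model: Module, x: np.ndarray, y: np.ndarray,
                cfg: TrainConfig) -> ad.Tensor:
    pred = model(x)
    return mixed_loss(pred, y, cfg.loss_weights, cfg.dice_weighting)


def train(config: TrainConfig,
          train_cases: list[CaseRecord],
          val_cases: list[CaseRecord],
          log_path: str | Path | None = None
          ) -> tuple[IResUnet3Plus, list[dict]]:
    """Train a model; returns (best model, per-epoch log).

    The best checkpoint (by the early-stopping metric) is restored into the
    returned model.  The log holds per-epoch train/val loss and val Dice.
    """
    if not train_cases or not val_cases:
        raise TrainingError("empty train or validation case list")
    rng = np.random.default_rng(config.seed)
    model = build_model(config.model_spec, seed=config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)

    x_train, y_train = prepare_blocks(train_cases, config.block_spec)
    x_val, y_val = prepare_blocks(val_cases, config.block_spec)

    best_state = model.state_dict()
    best_metric = -np.inf
    bad_epochs = 0
    log: list[dict] = []

    for epoch in range(config.max_epochs):
        model.train()
        order = rng.permutation(len(x_train))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            model.zero_grad()
            loss = _batch_loss(model, x_train[idx], y_train[idx], config)
            val = loss.item()
            if not np.isfinite(val):
                raise TrainingError(
                    f"non-finite training loss at epoch {epoch}: {val}")
            loss.backward()
            opt.step()
            losses.append(val)

        model.eval()
        val_losses, val_dices = [], []
        with ad.no_grad():
            for start in range(0, len(x_val), config.batch_size):
                xb = x_val[start:start + config.batch_size]
                yb = y_val[start:start + config.batch_size]
                pred = model(xb)
                val_losses.append(
                    mixed_loss(pred, yb, config.loss_weights,
                               config.dice_weighting).item())
                hard = pred.data >= config.threshold
                for c in range(yb.shape[1]):
                    val_dices.append(soft_dice(hard[:, c], yb[:, c] > 0.5))
        row = {
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "val_loss": float(np.mean(val_losses)),
            "val_dice": float(np.mean(val_dices)),
        }
        log.append(row)

        metric = row["val_dice"] if config.early_stop_metric == "dice" \
            else -row["val_loss"]
        if metric > best_metric:
            best_metric = metric
            best_state = model.state_dict()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break

    model.load_state_dict(best_state)
    if log_path is not None:
        write_log_csv(log, log_path)
    return model, log


def write_log_csv(log: list[dict], path: str | Path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(log[0].keys()))
        writer.writeheader()
        writer.writerows(log)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def predict_case(model, case: CaseRecord, block_spec: BlockSpec,
                 threshold: float = 0.5, batch_size: int = 2,
                 enforce_nesting: bool = True) -> RegionMask:
    """Block-wise inference mapped back to native case geometry.

    `model` is any callable taking a (N, 4, bd, ch, cw) float array and
    returning (N, 3, bd, ch, cw) probabilities (an IResUnet3Plus, or a stub
    in tests).  Overlapping block predictions are averaged, thresholded,
    placed back through the recorded crop/pad geometry; voxels outside the
    crop window are background.
    """
    image_blocks, _, sidecar = preprocess_case_3d(case, block_spec)
    x = np.stack(image_blocks).astype(np.float32)
    probs = []
    if isinstance(model, Module):
        model.eval()
    with ad.no_grad():
        for start in range(0, len(x), batch_size):
            out = model(x[start:start + batch_size])
            out = out.data if isinstance(out, ad.Tensor) else np.asarray(out)
            probs.extend(out)
    prob_vol = reassemble_case_3d(list(probs), sidecar)  # (3, D, H, W)
    hard = prob_vol >= threshold
    wt, tc, et = hard[0], hard[1], hard[2]
    if enforce_nesting:
        tc = tc & wt
        et = et & tc
    return RegionMask(wt=wt, tc=tc, et=et)


def evaluate_run(predictions: dict[str, RegionMask],
                 references: dict[str, RegionMask],
                 out_dir: str | Path | None = None,
                 hd_percentile: float | None = None) -> dict:
    """Per-case and aggregate Dice/SEN/HD per region.

    Writes a per-case CSV and a JSON summary when `out_dir` is given.
    """
    if not predictions:
        raise MetricError("empty prediction set")
    if set(predictions) != set(references):
        missing = set(predictions) ^ set(references)
        raise MetricError(f"unpaired case ids: {sorted(missing)}")
    per_case = {cid: region_metrics(predictions[cid], references[cid],
                                    hd_percentile=hd_percentile)
                for cid in sorted(predictions)}
    report = metric_report(per_case)
    report["per_case"] = per_case
    if out_dir is not None:
        import json

        import pandas as pd

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = [{"case_id": cid, "region": region, **vals}
                for cid, regions in per_case.items()
                for region, vals in regions.items()]
        pd.DataFrame(rows).to_csv(out_dir / "per_case_metrics.csv",
                                  index=False)
        (out_dir / "summary.json").write_text(json.dumps(report, indent=2))
    return report
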