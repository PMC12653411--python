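"""Training, prediction and dataset evaluation orchestration.

Training follows the recipe the model was designed with: multi-class soft
Dice loss summed over the Phase-1, Phase-2 and fused outputs, Adam at a base
learning rate of 1e-4 with polynomial decay over the full step budget,
batch size 16 for 224-sized inputs or 4 for 512-sized ones, and the
stochastic augmentation policy. All randomness (shuffling, augmentation,
parameter init) flows from the single configured seed; the run log records
one entry per epoch with train/validation accuracy, mean DSC and mean IoU
plus the loss and learning-rate traces.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.transform import resize as sk_resize

from . import io as gio
from .loss import deep_supervision_loss, one_hot
from .metrics import evaluate
from .network import GaadUNet, ModelConfig, load_checkpoint, save_checkpoint
from .nn import Adam
from .synth import AugmentationConfig, augment
from .tensor import Tensor, no_grad

__all__ = ["TrainConfig", "poly_lr", "train", "predict_masks",
           "evaluate_dataset", "resize_pair", "load_dataset"]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.999)
    poly_power: float = 0.9
    batch_size: int = 16
    epochs: int = 100
    loss_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    augmentation: AugmentationConfig | None = None
    teacher_forcing: bool = False  # gate Phase-2 input with the ground truth
    metrics_every: int = 1  # epochs between metric evaluations (0: final only)
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("batch_size and epochs must be >= 1 and "
                             "learning_rate positive")


def poly_lr(step: int, total_steps: int, base_lr: float,
            power: float = 0.9) -> float:
    """Polynomial decay base_lr · (1 − step/total)^power, clamped at 0."""
    if step < 0:
        raise ValueError("step must be nonnegative")
    frac = min(step / total_steps, 1.0)
    return base_lr * (1.0 - frac) ** power


def resize_pair(image: np.ndarray, mask: np.ndarray | None,
                size: tuple[int, int]):
    """Resize image (bilinear) and mask (nearest) to ``size``."""
    if image.shape[:2] != tuple(size):
        image = sk_resize(image, size, order=1, anti_aliasing=True,
                          preserve_range=True).astype(np.float32)
    if mask is not None and mask.shape != tuple(size):
        mask = sk_resize(mask, size, order=0, anti_aliasing=False,
                         preserve_range=True).astype(np.uint8)
    return image, mask


def load_dataset(data_dir, size: tuple[int, int] | None = None):
    """Load paired (image, mask) arrays from a dataset directory.

    Returns (pairs, skipped_image_paths); images without a mask are skipped.
    """
    file_pairs, missing = gio.list_pairs(data_dir)
    pairs = []
    for img_path, mask_path in file_pairs:
        img = gio.load_image(img_path)
        mask = gio.load_mask(mask_path)
        if size is not None:
            img, mask = resize_pair(img, mask, size)
        pairs.append((img, mask))
    return pairs, missing


def _to_batch(images, masks):
    x = np.stack([im.transpose(2, 0, 1) for im in images]).astype(np.float32)
    y = np.stack(masks).astype(np.uint8)
    return x, y


def train(pairs, model_cfg: ModelConfig, cfg: TrainConfig,
          val_pairs=None, checkpoint_path=None, log_path=None,
          verbose: bool = False):
    """Train a model on in-memory (image, mask) pairs.

    Returns (model, run_log). The checkpoint with the best validation mean
    DSC (training DSC when no validation split is given) is written to
    ``checkpoint_path`` if provided; the run log is a list of per-epoch
    records, also written as line-delimited JSON to ``log_path``.
    """
    if not pairs:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(cfg.seed)
    model = GaadUNet(model_cfg, seed=int(rng.integers(2 ** 31)))
    opt = Adam(model.parameters(), lr=cfg.learning_rate, betas=cfg.betas)
    n = len(pairs)
    steps_per_epoch = (n + cfg.batch_size - 1) // cfg.batch_size
    total_steps = cfg.epochs * steps_per_epoch
    run_log, step = [], 0
    best_dsc, best_state = -1.0, None

    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(n)
        epoch_losses, lr_trace = [], []
        for start in range(0, n, cfg.batch_size):
            batch_idx = order[start:start + cfg.batch_size]
            images, masks = [], []
            for i in batch_idx:
                img, msk = pairs[i]
                if cfg.augmentation is not None:
                    img, msk = augment(img, msk, cfg.augmentation, rng)
                images.append(img)
                masks.append(msk)
            x, y = _to_batch(images, masks)
            gt_gate = Tensor(one_hot(y, model_cfg.num_classes)) \
                if cfg.teacher_forcing else None
            final, out1, out2 = model(Tensor(x), gt_onehot=gt_gate)
            loss = deep_supervision_loss(final, out1, out2, y,
                                         cfg.loss_weights)
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {step}; "
                    "aborting (check learning rate / data normalization)")
            opt.zero_grad()
            loss.backward()
            lr = poly_lr(step, total_steps, cfg.learning_rate, cfg.poly_power)
            opt.step(lr=lr)
            epoch_losses.append(loss.item())
            lr_trace.append(lr)
            step += 1
        record = {"epoch": epoch, "loss": float(np.mean(epoch_losses)),
                  "lr": lr_trace, "seed": cfg.seed}
        last_epoch = epoch == cfg.epochs - 1
        if last_epoch or (cfg.metrics_every and epoch % cfg.metrics_every == 0):
            record.update(_split_metrics(model, pairs, "train"))
            if val_pairs:
                record.update(_split_metrics(model, val_pairs, "val"))
            monitor = record.get("val_mean_dsc", record["train_mean_dsc"])
            if monitor > best_dsc:
                best_dsc = monitor
                best_state = {k: v.copy()
                              for k, v in model.state_dict().items()}
        run_log.append(record)
        if verbose:
            print(json.dumps({k: v for k, v in record.items() if k != "lr"}))

    if best_state is not None:
        model.load_state_dict(best_state)
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, model,
                        extra={"best_dsc": best_dsc, "train_config": asdict(cfg)})
    if log_path is not None:
        with open(log_path, "w") as fh:
            for rec in run_log:
                fh.write(json.dumps(rec) + "\n")
    return model, run_log


def _split_metrics(model, pairs, prefix):
    reports = [evaluate(pred, msk) for pred, msk in
               zip(predict_masks(model, [im for im, _ in pairs]),
                   [msk for _, msk in pairs])]
    return {f"{prefix}_accuracy": float(np.mean([r.accuracy for r in reports])),
            f"{prefix}_mean_dsc": float(np.mean([r.mean_dsc for r in reports])),
            f"{prefix}_mean_iou": float(np.mean([r.mean_iou for r in reports]))}


def predict_masks(model: GaadUNet, images, batch_size: int = 4):
    """Predicted class masks for (H, W, 3) float images."""
    out = []
    for start in range(0, len(images), batch_size):
        x = np.stack([im.transpose(2, 0, 1)
                      for im in images[start:start + batch_size]])
        out.extend(model.predict(Tensor(x.astype(np.float32))))
    return out


def evaluate_dataset(model: GaadUNet, data_dir, out_prefix=None,
                     include_background: bool = True,
                     size: tuple[int, int] | None = None):
    """Evaluate a checkpointed model over a paired dataset directory.

    Returns (per_image_reports, summary, skipped). Writes ``<prefix>.json``
    and ``<prefix>.csv`` (one row per image plus a summary row) when
    ``out_prefix`` is given.
    """
    pairs, missing = gio.list_pairs(data_dir)
    per_image, skipped = [], [str(p) for p in missing]
    for img_path, mask_path in pairs:
        img = gio.load_image(img_path)
        gt = gio.load_mask(mask_path)
        if size is not None:
            img, gt = resize_pair(img, gt, size)
        pred = predict_masks(model, [img])[0]
        rep = evaluate(pred, gt, include_background=include_background)
        row = {"image": img_path.name}
        row.update(rep.to_dict())
        per_image.append(row)
    summary = _summarize(per_image)
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        payload = {"per_image": per_image, "summary": summary,
                   "skipped_images": skipped}
        out_prefix.with_suffix(".json").write_text(json.dumps(payload, indent=2))
        _write_csv(out_prefix.with_suffix(".csv"), per_image, summary)
    return per_image, summary, skipped


def _summarize(per_image):
    summary = {"image": "summary"}
    if not per_image:
        return summary
    keys = [k for k, v in per_image[0].items()
            if isinstance(v, (int, float)) and not isinstance(v, bool)]
    for k in keys:
        vals = [r[k] for r in per_image if r[k] is not None]
        summary[k] = float(np.mean(vals)) if vals else None
    return summary


def _write_csv(path, per_image, summary):
    fields = list(per_image[0].keys()) if per_image else list(summary.keys())
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields, extrasaction="ignore")
        writer.writeheader()
        for row in per_image:
            writer.writerow(row)
        writer.writerow(summary)
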