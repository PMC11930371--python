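"""Training, evaluation and prediction orchestration.

The training recipe: Adam with weight decay 1e-6, batch size 4, initial
learning rate 1e-3 annealed per epoch along a single half-cosine,

    lr(t) = eta_min + 0.5 * (lr0 - eta_min) * (1 + cos(pi * t / T)),

default 300 epochs. Everything that consumes randomness (weight
initialization, data order, augmentation) is driven by the configured seeds,
so two runs with identical configuration produce identical history CSVs.
The best-validation-DSC checkpoint and the last checkpoint are both kept;
checkpoints carry a format-version string, both configurations and the
optimizer state, so runs are resumable.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import preprocess as pp
from .engine import Adam, Tensor, no_grad
from .errors import ConfigurationError
from .losses import LossConfig, combined_loss
from .metrics import BoundaryConfig, ConfusionCounts, MetricReport, confusion_counts, dsc, evaluate_pairs, iou
from .network import ModelConfig, SegmentationModel, build_model
from .phantom import read_manifest

logger = logging.getLogger(__name__)

CHECKPOINT_FORMAT = "cseanet-checkpoint-1"
HISTORY_COLUMNS = ("epoch", "lr", "train_loss", "val_loss", "val_dsc", "val_iou")


@dataclass
class TrainConfig:
    epochs: int = 300
    batch_size: int = 4
    lr0: float = 1e-3
    eta_min: float = 0.0
    weight_decay: float = 1e-6
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    augment_prob: float = 0.5
    augment_strength: float = 0.2
    threshold: float = 0.5
    checkpoint_every: int = 0  # extra periodic checkpoints; 0 = best/last only

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__ if k != "loss"}
        d["loss"] = {"dice_smoothing": self.loss.dice_smoothing,
                     "dice_weight": self.loss.dice_weight, "eps": self.loss.eps}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        loss = d.pop("loss", None)
        cfg = cls(**d)
        if loss:
            cfg.loss = LossConfig(**loss)
        return cfg


def cosine_lr(t: int, T: int, lr0: float, eta_min: float = 0.0) -> float:
    """Cosine-annealed learning rate at epoch t of T (no warm restarts)."""
    if T < 1:
        raise ValueError("total epochs must be >= 1")
    if t < 0:
        raise ValueError("epoch index must be >= 0")
    if t > T:
        warnings.warn(f"epoch {t} beyond schedule end {T}; clamping to eta_min")
        return eta_min
    return eta_min + 0.5 * (lr0 - eta_min) * (1.0 + np.cos(np.pi * t / T))


# -- data -----------------------------------------------------------------


def load_sample(record: pp.SampleRecord, patch_size: int | None = None):
    """Read one manifest record into a ((3,H,W) float32, (H,W) uint8) pair."""
    ct = pp.read_image(record.image)
    if isinstance(ct, list):
        ct = ct[record.row]
    x = pp.to_three_channel(pp.normalize(pp.clip_hu(ct)))
    y = pp.read_mask(record.mask)
    if patch_size is not None:
        x = pp.crop_patch(x, record, patch_size)
        y = pp.crop_patch(y, record, patch_size)
    return x, y.astype(np.float32)


def _load_split(records, split: str, patch_size=None):
    subset = [r for r in records if r.split == split]
    return [load_sample(r, patch_size) for r in subset], subset


def _batches(samples, batch_size, rng=None):
    idx = np.arange(len(samples))
    if rng is not None:
        rng.shuffle(idx)
    for start in range(0, len(idx), batch_size):
        chunk = idx[start : start + batch_size]
        xs = np.stack([samples[i][0] for i in chunk])
        ys = np.stack([samples[i][1] for i in chunk])[:, None, :, :]
        yield xs, ys


# -- checkpointing --------------------------------------------------------


def save_checkpoint(path, model: SegmentationModel, train_cfg: TrainConfig,
                    optimizer: Adam | None = None, epoch: int = 0,
                    best_dsc: float = -1.0) -> None:
    meta = {
        "format": CHECKPOINT_FORMAT,
        "model_cfg": model.cfg.to_dict(),
        "train_cfg": train_cfg.to_dict(),
        "epoch": epoch,
        "best_dsc": best_dsc,
    }
    arrays = {f"model/{k}": v for k, v in model.state_dict().items()}
    if optimizer is not None:
        arrays.update({f"optim/{k}": v for k, v in optimizer.state_dict().items()})
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path):
    """Return (model, train_cfg, optim_state, epoch, best_dsc)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if meta.get("format") != CHECKPOINT_FORMAT:
            raise ConfigurationError(
                f"checkpoint format {meta.get('format')!r} does not match {CHECKPOINT_FORMAT!r}"
            )
        model = build_model(ModelConfig.from_dict(meta["model_cfg"]))
        model.load_state_dict({k[len("model/"):]: data[k] for k in data.files
                               if k.startswith("model/")})
        optim_state = {k[len("optim/"):]: data[k] for k in data.files
                       if k.startswith("optim/")}
    train_cfg = TrainConfig.from_dict(meta["train_cfg"])
    return model, train_cfg, optim_state or None, int(meta["epoch"]), float(meta["best_dsc"])


# -- training -------------------------------------------------------------


def train_step(model, optimizer, xs, ys, loss_cfg: LossConfig) -> float:
    """One optimization step on a batch; returns the scalar loss."""
    model.train()
    logits = model(Tensor(xs), logits=True)
    loss = combined_loss(logits, Tensor(ys), cfg=loss_cfg, from_logits=True)
    optimizer.zero_grad()
    loss.backward()
    optimizer.step()
    return loss.item()


def _validate(model, samples, batch_size, loss_cfg, threshold):
    model.eval()
    losses = []
    total = ConfusionCounts()
    with no_grad():
        for xs, ys in _batches(samples, batch_size):
            logits = model(Tensor(xs), logits=True)
            losses.append(combined_loss(logits, Tensor(ys), cfg=loss_cfg,
                                        from_logits=True).item())
            probs = 1.0 / (1.0 + np.exp(-logits.data))
            pred = (probs >= threshold).astype(np.uint8)
            for b in range(pred.shape[0]):
                total = total + confusion_counts(pred[b, 0], ys[b, 0].astype(np.uint8))
    return float(np.mean(losses)) if losses else float("nan"), dsc(total), iou(total)


def train(model_cfg: ModelConfig, train_cfg: TrainConfig, manifest,
          out_dir, patch_size: int | None = None,
          resume_from=None) -> dict:
    """Train per the recipe; returns {'history': rows, 'best': path, 'last': path}.

    ``manifest`` is a manifest CSV path or a list of SampleRecords with
    train/val split labels already assigned.
    """
    records = read_manifest(manifest) if isinstance(manifest, (str, Path)) else list(manifest)
    train_samples, _ = _load_split(records, "train", patch_size)
    val_samples, _ = _load_split(records, "val", patch_size)
    if not train_samples or not val_samples:
        raise ConfigurationError("manifest must contain non-empty train and val splits")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    start_epoch, best_dsc = 0, -1.0
    if resume_from is not None:
        model, prev_cfg, optim_state, start_epoch, best_dsc = load_checkpoint(resume_from)
        if prev_cfg.to_dict() != train_cfg.to_dict():
            raise ConfigurationError("resume checkpoint was trained with a different TrainConfig")
        optimizer = Adam(model.parameters(), lr=train_cfg.lr0,
                         weight_decay=train_cfg.weight_decay)
        if optim_state:
            optimizer.load_state_dict(optim_state)
    else:
        model = build_model(model_cfg)
        optimizer = Adam(model.parameters(), lr=train_cfg.lr0,
                         weight_decay=train_cfg.weight_decay)

    history_path = out_dir / "history.csv"
    mode = "a" if (resume_from is not None and history_path.exists()) else "w"
    history_rows = []
    with open(history_path, mode, newline="") as fh:
        writer = csv.writer(fh)
        if mode == "w":
            writer.writerow(HISTORY_COLUMNS)
        for epoch in range(start_epoch, train_cfg.epochs):
            lr = cosine_lr(epoch, train_cfg.epochs, train_cfg.lr0, train_cfg.eta_min)
            optimizer.lr = lr
            rng = np.random.default_rng(train_cfg.seed + 1000 * epoch)
            epoch_samples = _augmented(train_samples, train_cfg, rng)
            losses = [train_step(model, optimizer, xs, ys, train_cfg.loss)
                      for xs, ys in _batches(epoch_samples, train_cfg.batch_size, rng)]
            val_loss, val_dsc, val_iou = _validate(model, val_samples, train_cfg.batch_size,
                                                   train_cfg.loss, train_cfg.threshold)
            row = [epoch, f"{lr:.8g}", f"{np.mean(losses):.6f}", f"{val_loss:.6f}",
                   f"{val_dsc:.6f}", f"{val_iou:.6f}"]
            writer.writerow(row)
            fh.flush()
            history_rows.append(row)
            logger.info("epoch %d lr %.2e train %.4f val %.4f dsc %.4f",
                        epoch, lr, np.mean(losses), val_loss, val_dsc)
            if val_dsc > best_dsc:
                best_dsc = val_dsc
                save_checkpoint(out_dir / "best.npz", model, train_cfg, optimizer,
                                epoch + 1, best_dsc)
            if train_cfg.checkpoint_every and (epoch + 1) % train_cfg.checkpoint_every == 0:
                save_checkpoint(out_dir / f"epoch_{epoch + 1:04d}.npz", model, train_cfg,
                                optimizer, epoch + 1, best_dsc)
            save_checkpoint(out_dir / "last.npz", model, train_cfg, optimizer,
                            epoch + 1, best_dsc)
    return {"history": history_rows, "best": out_dir / "best.npz",
            "last": out_dir / "last.npz", "best_dsc": best_dsc, "model": model}


def _augmented(samples, train_cfg: TrainConfig, rng):
    if train_cfg.augment_prob <= 0 or train_cfg.augment_strength <= 0:
        return samples
    out = []
    for x, y in samples:
        if rng.random() < train_cfg.augment_prob:
            x = pp.hsv_luminance_augment(x, train_cfg.augment_strength, rng)
        out.append((x, y))
    return out


def overfit_one_batch(model_cfg: ModelConfig, xs, ys, steps: int = 200,
                      lr: float = 3e-3, weight_decay: float = 1e-6) -> list[float]:
    """Debug-mode sanity run: repeated steps on a single batch.

    A correctly wired model with healthy gradients drives the combined loss
    well below 0.1; a broken skip path or dead gradient shows up immediately.
    The default learning rate is more aggressive than the training recipe's
    because the goal here is to memorize one batch quickly.
    """
    model = build_model(model_cfg)
    optimizer = Adam(model.parameters(), lr=lr, weight_decay=weight_decay)
    cfg = LossConfig()
    return [train_step(model, optimizer, xs, ys, cfg) for _ in range(steps)]


# -- evaluation / prediction ---------------------------------------------


def evaluate(checkpoint, manifest, split: str = "test", threshold: float = 0.5,
             boundary_cfg: BoundaryConfig | None = None,
             patch_size: int | None = None) -> MetricReport:
    """Deterministic metric report (inference mode, no augmentation)."""
    model, train_cfg, *_ = load_checkpoint(checkpoint)
    records = read_manifest(manifest) if isinstance(manifest, (str, Path)) else list(manifest)
    subset = [r for r in records if r.split == split]
    pairs = []
    model.eval()
    with no_grad():
        for r in subset:
            try:
                x, y = load_sample(r, patch_size)
            except (OSError, ValueError) as exc:
                logger.warning("skipping %s: %s", r.case_id, exc)
                pairs.append((r.case_id, None, None))
                continue
            prob = model(Tensor(x[None])).data[0, 0]
            pairs.append((r.case_id, prob, y.astype(np.uint8)))
    loss_fn = lambda p, t: combined_loss(p.astype(np.float64), t.astype(np.float64),
                                         cfg=train_cfg.loss)
    return evaluate_pairs(pairs, threshold=threshold, boundary_cfg=boundary_cfg,
                          loss_fn=loss_fn)


def predict(checkpoint, image_path, out_path, threshold: float = 0.5,
            prob_path=None) -> np.ndarray:
    """Segment one image and write the binary mask aligned to its geometry."""
    model, *_ = load_checkpoint(checkpoint)
    ct = pp.read_image(image_path)
    if isinstance(ct, list):
        ct = ct[0]
    x = pp.to_three_channel(pp.normalize(pp.clip_hu(ct)))
    H, W = x.shape[-2:]
    div = model.cfg.spatial_divisor
    ph = (-H) % div
    pw = (-W) % div
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, ph), (0, pw)))
    model.eval()
    with no_grad():
        prob = model(Tensor(x[None])).data[0, 0][:H, :W]
    mask = (prob >= threshold).astype(np.uint8)
    pp.write_mask(out_path, mask, affine=ct.affine)
    if prob_path is not None:
        np.save(prob_path, prob)
    return mask
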