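"""Training recipe, augmentation, evaluation metrics and profiling.

The optimisation recipe is fixed across every experiment: Adam at an
initial learning rate of 1e-3 annealed to zero on a cosine schedule,
weight decay 1e-5, global gradient-norm clipping at 5.0, batch size 32,
up to 120 epochs with early stopping after 12 epochs without validation
improvement, and the static 0.4/0.3/0.3 multi-task loss weights.  A
stratified 10 % slice of the training split serves as the validation set
for early stopping; the test split is never touched during training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.metrics import accuracy_score, f1_score

from .model import FusionModel, LossWeights, total_loss
from .nn.optim import Adam, clip_grad_norm, cosine_lr
from .nn.tensor import Tensor, softmax
from .profiling import count_macs, count_params
from .sensors import (
    StandardizationStats,
    align_by_tree_id,
    default_schema,
    encode_features,
    fit_standardization,
    impute_missing,
    invert_target_standardization,
    stratified_split,
)

__all__ = [
    "TrainConfig",
    "ArrayDataset",
    "MetricsReport",
    "TrainResult",
    "augment",
    "load_image",
    "prepare_datasets",
    "train",
    "evaluate",
    "profile",
]


@dataclass
class TrainConfig:
    lr: float = 1e-3
    weight_decay: float = 1e-5
    grad_clip: float = 5.0
    batch_size: int = 32
    max_epochs: int = 120
    patience: int = 12
    loss_weights: LossWeights = field(default_factory=LossWeights)
    val_fraction: float = 0.10
    augment: bool = True
    seed: int = 0

    def __post_init__(self):
        if min(self.lr, self.grad_clip, self.batch_size, self.max_epochs,
               self.patience, self.val_fraction) <= 0:
            raise ValueError("training configuration values must be positive")
        if self.patience >= self.max_epochs:
            raise ValueError("early-stopping patience must be below max epochs")


@dataclass
class ArrayDataset:
    """In-memory paired dataset: images are raw uint8 HWC, sensors are the
    encoded standardized feature matrix, gas targets carried on both the
    original and the z-scored scale."""

    ids: np.ndarray
    images: np.ndarray | None
    sensors: np.ndarray | None
    labels: np.ndarray
    o2_std: np.ndarray
    co2_std: np.ndarray
    o2_orig: np.ndarray
    co2_orig: np.ndarray

    def __len__(self):
        return len(self.labels)


@dataclass
class MetricsReport:
    accuracy: float
    macro_f1: float
    per_class_f1: tuple
    o2_mae: float
    o2_rmse: float
    co2_mae: float
    co2_rmse: float
    n_params: int | None = None
    n_macs: int | None = None
    latency_ms: float | None = None  # informational only

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}


@dataclass
class TrainResult:
    history: list
    best_state: dict
    best_epoch: int
    best_val_total: float
    stopped_early: bool


# ---------------------------------------------------------------------------
# augmentation


def augment(images: np.ndarray, rng: np.random.Generator,
            crop_scale=(0.8, 1.0), flip_prob: float = 0.5,
            brightness=(0.8, 1.2), contrast=(0.8, 1.2)) -> np.ndarray:
    """Stochastic training-time augmentation of a uint8 (N, H, W, 3) batch.

    Random area crop (resized back to the model resolution), horizontal
    flip, and multiplicative brightness / mean-anchored contrast jitter.
    Returns float32 in [0, 1].  With the ranges pinned to 1 and flips off
    the transform is the identity; fully deterministic for a fixed ``rng``.
    """
    n, h, w, _ = images.shape
    out = np.empty((n, h, w, 3), dtype=np.float32)
    for i in range(n):
        img = images[i]
        scale = rng.uniform(*crop_scale)
        side = max(1, int(round(h * np.sqrt(scale))))
        top = rng.integers(0, h - side + 1)
        left = rng.integers(0, w - side + 1)
        crop = img[top:top + side, left:left + side]
        if side != h:
            crop = np.asarray(
                Image.fromarray(crop).resize((w, h), Image.BILINEAR))
        if rng.uniform() < flip_prob:
            crop = crop[:, ::-1]
        x = crop.astype(np.float32) / 255.0
        x = x * rng.uniform(*brightness)
        c = rng.uniform(*contrast)
        mean = x.mean()
        x = mean + (x - mean) * c
        out[i] = np.clip(x, 0.0, 1.0)
    return out


def load_image(path, resolution: int | None = None,
               fill: int = 0) -> np.ndarray:
    """Read a tree image, applying an optional binary mask.

    If ``<path stem>.mask.png`` exists beside the image, background pixels
    (mask value 0) are set to the constant ``fill`` before any resizing, so
    the model only ever sees the isolated tree structure.  Returns uint8
    (H, W, 3).
    """
    path = Path(path)
    arr = np.asarray(Image.open(path).convert("RGB"))
    mask_path = path.parent / (path.stem + ".mask.png")
    if mask_path.exists():
        mask = np.asarray(Image.open(mask_path).convert("L")) > 0
        arr = np.where(mask[..., None], arr, np.uint8(fill))
    if resolution is not None and arr.shape[:2] != (resolution, resolution):
        arr = np.asarray(Image.fromarray(arr).resize(
            (resolution, resolution), Image.BILINEAR))
    return arr


def to_model_input(images01: np.ndarray, img_mean: np.ndarray,
                   img_sd: np.ndarray) -> np.ndarray:
    """Channel-standardize [0,1] NHWC images and convert to NCHW float32."""
    x = (images01 - img_mean.reshape(1, 1, 1, 3)) / img_sd.reshape(1, 1, 1, 3)
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2)).astype(np.float32)


# ---------------------------------------------------------------------------
# dataset preparation


@dataclass
class PreparedData:
    train: ArrayDataset
    test: ArrayDataset
    stats: StandardizationStats
    img_mean: np.ndarray
    img_sd: np.ndarray
    sensor_dim: int


def prepare_datasets(dataset_dir, seed: int = 0, test_fraction: float = 0.2,
                     schema=None) -> PreparedData:
    """Full preprocessing pipeline from a dataset directory.

    Aligns images and sensor rows by tree ID, splits 80/20 stratified on the
    health class, imputes, encodes and standardizes with statistics fit on
    the training split only, and estimates image channel statistics from the
    training images.
    """
    schema = schema or default_schema()
    dataset_dir = Path(dataset_dir)
    sensors = pd.read_csv(dataset_dir / "sensors.csv")
    manifest = pd.read_csv(dataset_dir / "manifest.csv")
    paired, dropped = align_by_tree_id(manifest, sensors)
    if dropped:
        print(f"[prepare] dropped unmatched tree IDs: {dropped}")
    train_df, test_df = stratified_split(paired, "health_class",
                                         test_fraction=test_fraction, seed=seed)
    train_df = impute_missing(train_df, schema)
    test_df = impute_missing(test_df, schema)
    stats = fit_standardization(train_df, schema)

    def build(df) -> ArrayDataset:
        feats = encode_features(df, schema, stats).astype(np.float32)
        images = np.stack([load_image(dataset_dir / p)
                           for p in df["image_path"]])
        o2 = df["O2_rate"].to_numpy(dtype=np.float64)
        co2 = df["CO2_rate"].to_numpy(dtype=np.float64)
        return ArrayDataset(
            ids=df["tree_id"].to_numpy(),
            images=images,
            sensors=feats,
            labels=df["health_class"].to_numpy(dtype=np.int64),
            o2_std=((o2 - stats.target_mean["O2_rate"])
                    / stats.target_sd["O2_rate"]).astype(np.float32),
            co2_std=((co2 - stats.target_mean["CO2_rate"])
                     / stats.target_sd["CO2_rate"]).astype(np.float32),
            o2_orig=o2, co2_orig=co2,
        )

    train_ds = build(train_df)
    test_ds = build(test_df)
    train01 = train_ds.images.astype(np.float32) / 255.0
    img_mean = train01.mean(axis=(0, 1, 2))
    img_sd = np.maximum(train01.std(axis=(0, 1, 2)), 1e-6)
    return PreparedData(train_ds, test_ds, stats, img_mean, img_sd,
                        sensor_dim=train_ds.sensors.shape[1])


def split_validation(ds: ArrayDataset, fraction: float, seed: int):
    """Carve a stratified validation slice out of a training dataset."""
    from sklearn.model_selection import train_test_split as _tts
    idx_train, idx_val = _tts(np.arange(len(ds)), test_size=fraction,
                              stratify=ds.labels, random_state=seed)
    idx_train, idx_val = np.sort(idx_train), np.sort(idx_val)

    def take(idx):
        return ArrayDataset(
            ids=ds.ids[idx],
            images=None if ds.images is None else ds.images[idx],
            sensors=None if ds.sensors is None else ds.sensors[idx],
            labels=ds.labels[idx],
            o2_std=ds.o2_std[idx], co2_std=ds.co2_std[idx],
            o2_orig=ds.o2_orig[idx], co2_orig=ds.co2_orig[idx])

    return take(idx_train), take(idx_val)


# ---------------------------------------------------------------------------
# training loop


def _model_inputs(model: FusionModel, ds: ArrayDataset, idx,
                  img_mean, img_sd, rng=None, do_augment=False):
    images = sensors = None
    if model.backbone is not None:
        raw = ds.images[idx]
        if do_augment:
            imgs01 = augment(raw, rng)
        else:
            imgs01 = raw.astype(np.float32) / 255.0
        images = to_model_input(imgs01, img_mean, img_sd)
    if model.mlp is not None:
        sensors = ds.sensors[idx]
    return images, sensors


def _batch_losses(model, ds, idx, img_mean, img_sd, weights,
                  rng=None, do_augment=False):
    images, sensors = _model_inputs(model, ds, idx, img_mean, img_sd,
                                    rng=rng, do_augment=do_augment)
    out = model(images=images, sensors=sensors)
    return out, total_loss(out, labels=ds.labels[idx],
                           o2_targets=ds.o2_std[idx],
                           co2_targets=ds.co2_std[idx], weights=weights)


def _eval_pass(model, ds, img_mean, img_sd, weights, batch_size=64):
    """Inference-mode loss components + accuracy over a whole dataset."""
    model.eval()
    sums = {}
    n_total = 0
    correct = 0
    for lo in range(0, len(ds), batch_size):
        idx = np.arange(lo, min(lo + batch_size, len(ds)))
        out, losses = _batch_losses(model, ds, idx, img_mean, img_sd, weights)
        bs = len(idx)
        n_total += bs
        for k, v in losses.items():
            sums[k] = sums.get(k, 0.0) + float(v.data) * bs
        if "logits" in out:
            correct += int((out["logits"].data.argmax(axis=1) == ds.labels[idx]).sum())
    model.train()
    result = {k: v / n_total for k, v in sums.items()}
    result["accuracy"] = correct / n_total if "logits" in out else float("nan")
    return result


def train(model: FusionModel, train_ds: ArrayDataset, val_ds: ArrayDataset,
          cfg: TrainConfig, img_mean=None, img_sd=None,
          verbose: bool = False) -> TrainResult:
    """Optimise the multi-task objective with the fixed recipe.

    Keeps the parameter set with the lowest validation total loss; stops
    once ``cfg.patience`` consecutive epochs fail to improve it.  Two runs
    with identical seeds and data produce identical histories.
    """
    img_mean = np.zeros(3) if img_mean is None else img_mean
    img_sd = np.ones(3) if img_sd is None else img_sd
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    weights = cfg.loss_weights
    history = []
    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = -1
    bad_epochs = 0
    stopped_early = False

    model.train()
    for epoch in range(cfg.max_epochs):
        lr = cosine_lr(cfg.lr, epoch, cfg.max_epochs)
        opt.lr = lr
        perm = rng.permutation(len(train_ds))
        epoch_sums: dict[str, float] = {}
        n_seen = 0
        for lo in range(0, len(perm), cfg.batch_size):
            idx = perm[lo:lo + cfg.batch_size]
            _, losses = _batch_losses(model, train_ds, idx, img_mean, img_sd,
                                      weights, rng=rng,
                                      do_augment=cfg.augment)
            lt = losses["total"]
            if not np.isfinite(lt.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {lo // cfg.batch_size}: "
                    f"{ {k: float(v.data) for k, v in losses.items()} }")
            opt.zero_grad()
            lt.backward()
            clip_grad_norm(model.parameters(), cfg.grad_clip)
            opt.step()
            for k, v in losses.items():
                epoch_sums[k] = epoch_sums.get(k, 0.0) + float(v.data) * len(idx)
            n_seen += len(idx)

        val = _eval_pass(model, val_ds, img_mean, img_sd, weights)
        record = {"epoch": epoch, "lr": lr}
        record.update({f"train_{k}": v / n_seen for k, v in epoch_sums.items()})
        record.update({f"val_{k}": v for k, v in val.items()})
        history.append(record)
        if verbose:
            print(f"[epoch {epoch:3d}] lr={lr:.2e} "
                  f"train={record['train_total']:.4f} "
                  f"val={record['val_total']:.4f} acc={val['accuracy']:.3f}")

        if val["total"] < best_val:
            best_val = val["total"]
            best_state = model.state_dict()
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                stopped_early = True
                break

    model.load_state_dict(best_state)
    return TrainResult(history=history, best_state=best_state,
                       best_epoch=best_epoch, best_val_total=float(best_val),
                       stopped_early=stopped_early)


# ---------------------------------------------------------------------------
# evaluation & profiling


def evaluate(model: FusionModel, ds: ArrayDataset,
             stats: StandardizationStats, img_mean=None, img_sd=None,
             batch_size: int = 64) -> MetricsReport:
    """Test-set metrics: accuracy, macro-F1 and per-class F1 for the health
    head; MAE / RMSE in original units for the gas heads (predictions and
    targets un-z-scored with the training statistics)."""
    if len(ds) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    img_mean = np.zeros(3) if img_mean is None else img_mean
    img_sd = np.ones(3) if img_sd is None else img_sd
    preds, o2p, co2p = [], [], []
    for lo in range(0, len(ds), batch_size):
        idx = np.arange(lo, min(lo + batch_size, len(ds)))
        images, sensors = _model_inputs(model, ds, idx, img_mean, img_sd)
        out = model.predict(images=images, sensors=sensors)
        if out.probs is not None:
            preds.append(out.probs.argmax(axis=1))
        if out.o2 is not None:
            o2p.append(out.o2)
        if out.co2 is not None:
            co2p.append(out.co2)

    if preds:
        y_pred = np.concatenate(preds)
        acc = accuracy_score(ds.labels, y_pred)
        per_class = f1_score(ds.labels, y_pred, labels=[0, 1, 2, 3],
                             average=None, zero_division=0)
        macro = float(per_class.mean())
    else:
        acc, macro, per_class = float("nan"), float("nan"), (float("nan"),) * 4

    def reg_metrics(pred_std, target_name, orig):
        if not pred_std:
            return float("nan"), float("nan")
        pred = invert_target_standardization(
            np.concatenate(pred_std), target_name, stats)
        err = pred - orig
        return float(np.abs(err).mean()), float(np.sqrt((err ** 2).mean()))

    o2_mae, o2_rmse = reg_metrics(o2p, "O2_rate", ds.o2_orig)
    co2_mae, co2_rmse = reg_metrics(co2p, "CO2_rate", ds.co2_orig)
    return MetricsReport(accuracy=float(acc), macro_f1=macro,
                         per_class_f1=tuple(float(f) for f in np.atleast_1d(per_class)),
                         o2_mae=o2_mae, o2_rmse=o2_rmse,
                         co2_mae=co2_mae, co2_rmse=co2_rmse)


def profile(model: FusionModel, latency_passes: int = 30) -> dict:
    """Parameter count, static MAC count and a median single-image forward
    latency (informational; never asserted)."""
    import time

    cfg = model.cfg
    n_params = count_params(model)
    n_macs = count_macs(
        cfg.backbone, cfg.sensor_dim, mlp_widths=cfg.mlp_widths,
        head_hidden=cfg.head_hidden, n_classes=cfg.n_classes,
        use_se=cfg.use_se, heads=tuple(cfg.heads))
    images = sensors = None
    if cfg.backbone is not None:
        res = cfg.backbone.resolution
        images = np.zeros((1, 3, res, res), dtype=np.float32)
    if cfg.sensor_dim is not None:
        sensors = np.zeros((1, cfg.sensor_dim), dtype=np.float32)
    model.eval()
    times = []
    for _ in range(max(latency_passes, 1)):
        t0 = time.perf_counter()
        model.predict(images=images, sensors=sensors)
        times.append((time.perf_counter() - t0) * 1e3)
    return {"n_params": n_params, "n_macs": n_macs,
            "latency_ms": float(np.median(times))}
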