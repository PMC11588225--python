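"""Dataset I/O, training and evaluation loops, prediction and profiling.

Training follows the reference recipe for this family of lightweight
segmentation networks: Adam at an initial learning rate of 1e-4, batch
size 8, the combined BCE-Dice objective, and plateau-based learning-rate
decay — when the validation loss fails to improve for
``decay_patience_epochs`` epochs the rate is multiplied by
``lr_decay_factor`` (default 0.5).  Everything is seeded: weight
initialisation, batch shuffling, and the synthetic data feeding the tests,
so two runs with the same seed produce identical loss curves.

Evaluation binarises the predicted probability map at ``threshold``
(default 0.5) and reports per-image IoU/DSC/accuracy/sensitivity,
macro-averaged (mean +- std over images) by default, with pooled (micro)
counts also available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize as sk_resize

from . import autograd as ag
from .autograd import Tensor
from .network import (ComplexityReport, NetworkConfig, SegmentationNetwork,
                      complexity, variant_config)
from .objectives import (ConfusionCounts, MetricReport, combined_loss,
                         confusion, metrics)
from .synthetic import LabeledSample

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "LoadReport",
    "load_dataset",
    "train",
    "evaluate",
    "EvalResult",
    "predict",
    "summarize",
]

IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}
MASK_SUFFIX = "_mask"


@dataclass
class TrainConfig:
    epochs: int = 200
    batch_size: int = 8
    initial_lr: float = 1e-4
    lr_decay_factor: float = 0.5
    decay_patience_epochs: int = 10
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if not 0.0 < self.lr_decay_factor < 1.0:
            raise ValueError("lr_decay_factor must lie in (0, 1)")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_metrics: list[MetricReport] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)


@dataclass
class LoadReport:
    """Loaded samples plus anything that went wrong, never silently dropped."""

    samples: list[LabeledSample]
    missing_masks: list[str] = field(default_factory=list)


def _read_image(path: Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    return arr.astype(np.float64) / 255.0


def load_dataset(root_path, input_size: tuple[int, int] | None = None) -> LoadReport:
    """Read image/mask pairs from a directory.

    Masks share the image's stem with a ``_mask`` suffix (PNG).  Images are
    scaled to [0, 1]; masks binarised at 127/255 (values outside {0, 255}
    trigger a warning, not an error).  When ``input_size`` is given both
    are resized to it — bilinear for images, nearest for masks.
    """
    root = Path(root_path)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset directory not found: {root}")
    samples: list[LabeledSample] = []
    missing: list[str] = []
    for img_path in sorted(root.iterdir()):
        if img_path.suffix.lower() not in IMAGE_SUFFIXES:
            continue
        if img_path.stem.endswith(MASK_SUFFIX):
            continue
        mask_path = img_path.with_name(img_path.stem + MASK_SUFFIX + ".png")
        if not mask_path.exists():
            missing.append(img_path.name)
            continue
        image = _read_image(img_path).transpose(2, 0, 1)
        raw_mask = np.asarray(iio.imread(mask_path))
        if raw_mask.ndim == 3:
            raw_mask = raw_mask[..., 0]
        values = np.unique(raw_mask)
        if not np.all(np.isin(values, (0, 1, 255))):
            warnings.warn(
                f"mask {mask_path.name} is not binary; binarising at 127/255",
                stacklevel=2)
        mask = (raw_mask > 127).astype(np.uint8) if raw_mask.max() > 1 \
            else raw_mask.astype(np.uint8)
        if input_size is not None and image.shape[1:] != tuple(input_size):
            image = np.stack([
                sk_resize(ch, input_size, order=1, anti_aliasing=False,
                          preserve_range=True) for ch in image])
            mask = sk_resize(mask, input_size, order=0, anti_aliasing=False,
                             preserve_range=True).astype(np.uint8)
        samples.append(LabeledSample(image=image, mask=mask,
                                     meta={"path": img_path.name}))
    if missing:
        warnings.warn(
            f"{len(missing)} image(s) without a mask were skipped: {missing[:5]}",
            stacklevel=2)
    return LoadReport(samples=samples, missing_masks=missing)


def _stack(samples: list[LabeledSample]) -> tuple[np.ndarray, np.ndarray]:
    images = np.stack([s.image for s in samples])
    masks = np.stack([s.mask for s in samples])[:, None].astype(np.float64)
    return images, masks


def _dataset_loss(net: SegmentationNetwork, samples: list[LabeledSample],
                  batch_size: int) -> float:
    total, count = 0.0, 0
    for lo in range(0, len(samples), batch_size):
        chunk = samples[lo:lo + batch_size]
        images, masks = _stack(chunk)
        pred = net.forward(Tensor(images))
        total += combined_loss(pred, Tensor(masks)).item() * len(chunk)
        count += len(chunk)
    return total / count


def train(net: SegmentationNetwork, train_set: list[LabeledSample],
          val_set: list[LabeledSample], cfg: TrainConfig,
          progress: bool = False) -> TrainHistory:
    """Optimise `net` in place; returns the per-epoch history."""
    from .nn import Adam

    if not train_set or not val_set:
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.parameters(), lr=cfg.initial_lr)
    history = TrainHistory()
    best_val = np.inf
    stale = 0

    for epoch in range(cfg.epochs):
        net.train()
        order = rng.permutation(len(train_set))
        epoch_loss, seen = 0.0, 0
        for lo in range(0, len(order), cfg.batch_size):
            batch = [train_set[i] for i in order[lo:lo + cfg.batch_size]]
            images, masks = _stack(batch)
            opt.zero_grad()
            pred = net.forward(Tensor(images))
            loss = combined_loss(pred, Tensor(masks))
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {value}")
            loss.backward()
            opt.step()
            epoch_loss += value * len(batch)
            seen += len(batch)

        net.eval()
        val_loss = _dataset_loss(net, val_set, cfg.batch_size)
        val_report = evaluate(net, val_set, cfg).macro_mean
        history.train_loss.append(epoch_loss / seen)
        history.val_loss.append(val_loss)
        history.val_metrics.append(val_report)
        history.lr.append(opt.lr)
        if progress:  # pragma: no cover - console nicety
            print(f"epoch {epoch + 1}/{cfg.epochs} "
                  f"train {history.train_loss[-1]:.4f} val {val_loss:.4f} "
                  f"iou {val_report.iou:.3f} lr {opt.lr:.2e}")

        if val_loss < best_val - 1e-12:
            best_val = val_loss
            stale = 0
        else:
            stale += 1
            if stale >= cfg.decay_patience_epochs:
                opt.lr *= cfg.lr_decay_factor
                stale = 0
    return history


@dataclass
class EvalResult:
    per_image: list[tuple[str, MetricReport]]
    macro_mean: MetricReport
    macro_std: MetricReport
    micro: MetricReport


def evaluate(net: SegmentationNetwork, test_set: list[LabeledSample],
             cfg: TrainConfig, batch_size: int | None = None) -> EvalResult:
    """Per-image confusion at ``cfg.threshold``; macro mean +- std plus
    pooled (micro) metrics."""
    if not test_set:
        raise ValueError("evaluation set must be non-empty")
    was_training = net.training
    net.eval()
    bs = batch_size or cfg.batch_size
    per_image: list[tuple[str, MetricReport]] = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for lo in range(0, len(test_set), bs):
        chunk = test_set[lo:lo + bs]
        images, masks = _stack(chunk)
        pred = net.forward(Tensor(images)).data
        for j, sample in enumerate(chunk):
            c = confusion(pred[j, 0], sample.mask, cfg.threshold)
            pooled = pooled + c
            name = str(sample.meta.get("path", sample.meta.get("seed", lo + j)))
            per_image.append((name, metrics(c)))
    if was_training:
        net.train()
    table = np.array([[r.iou, r.dsc, r.acc, r.sen] for _, r in per_image])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean = np.nanmean(table, axis=0)
        std = np.nanstd(table, axis=0)
    return EvalResult(
        per_image=per_image,
        macro_mean=MetricReport(*mean),
        macro_std=MetricReport(*std),
        micro=metrics(pooled),
    )


def predict(net: SegmentationNetwork, image_path, out_path,
            cfg: TrainConfig | None = None) -> np.ndarray:
    """Segment one image file and write a {0, 255} PNG mask at its
    original resolution; returns the binary mask array."""
    cfg = cfg or TrainConfig()
    path = Path(image_path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    image = _read_image(path)
    orig_size = image.shape[:2]
    net_size = net.cfg.input_size
    resized = np.stack([
        sk_resize(image[..., ch], net_size, order=1, anti_aliasing=False,
                  preserve_range=True) for ch in range(3)])
    net.eval()
    prob = net.forward(Tensor(resized[None]))
    prob_full = ag.bilinear_resize(prob, orig_size).data[0, 0]
    mask = (prob_full >= cfg.threshold).astype(np.uint8)
    iio.imwrite(Path(out_path), mask * 255)
    return mask


def summarize(cfg: NetworkConfig | str | None = None,
              input_size: tuple[int, int] | None = None,
              seed: int = 0) -> ComplexityReport:
    """Complexity report for a config or a named ablation variant."""
    if isinstance(cfg, str):
        cfg = variant_config(cfg)
    return complexity(cfg, seed=seed, input_size=input_size)
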