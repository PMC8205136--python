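"""Train / predict / evaluate orchestration over phantom or real datasets.

A dataset directory holds paired 8-bit PNGs named ``img_####.png`` (greyscale
image) and ``msk_####.png`` (ordinary labels {0, 1, 2}).  Training minimises
the expanded cross-entropy (or its per-channel binary form) over either
grey-level probability targets or ordinary one-hot targets — the two
conditions whose loss curves the method compares — and records a per-epoch
loss history.  Prediction writes the channel-mean grey map of the network
output as an 8-bit PNG; evaluation produces one grey-mass overlap row per
image per lesion class plus mean/standard-deviation summaries on the Dice-%
/ IOU-% scale.
"""

from __future__ import annotations

import csv
import re
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import labels as _labels
from . import loss as _loss
from . import metrics as _metrics
from .model import ArchitectureConfig, ExpandedUNet
from .nn import Adam

__all__ = [
    "TrainConfig",
    "TrainResult",
    "load_pairs",
    "load_train_config",
    "train",
    "predict",
    "evaluate",
]

LOSS_VARIANTS = ("ece", "bce")
LABEL_MODES = ("grey-probability", "ordinary")


@dataclass(frozen=True)
class TrainConfig:
    """Training conditions.

    ``loss_variant`` selects the expanded cross-entropy proper (``"ece"``) or
    the per-channel binary cross-entropy mean (``"bce"``, the deployment
    compatibility mode — identical gradient direction, 1/3 the magnitude).
    ``label_mode`` selects grey-level probability targets
    (0 / 0.5 / 1 on all three channels) or ordinary one-hot targets.
    """

    epochs: int = 15
    batch_size: int = 4
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    loss_variant: str = "ece"
    label_mode: str = "grey-probability"
    seed: int = 0
    checkpoint: str = "model.npz"
    history: str = "history.tsv"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss_variant not in LOSS_VARIANTS:
            raise ValueError(f"loss_variant must be one of {LOSS_VARIANTS}")
        if self.label_mode not in LABEL_MODES:
            raise ValueError(f"label_mode must be one of {LABEL_MODES}")


@dataclass
class TrainResult:
    checkpoint: str
    history: list[dict] = field(default_factory=list)


def load_pairs(data_dir) -> list[tuple[Path, Path]]:
    """Collect matched (image, mask) path pairs; report unpaired files."""
    data_dir = Path(data_dir)
    imgs = {p.stem[4:]: p for p in sorted(data_dir.glob("img_*.png"))}
    msks = {p.stem[4:]: p for p in sorted(data_dir.glob("msk_*.png"))}
    missing_masks = sorted(set(imgs) - set(msks))
    missing_imgs = sorted(set(msks) - set(imgs))
    if missing_masks or missing_imgs:
        problems = [f"image img_{k}.png has no mask" for k in missing_masks]
        problems += [f"mask msk_{k}.png has no image" for k in missing_imgs]
        raise FileNotFoundError(
            f"unpaired files in {data_dir}: " + "; ".join(problems))
    if not imgs:
        raise FileNotFoundError(f"no img_*.png / msk_*.png pairs in {data_dir}")
    return [(imgs[k], msks[k]) for k in sorted(imgs)]


def _targets_from_mask(mask: np.ndarray, label_mode: str) -> np.ndarray:
    """(3, H, W) training target for one mask."""
    if label_mode == "grey-probability":
        t = _labels.ordinary_to_grey_probability(mask)
    else:  # ordinary one-hot
        t = np.eye(3)[np.asarray(mask, dtype=int)]
    return np.moveaxis(t, -1, 0)


def _loss_and_grad(targets: np.ndarray, probs: np.ndarray,
                   variant: str) -> tuple[float, np.ndarray]:
    """Loss value and gradient w.r.t. probabilities, both in NCHW layout."""
    t = np.moveaxis(targets, 1, -1)
    p = np.moveaxis(probs, 1, -1)
    value = _loss.expanded_cross_entropy(t, p)
    grad = _loss.expanded_cross_entropy_grad(t, p)
    if variant == "bce":
        value /= 3.0
        grad = grad / 3.0
    return value, np.moveaxis(grad, -1, 1)


def train(data_dir, cfg: TrainConfig | None = None,
          arch: ArchitectureConfig | None = None) -> TrainResult:
    """Train the expanded U-Net on a paired dataset directory.

    Writes the per-epoch loss history (TSV: epoch, loss, seconds) to
    ``cfg.history``, the final checkpoint to ``cfg.checkpoint`` and an
    architecture summary next to it.  A fixed seed makes the run — weight
    initialisation, shuffling, dropout — reproducible.
    """
    cfg = cfg or TrainConfig()
    arch = arch or ArchitectureConfig()
    pairs = load_pairs(data_dir)
    images = np.stack([_labels.read_image(ip) for ip, _ in pairs])
    masks = [_labels.read_mask(mp) for _, mp in pairs]
    for (ip, mp), img, msk in zip(pairs, images, masks):
        if img.shape != msk.shape:
            raise ValueError(f"{ip.name} and {mp.name} have different sizes: "
                             f"{img.shape} vs {msk.shape}")
    targets = np.stack([_targets_from_mask(m, cfg.label_mode) for m in masks])

    model = ExpandedUNet(arch, seed=cfg.seed)
    optimizer = Adam(model.layers, lr=cfg.learning_rate)
    shuffle_rng = np.random.default_rng(cfg.seed + 1)
    n = len(pairs)

    history: list[dict] = []
    for epoch in range(1, cfg.epochs + 1):
        t0 = time.perf_counter()
        order = shuffle_rng.permutation(n)
        batch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            probs = model.forward(images[idx], train=True)
            value, grad = _loss_and_grad(targets[idx], probs, cfg.loss_variant)
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {value}")
            model.backward(grad)
            optimizer.step()
            batch_losses.append(value)
        history.append({"epoch": epoch,
                        "loss": float(np.mean(batch_losses)),
                        "seconds": time.perf_counter() - t0})

    hist_path = Path(cfg.history)
    hist_path.parent.mkdir(parents=True, exist_ok=True)
    with open(hist_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["epoch", "loss", "seconds"],
                                delimiter="\t")
        writer.writeheader()
        for row in history:
            writer.writerow({"epoch": row["epoch"],
                             "loss": f"{row['loss']:.6f}",
                             "seconds": f"{row['seconds']:.3f}"})
    ckpt = Path(cfg.checkpoint)
    ckpt.parent.mkdir(parents=True, exist_ok=True)
    model.save(str(ckpt))
    Path(str(ckpt) + ".summary.txt").write_text(model.summary_text())
    return TrainResult(checkpoint=str(ckpt), history=history)


def _index_of(path: Path) -> str:
    m = re.search(r"(\d+)$", path.stem)
    return m.group(1) if m else path.stem


def predict(checkpoint, image_paths, out_dir=None,
            save_raw: bool = False) -> list[np.ndarray]:
    """Run inference and write grey output maps as 8-bit PNGs.

    For an input named ``img_0007.png`` the grey map is written as
    ``pred_0007.png``; with ``save_raw=True`` the 3-channel probability map is
    also stored as ``raw_0007.npz``.  Inference is deterministic (dropout
    off).  Returns the grey maps on the 0–255 scale.
    """
    model = ExpandedUNet.load(str(checkpoint))
    out = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
    greys = []
    for path in image_paths:
        path = Path(path)
        img = _labels.read_image(path)
        probs = model.forward(img[None], train=False)[0]
        pred = np.moveaxis(probs, 0, -1)
        grey = _labels.prediction_to_grey_map(pred)
        greys.append(grey)
        if out is not None:
            stem = _index_of(path)
            _labels.write_grey_png(out / f"pred_{stem}.png", grey)
            if save_raw:
                np.savez(out / f"raw_{stem}.npz", probabilities=pred)
    return greys


def evaluate(pred_dir, truth_dir, out_path=None) -> tuple[list[dict], dict]:
    """Grey-mass Dice/IOU report over matched prediction/truth files.

    Pairs ``pred_####.png`` in ``pred_dir`` with ``msk_####.png`` in
    ``truth_dir`` by numeric index; every lesion class present in a truth mask
    yields one row (x_t, x_p, Δx, Dice %, IOU %, tolerance flag).  Returns
    the rows and a summary with per-class and overall mean/std, and writes
    them as a delimited report if ``out_path`` is given.
    """
    pred_dir, truth_dir = Path(pred_dir), Path(truth_dir)
    truths = {_index_of(p): p for p in sorted(truth_dir.glob("msk_*.png"))}
    preds = {_index_of(p): p for p in sorted(pred_dir.glob("pred_*.png"))}
    if not truths:
        raise FileNotFoundError(f"no msk_*.png files in {truth_dir}")
    unmatched = sorted(set(truths) ^ set(preds))
    if unmatched:
        raise FileNotFoundError(
            f"unmatched prediction/truth indices: {', '.join(unmatched)}")

    rows: list[dict] = []
    for idx in sorted(truths):
        mask = _labels.read_mask(truths[idx])
        grey = np.asarray(_labels.read_image(preds[idx])) * 255.0
        for class_id in (1, 2):
            if not (mask == class_id).any():
                continue
            rep = _metrics.grey_dice_iou(mask, grey, _metrics.CLASS_MODELS[class_id])
            rows.append({"stem": idx,
                         "class": _metrics.CLASS_MODELS[class_id].name,
                         "x_t": rep.x_t, "x_p": rep.x_p,
                         "delta_x": rep.delta_x,
                         "dice_pct": 100.0 * rep.dice,
                         "iou_pct": 100.0 * rep.iou,
                         "within_tolerance": rep.within_tolerance})

    def _stats(selected: list[dict]) -> dict:
        dice = np.array([r["dice_pct"] for r in selected])
        iou = np.array([r["iou_pct"] for r in selected])
        return {"n": len(selected),
                "dice_mean": float(dice.mean()) if len(dice) else float("nan"),
                "dice_std": float(dice.std()) if len(dice) else float("nan"),
                "iou_mean": float(iou.mean()) if len(iou) else float("nan"),
                "iou_std": float(iou.std()) if len(iou) else float("nan")}

    summary = {"overall": _stats(rows)}
    for name in ("benign", "malignant"):
        summary[name] = _stats([r for r in rows if r["class"] == name])

    if out_path is not None:
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        with open(out_path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, delimiter="\t",
                fieldnames=["stem", "class", "x_t", "x_p", "delta_x",
                            "dice_pct", "iou_pct", "within_tolerance"])
            writer.writeheader()
            for row in rows:
                writer.writerow({**row,
                                 "x_t": f"{row['x_t']:.1f}",
                                 "x_p": f"{row['x_p']:.1f}",
                                 "delta_x": f"{row['delta_x']:.1f}",
                                 "dice_pct": f"{row['dice_pct']:.1f}",
                                 "iou_pct": f"{row['iou_pct']:.1f}"})
        with open(str(out_path) + ".summary.tsv", "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, delimiter="\t",
                fieldnames=["group", "n", "dice_mean", "dice_std",
                            "iou_mean", "iou_std"])
            writer.writeheader()
            for group, st in summary.items():
                writer.writerow({"group": group, "n": st["n"],
                                 **{k: f"{st[k]:.1f}" for k in
                                    ("dice_mean", "dice_std", "iou_mean", "iou_std")}})
    return rows, summary


def load_train_config(path) -> tuple[TrainConfig, ArchitectureConfig]:
    """Read a flat key/value YAML config into train + architecture configs.

    Keys are the field names of :class:`TrainConfig` and
    :class:`ArchitectureConfig`; unknown keys raise an error.
    """
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping of key: value pairs")
    train_keys = set(TrainConfig.__dataclass_fields__)
    arch_keys = {k for k, f in ArchitectureConfig.__dataclass_fields__.items()
                 if f.init}
    unknown = set(data) - train_keys - arch_keys
    if unknown:
        raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
    train_kwargs = {k: v for k, v in data.items() if k in train_keys}
    arch_kwargs = {k: v for k, v in data.items() if k in arch_keys}
    for key in ("input_size", "dropout_after"):
        if key in arch_kwargs and arch_kwargs[key] is not None:
            arch_kwargs[key] = tuple(arch_kwargs[key])
    return TrainConfig(**train_kwargs), ArchitectureConfig(**arch_kwargs)
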